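# Methods

This note documents the models, conventions and numerical choices behind
facetmorph, and what the synthetic surfaces do and do not emulate.

## Sphere fit and error metrics

The radius of curvature of a facet is defined by the *geometric*
least-squares sphere: minimize Σᵢ(‖pᵢ−c‖−r)² over center c and radius r.
The solver seeds with the algebraic linear fit (solving ‖p‖² = 2c·p +
(r²−‖c‖²) by least squares) and refines by Gauss–Newton with step halving,
so the refined objective can never exceed the seed's; iteration stops when
the relative parameter change falls below 1e-10 or after 100 iterations
(the `converged` flag records which).  Orthogonal residuals are summarized
as the mean absolute error (mm) and as a fraction of the radius; both are
reported because a 0.1 mm error means something different on a 5 mm and a
20 mm facet.

Fewer than 4 points, or a point cloud whose smallest-to-largest PCA
eigenvalue ratio is below 1e-10 (a plane), is rejected: a sphere is
unidentifiable there, and the facet pipeline falls back to a plane fit with
the ROC marked unavailable.

Concave/convex classification uses the side of the mean outward surface
normal on which the fitted center lies (center "above" the surface ⇒
concave socket).  It therefore needs mesh normals: the point-only fit
returns `curvature_sense=None`, and facet meshes are expected to carry
outward-oriented normals (the generator guarantees this; real meshes can be
corrected via the orientation file).

## Anatomical frame and measurement planes

The published length/width/angle conventions presuppose an anatomical
orientation that a disarticulated bone mesh does not carry.  The frame is
therefore explicit: with landmarks, the supplied dorsal–volar and
radial–ulnar axes are projected into the surface tangent plane and
re-orthogonalized; without them, vertex PCA supplies sagittal (largest
variance), coronal (second) and normal (smallest) axes, the normal flipped
to agree with the mean face normal.  The PCA path is a convention, not an
anatomical fact — for strongly symmetric patches (near-circular caps) the
in-plane axes are arbitrary, and for bicondylar surfaces whose width
exceeds their length it can swap sagittal and coronal, which is why the
pipeline prefers an orientation file when one exists and the simulator
always writes one.

Planes: *mid-sagittal* = span(sagittal, normal) through the area-weighted
centroid (its plane normal is the coronal axis); *mid-coronal* =
span(coronal, normal).  Length and width are the arc lengths of the longest
connected cross-section polyline in those planes.  Cross-sections are
chained from triangle–plane intersection segments; ties between polylines
are broken deterministically by chaining order.

## Bicondylar decomposition

Initialization splits vertices at the median coronal coordinate (or from a
per-vertex label file mimicking a manual outline).  Each round fits a
sphere to each group and reassigns every vertex to the sphere with the
smaller absolute residual; the total squared residual is non-increasing, so
the iteration reaches a fixed point (cap 50 rounds).  Groups are named
radial/ulnar by mean coronal coordinate (+coronal = ulnar by convention);
faces inherit the majority vertex label; area fractions are face-area sums.
A group shrinking below 4 vertices or degenerating to a plane raises a
partition error, signalling an effectively unicondylar surface.

The divergence angle is defined as the angle between the rays from each
condyle's sphere center through its region's area-weighted centroid, both
projected into the mid-coronal plane.  This is one of several defensible
formalizations of "divergence between the condyles"; an alternative using
the regions' mean surface normals is available via
`divergence_method="mean-normals"`.

## Dorsal flattening

Two sub-criteria, both reported so either can be used alone: (a) the
whole-facet sphere-fit mean error exceeds a threshold (default 0.25 mm,
the value that correlated with visually flattened specimens); (b) some
dorsal band of the facet is fitted better by a plane than by the sphere.
For (b), candidate bands from 25 % up to the configured maximum fraction
(default 50 %) of vertices, ranked along the sagittal axis, are
plane-fitted and the band with the lowest plane-rms to sphere-error ratio
decides.  Scanning the band size rather than fixing it matters because the
true extent of a flat region is unknown and a band that overshoots it mixes
in curved surface, masking genuine flattening; conversely pure noise passes
no band, so the conjunction is robust on both sides.

## Synthetic surfaces

The generator emulates laser-scanned facet patches with exact ground truth:

- **Caps.**  Concentric-ring sampling in angle space, Delaunay-triangulated
  and mapped to the sphere; elongation (default 1.6) stretches the sampled
  region along the sagittal axis *in angle space*, so length > width while
  every vertex stays exactly on the sphere and the ROC ground truth remains
  exact.  Default target edge length 0.15 mm; cohort work uses 0.25–0.35 mm
  to keep runs fast, which leaves analytic areas and arcs within ~0.3 %.
- **Noise.**  Radial Gaussian displacement along vertex normals, default sd
  0.1 mm — the scanner's stated ±100 µm accuracy read as one standard
  deviation (the error distribution is not published).  Isotropic 3-D noise
  is not modelled; nor are registration artifacts, occlusion, surface
  powder effects or cartilage thickness, so passing tests demonstrate
  correctness of the measurement pipeline under idealized scan error, not
  robustness to every real-scan pathology.
- **Bicondylar surfaces.**  Two spheres side by side along the coronal
  axis; the emitted surface is the outer (max-height) union over the union
  of their footprints, so the condyles meet along the sphere-intersection
  ridge at mesh resolution (the ridge is a crease, not a blended fillet —
  its true shape is not quantified anywhere).  Targets are met by nested
  calibration: center separation is root-found for the requested divergence
  and the ulnar cap angle for the requested area fraction on a cheap
  continuous grid (with a half-cell rim erosion term so the grid agrees
  with the eventual triangulation), then the targets are corrected against
  the actual mesh with damped fixed-point steps.  Achieved values, recorded
  in the ground truth, land within ~0.35° and ~1 area point of the request;
  a second lever (sinking the ulnar sphere so its patch sits off-apex)
  extends the reachable divergence range for unequal radii.  Extreme corner
  combinations (large divergence with a very small ulnar share) can remain
  infeasible and raise an error; the cohort simulator redraws in that case.
- **Flattened caps.**  The dorsal fraction of vertices (default 40 %) is
  projected onto the tangent plane at the region's central direction; the
  generator verifies the emitted surface's best-sphere mean error exceeds
  0.25 mm, enlarging the fraction in 0.05 steps and failing at 0.8.
- **Cohort.**  Each simulated specimen carries a fourth-CMC pair, a
  bicondylar fifth-CMC pair and an intermetacarpal pair, with generating
  parameters drawn uniformly from the published measurement envelopes
  (cap angles solved from a surface-area draw, clamped to 12–75°); 6 of 10
  specimens get a flattened fourth-CMC hamate facet, matching the reported
  prevalence.  All draws flow through one seeded generator, so a seed fixes
  the cohort bit-for-bit.

One simplification: the simulated bicondylar patch is wider (coronal) than
long (sagittal) because the two condyles sit along the coronal axis, where
the published facets are longer than wide; the geometric measurements do
not depend on this, but it is why the pipeline uses the landmark frame
rather than PCA for these surfaces.

## Tolerances and problem sizes

Defaults, overridable per call or via the CLI config: weld tolerance 1e-9
mm; degenerate-face area 1e-12 mm²; sphere-fit convergence 1e-10 relative
with 100 iterations; partition cap 50 rounds; flattening threshold 0.25 mm.
Tests and the acceptance script run caps of roughly 2–40 k vertices and
cohorts of 10 specimens at 0.25–0.35 mm resolution — sizes chosen so the
full suite completes in a few minutes on one CPU while keeping every
analytic check inside a 0.5 % band.

## Known limitations

- The mid-sagittal/mid-coronal conventions, the divergence-ray definition
  and the mid-axial 3-point rule are explicit formalizations of quantities
  that are usually drawn by hand on a rendering; other conventions would
  give systematically different (though strongly correlated) numbers.
- Curvature is modelled only by spheres (plus the plane fallback and the
  3-point circle); cylinder or ellipsoid fits are out of scope.
- The alternating two-sphere fit is a local optimizer; its coronal-median
  initialization assumes the condyles separate along the coronal axis.
  Pathological inputs can converge to a poor local fixed point, which is
  why precomputed labels are accepted as an alternative initialization.
- Cohort statistics are descriptive (mean, range); no inter-specimen
  inference is attempted.
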