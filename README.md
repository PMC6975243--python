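# facetmorph

Morphometry of small articular surfaces on triangle meshes, built around the
joints between the hamate and the fourth/fifth metacarpal (MC) bases — the
surfaces harvested for hemi-hamate autografts and loaded in precision and
power grips.  Laser scans of such facets are only a few mm across, so their
shape is summarized by a handful of robust quantities which this package
computes:

- **Sphere-fit radius of curvature (ROC).**  For a facet patch with vertices
  $p_i$, the geometric least-squares sphere minimizes
  $\sum_i (\lVert p_i - c\rVert - r)^2$ over center $c$ and radius $r$
  (algebraic linear fit as seed, damped Gauss–Newton refinement).  The fit
  error is reported as the mean absolute orthogonal residual
  $\bar e = \tfrac1n \sum_i |\lVert p_i - c\rVert - r|$ in mm and as a
  fraction of the radius, and the facet is classified concave/convex from
  the side of the surface on which the center falls.
- **Cross-sectional dimensions.**  Facet length and width are arc lengths of
  the mid-sagittal and mid-coronal plane sections through the area-weighted
  centroid, with the anatomical frame taken from a landmark file or from
  vertex PCA.
- **Bicondylar decomposition.**  Fifth-CMC-type surfaces are split into a
  radial and an ulnar condyle by an alternating two-sphere fit (fit each
  group, reassign every vertex to the nearer sphere, repeat to a fixed
  point), yielding per-condyle ROCs, area fractions, and the **angle of
  divergence**: the angle between the center-to-centroid rays of the two
  condyles projected into the mid-coronal plane.
- **Dorsal flattening.**  A facet is flagged when its sphere-fit mean error
  exceeds 0.25 mm *and* a dorsal band of the patch is described better by a
  plane than by the sphere.
- **Inter-facet and 3-point measures.**  The angle between two neighbouring
  facets is measured between line fits of their shared mid-coronal
  cross-sections; cylinder-like facets get a 3-point circumradius
  ($R = abc/4K$) at their mid-axial section.

Because no scan data accompany the published measurements, the package
includes a first-class synthetic generator (`facetmorph.synthetic`):
spherical caps (optionally elongated, optionally dorsally flattened),
two-sphere bicondylar surfaces with calibrated divergence and area split,
planar facet pairs at a known dihedral, and a whole simulated study cohort —
all with exact ground truth and radial Gaussian noise at the scanner's
0.1 mm accuracy.

## Worked example

```python
from facetmorph import CapSpec, fit_sphere, generate_cap

mesh, truth = generate_cap(CapSpec(radius=11.18, cap_angle=60, noise_sd=0.1,
                                   resolution=0.3, seed=1))
fit = fit_sphere(mesh.vertices)
print(f"ROC {fit.radius:.4f} mm, mean error {fit.mean_abs_error:.4f} mm")
```

prints

```
ROC 11.1815 mm, mean error 0.0795 mm
```

i.e. the generating 11.18 mm radius is recovered essentially unbiased under
0.1 mm radial noise, and the mean absolute residual sits at the theoretical
mean of |N(0, 0.1 mm)|, about 0.0798 mm.  The `examples/` directory holds
one short script per capability (sphere fits, full facet measurement with
flattening, bicondylar decomposition, inter-facet angles, and a shell
pipeline); each prints the numbers it computes and what they mean.

## Command line

```sh
facetmorph simulate --cohort 10 --seed 7 --out cohort   # meshes + ground truth
facetmorph measure  --input cohort --out measured       # per-facet table
facetmorph report   --measurements measured/measurements.json
```

`measure` consumes any manifest CSV (`specimen_id, path, role, side`)
pointing at PLY/STL/OBJ facet meshes in mm, so real scan exports can be
analysed the same way.

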