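"""Per-facet morphometry: the measurements reported for hamate-metacarpal
articular surfaces.

For a single facet this produces surface area, mid-sagittal length,
mid-coronal width, best sphere-fit radius of curvature (ROC) with mean
error, and the concave/convex call.  For the bicondylar fifth
carpometacarpal surface a two-sphere alternating fit splits the patch into
a radial and an ulnar condyle, giving per-condyle ROCs, area fractions and
the angle of divergence.  Dorsal flattening (seen in the fourth
carpometacarpal joint) is flagged when the single-sphere mean error exceeds
a threshold (default 0.25 mm) and the dorsal half of the patch is better
described by a plane.  The angle between two neighbouring facets is
measured between line fits of their mid-coronal cross-sections.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from . import geom_core
from .errors import (
    CoplanarPointsError,
    DegeneratePartitionError,
    InsufficientRegionError,
    ValidationError,
)
from .geom_core import AnatomicalFrame, CrossSection, SphereFit, angle_between, fit_sphere
from .mesh_io import TriangleMesh

FLATTENING_THRESHOLD_MM = 0.25  # mean sphere-fit error above this suggests a flat region


@dataclass
class FacetReport:
    """One facet's row of measurements."""

    name: str
    surface_area: float          # mm^2
    mid_sagittal_length: float   # mm
    mid_coronal_width: float     # mm
    roc: float | None            # mm; None when the patch is planar
    mean_abs_error: float | None # mm
    mean_error_pct: float | None # fraction of ROC
    curvature_sense: str | None
    flattened_dorsal: bool | None = None  # None = not evaluated
    warnings: list[str] = field(default_factory=list)


@dataclass
class FlatteningResult:
    """Outcome of the dorsal-flattening test on one facet."""

    flagged: bool
    sphere_mean_abs_error: float   # mm, whole facet
    dorsal_sphere_mean_abs_error: float  # mm, dorsal subset only
    dorsal_plane_rms: float        # mm
    dorsal_fraction_used: float
    threshold: float


@dataclass
class BicondylarResult:
    """Two-sphere decomposition of a bicondylar facet."""

    radial_fit: SphereFit
    ulnar_fit: SphereFit
    assignment: np.ndarray          # per-vertex label: 0 = radial, 1 = ulnar
    face_labels: np.ndarray         # per-face label by vertex majority
    radial_area_fraction: float     # percent
    ulnar_area_fraction: float      # percent
    radial_centroid: np.ndarray     # area-weighted centroid of the radial region
    ulnar_centroid: np.ndarray
    radial_mean_normal: np.ndarray  # area-weighted mean surface normal per region
    ulnar_mean_normal: np.ndarray
    divergence_angle: float         # degrees
    n_iterations: int
    converged: bool
    sse_history: list[float] = field(default_factory=list)


# ---------------------------------------------------------------------------
# single-facet measurements
# ---------------------------------------------------------------------------

def measure_facet(
    mesh: TriangleMesh,
    frame: AnatomicalFrame,
    flattening: bool = False,
    flattening_threshold: float = FLATTENING_THRESHOLD_MM,
    dorsal_fraction: float = 0.5,
) -> FacetReport:
    """Measure a single articular facet.

    Length is the arc length of the mid-sagittal cross-section, width that
    of the mid-coronal cross-section; the ROC comes from the geometric
    sphere fit to all vertices.  A patch that is planar within tolerance
    gets a plane fit instead and a ``roc`` of None with a warning recorded.
    """
    mesh.validate()
    notes: list[str] = []
    area = geom_core.surface_area(mesh)
    length = geom_core.cross_section(mesh, *frame.mid_sagittal_plane).arc_length
    width = geom_core.cross_section(mesh, *frame.mid_coronal_plane).arc_length

    roc = mean_abs = mean_pct = None
    sense = None
    flat_flag: bool | None = None
    sphere: SphereFit | None = None
    try:
        sphere = fit_sphere(
            mesh.vertices,
            mean_normal=mesh.mean_surface_normal(),
            centroid=mesh.area_weighted_centroid(),
        )
        roc = sphere.radius
        mean_abs = sphere.mean_abs_error
        mean_pct = sphere.mean_error_pct
        sense = sphere.curvature_sense
        if not sphere.converged:
            notes.append("sphere fit did not fully converge; best iterate reported")
    except CoplanarPointsError:
        _, _, rms = geom_core.fit_plane(mesh.vertices)
        notes.append(f"patch is planar (plane rms {rms:.4g} mm); ROC unavailable")

    if flattening and sphere is not None:
        flat = detect_dorsal_flattening(
            mesh,
            frame,
            sphere,
            dorsal_fraction=dorsal_fraction,
            threshold=flattening_threshold,
        )
        flat_flag = flat.flagged

    return FacetReport(
        name=mesh.name,
        surface_area=area,
        mid_sagittal_length=length,
        mid_coronal_width=width,
        roc=roc,
        mean_abs_error=mean_abs,
        mean_error_pct=mean_pct,
        curvature_sense=sense,
        flattened_dorsal=flat_flag,
        warnings=notes,
    )


def detect_dorsal_flattening(
    mesh: TriangleMesh,
    frame: AnatomicalFrame,
    sphere: SphereFit,
    dorsal_fraction: float = 0.5,
    threshold: float = FLATTENING_THRESHOLD_MM,
    dorsal_sign: int = 1,
) -> FlatteningResult:
    """Flag a facet whose dorsal portion has flattened away from the sphere.

    Two sub-criteria, both reported: (a) the whole-facet sphere-fit mean
    absolute error exceeds ``threshold``; (b) some dorsal band of the facet
    is described better by a plane than by the sphere.  For (b) the
    vertices are ranked along the sagittal axis (dorsal =
    ``dorsal_sign`` * sagittal) and candidate dorsal bands from 25 % up to
    ``dorsal_fraction`` of the vertices are plane-fitted; the band with the
    lowest plane-rms-to-sphere-error ratio decides, since the true extent
    of a flat region is not known a priori and a band that overshoots it
    mixes in curved surface.  The flag is the conjunction of (a) and (b),
    so pure scanner noise — which inflates the sphere error isotropically
    but is not better explained by a plane — does not trip it.
    """
    if not 0.0 < dorsal_fraction < 1.0:
        raise ValidationError("dorsal_fraction must be in (0, 1)")
    coords = (mesh.vertices - frame.origin) @ (dorsal_sign * frame.sagittal_axis)
    fractions = [f for f in (0.25, 0.3, 0.35, 0.4, 0.45, 0.5, 0.6, 0.7)
                 if f <= dorsal_fraction]
    fractions = fractions or [dorsal_fraction]
    best = None  # (ratio, plane_rms, sphere_err, fraction)
    for frac in fractions:
        cut = np.quantile(coords, 1.0 - frac)
        dorsal = mesh.vertices[coords >= cut]
        if len(dorsal) < 10:
            continue
        _, _, plane_rms = geom_core.fit_plane(dorsal)
        sphere_err = float(
            np.abs(geom_core.point_sphere_residuals(dorsal, sphere)).mean()
        )
        ratio = plane_rms / max(sphere_err, 1e-12)
        if best is None or ratio < best[0]:
            best = (ratio, plane_rms, sphere_err, frac)
    if best is None:
        raise InsufficientRegionError(
            "dorsal subsets have fewer than 10 vertices; cannot assess flattening"
        )
    ratio, plane_rms, dorsal_sphere_err, frac_used = best
    flagged = bool(sphere.mean_abs_error > threshold and ratio < 1.0)
    return FlatteningResult(
        flagged=flagged,
        sphere_mean_abs_error=sphere.mean_abs_error,
        dorsal_sphere_mean_abs_error=dorsal_sphere_err,
        dorsal_plane_rms=plane_rms,
        dorsal_fraction_used=frac_used,
        threshold=threshold,
    )


# ---------------------------------------------------------------------------
# bicondylar decomposition
# ---------------------------------------------------------------------------

def _region_properties(mesh: TriangleMesh, face_mask: np.ndarray):
    """(area, area-weighted centroid, area-weighted mean unit normal)."""
    areas = mesh.face_areas()[face_mask]
    cents = mesh.face_centroids()[face_mask]
    cross = mesh.face_cross()[face_mask]
    total = areas.sum()
    if total <= 0:
        raise DegeneratePartitionError("a condyle region has zero area")
    centroid = (cents * areas[:, None]).sum(axis=0) / total
    mean_normal = cross.sum(axis=0)
    mean_normal = mean_normal / np.linalg.norm(mean_normal)
    return float(total), centroid, mean_normal


def partition_bicondylar(
    mesh: TriangleMesh,
    frame: AnatomicalFrame,
    initial_labels: np.ndarray | None = None,
    max_iter: int = 50,
    divergence_method: str = "center-ray",
) -> BicondylarResult:
    """Split a bicondylar facet into two spherical condyles.

    Alternating two-sphere fit: vertices start split at the median coronal
    coordinate (or from ``initial_labels``, e.g. a manual outline); each
    round fits a sphere to each group and reassigns every vertex to the
    sphere with the smaller absolute residual, until a fixed point (or
    ``max_iter``).  Groups are then named radial/ulnar by their mean coronal
    coordinate (+coronal = ulnar by convention).  Faces take the majority
    label of their vertices; area fractions are face-area sums over the
    total.  The divergence angle follows ``divergence_angle``.
    """
    mesh.validate()
    coords = (mesh.vertices - frame.origin) @ frame.coronal_axis
    if initial_labels is not None:
        labels = np.asarray(initial_labels, dtype=np.int64).copy()
        if labels.shape != (mesh.n_vertices,) or not np.isin(labels, [0, 1]).all():
            raise ValidationError("initial_labels must be one 0/1 label per vertex")
    else:
        labels = (coords >= np.median(coords)).astype(np.int64)

    sse_history: list[float] = []
    converged = False
    fits: list[SphereFit] = []
    n_iter = 0
    for n_iter in range(1, max_iter + 1):
        fits = []
        for g in (0, 1):
            pts = mesh.vertices[labels == g]
            if len(pts) < 4:
                raise DegeneratePartitionError(
                    f"group {g} shrank to {len(pts)} vertices; surface is likely unicondylar"
                )
            try:
                fits.append(fit_sphere(pts))
            except CoplanarPointsError as exc:
                raise DegeneratePartitionError(
                    f"group {g} became coplanar during partition: {exc}"
                ) from exc
        res = np.stack(
            [np.abs(geom_core.point_sphere_residuals(mesh.vertices, f)) for f in fits]
        )
        new_labels = np.argmin(res, axis=0).astype(np.int64)
        sse_history.append(float((res.min(axis=0) ** 2).sum()))
        if np.array_equal(new_labels, labels):
            converged = True
            break
        labels = new_labels
    if not converged:
        warnings.warn("bicondylar partition hit the iteration cap without a fixed point",
                      stacklevel=2)

    # name groups: +coronal = ulnar
    mean_c = [coords[labels == g].mean() for g in (0, 1)]
    radial_g, ulnar_g = (0, 1) if mean_c[0] <= mean_c[1] else (1, 0)
    assignment = (labels == ulnar_g).astype(np.int64)  # 0 radial, 1 ulnar
    radial_fit, ulnar_fit = fits[radial_g], fits[ulnar_g]

    # face labels by vertex majority; 2-of-3 always decides for two labels
    face_votes = assignment[mesh.faces].sum(axis=1)
    face_labels = (face_votes >= 2).astype(np.int64)
    areas = mesh.face_areas()
    total_area = areas.sum()
    ulnar_area = areas[face_labels == 1].sum()
    ulnar_pct = float(100.0 * ulnar_area / total_area)
    radial_pct = 100.0 - ulnar_pct

    _, radial_centroid, radial_normal = _region_properties(mesh, face_labels == 0)
    _, ulnar_centroid, ulnar_normal = _region_properties(mesh, face_labels == 1)

    result = BicondylarResult(
        radial_fit=radial_fit,
        ulnar_fit=ulnar_fit,
        assignment=assignment,
        face_labels=face_labels,
        radial_area_fraction=radial_pct,
        ulnar_area_fraction=ulnar_pct,
        radial_centroid=radial_centroid,
        ulnar_centroid=ulnar_centroid,
        radial_mean_normal=radial_normal,
        ulnar_mean_normal=ulnar_normal,
        divergence_angle=float("nan"),
        n_iterations=n_iter,
        converged=converged,
        sse_history=sse_history,
    )
    result.divergence_angle = divergence_angle(result, frame, method=divergence_method)
    return result


def divergence_angle(
    result: BicondylarResult, frame: AnatomicalFrame, method: str = "center-ray"
) -> float:
    """Angle of divergence between the two condyles, in the mid-coronal plane.

    ``center-ray`` (default): for each condyle, the ray from its sphere
    center through its region's area-weighted centroid; both rays are
    projected onto the mid-coronal plane and the angle between them
    returned.  ``mean-normals``: the regions' area-weighted mean surface
    normals are compared instead.
    """
    if method == "center-ray":
        u = result.radial_centroid - result.radial_fit.center
        v = result.ulnar_centroid - result.ulnar_fit.center
    elif method == "mean-normals":
        u = result.radial_mean_normal
        v = result.ulnar_mean_normal
    else:
        raise ValidationError(f"unknown divergence method {method!r}")
    # mid-coronal plane is spanned by coronal+normal axes: project out sagittal
    return angle_between(u, v, plane_normal=frame.sagittal_axis)


# ---------------------------------------------------------------------------
# inter-facet relationships
# ---------------------------------------------------------------------------

def _canonical_direction(d: np.ndarray, frame: AnatomicalFrame) -> np.ndarray:
    """Orient a section-line direction consistently (toward +coronal)."""
    s = d @ frame.coronal_axis
    if abs(s) < 1e-9:
        s = d @ frame.normal_axis
    return d if s >= 0 else -d


def interfacet_angle(
    facet_a: TriangleMesh, facet_b: TriangleMesh, shared_frame: AnatomicalFrame
) -> float:
    """Angle between two neighbouring facets at the shared mid-coronal plane.

    Both facets (expressed in one coordinate system) are cut by the shared
    mid-coronal plane; a total-least-squares line is fitted to each section
    polyline and the angle between the two directions returned in [0, 180].
    Directions are canonically oriented toward +coronal so the dihedral is
    reported rather than its supplement.
    """
    plane_point, plane_normal = shared_frame.mid_coronal_plane
    sec_a = geom_core.cross_section(facet_a, plane_point, plane_normal)
    sec_b = geom_core.cross_section(facet_b, plane_point, plane_normal)
    _, dir_a = geom_core.fit_line(sec_a.points)
    _, dir_b = geom_core.fit_line(sec_b.points)
    dir_a = _canonical_direction(dir_a, shared_frame)
    dir_b = _canonical_direction(dir_b, shared_frame)
    return angle_between(dir_a, dir_b)


def three_point_roc_of_facet(
    mesh: TriangleMesh, frame: AnatomicalFrame
) -> tuple[float, CrossSection]:
    """Three-point radius of curvature at the facet's mid-axial section.

    The facet is cut by the plane through its centroid spanned by the
    coronal and normal axes; the circle through the section's two endpoints
    and its mid-arc-length point gives the radius.
    """
    section = geom_core.cross_section(mesh, *frame.mid_coronal_plane)
    pts = section.points
    seg = np.linalg.norm(np.diff(pts, axis=0), axis=1)
    cum = np.concatenate([[0.0], np.cumsum(seg)])
    mid_idx = int(np.searchsorted(cum, cum[-1] / 2.0))
    mid_idx = min(max(mid_idx, 1), len(pts) - 2)
    radius = geom_core.three_point_roc(pts[0], pts[mid_idx], pts[-1])
    return radius, section


def area_fraction(sub_faces: np.ndarray, whole: TriangleMesh) -> float:
    """Percentage of the facet's area covered by a face subset."""
    areas = whole.face_areas()
    total = areas.sum()
    if total <= 0:
        raise ValidationError("whole mesh has zero area; fraction undefined")
    sub_faces = np.asarray(sub_faces)
    if sub_faces.dtype == bool:
        sub = areas[sub_faces].sum()
    else:
        sub = areas[sub_faces.astype(np.int64)].sum()
    return float(100.0 * sub / total)
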