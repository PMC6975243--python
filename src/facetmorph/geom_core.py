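"""Geometric primitives for articular-surface morphometry.

The central object is the least-squares sphere fit that defines a facet's
radius of curvature (ROC): the sphere whose surface deviates least from the
scanned patch, with the deviation summarized as a mean absolute error in mm
and as a fraction of the radius.  Around it sit the anatomical frame (which
pins down the mid-sagittal / mid-coronal measurement planes), plane and
circumcircle fits, plane cross-sections of a mesh, and angle helpers.

Conventions
-----------
* mid-sagittal plane: spanned by the sagittal (length) and normal axes, so
  its plane normal is the coronal axis; the facet length is the arc length
  of this section.
* mid-coronal plane: spanned by the coronal (width) and normal axes, plane
  normal = sagittal axis; the facet width is the arc length of this section.
* a facet is *concave* when the best-fit sphere center lies on the positive
  side of the mean outward surface normal (the center sits "above" a
  socket), *convex* otherwise.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import trimesh

from .errors import (
    AmbiguousFrameError,
    CollinearPointsError,
    CoplanarPointsError,
    DegenerateInputError,
    DegenerateSectionError,
    NoIntersectionError,
    UndefinedAngleError,
)
from .mesh_io import OrientationSpec, TriangleMesh

# sphere-fit convergence: relative parameter change below this stops Gauss-Newton
SPHERE_FIT_RTOL = 1e-10
SPHERE_FIT_MAX_ITER = 100
# points are "coplanar" when the smallest/largest PCA eigenvalue ratio is below this
COPLANARITY_RATIO = 1e-10


@dataclass
class AnatomicalFrame:
    """Orthonormal measurement frame anchored at the facet centroid."""

    origin: np.ndarray
    sagittal_axis: np.ndarray   # length direction (dorsal-volar-ish)
    coronal_axis: np.ndarray    # width direction (radial-ulnar-ish)
    normal_axis: np.ndarray     # out-of-surface
    handedness: int = 1

    def __post_init__(self) -> None:
        for name in ("origin", "sagittal_axis", "coronal_axis", "normal_axis"):
            setattr(self, name, np.asarray(getattr(self, name), dtype=np.float64))
        gram = np.abs(
            [
                self.sagittal_axis @ self.coronal_axis,
                self.sagittal_axis @ self.normal_axis,
                self.coronal_axis @ self.normal_axis,
            ]
        )
        if gram.max() > 1e-8:
            raise ValueError("frame axes are not orthogonal")

    @property
    def mid_sagittal_plane(self) -> tuple[np.ndarray, np.ndarray]:
        """(point, normal) of the plane containing sagittal + normal axes."""
        return self.origin, self.coronal_axis

    @property
    def mid_coronal_plane(self) -> tuple[np.ndarray, np.ndarray]:
        """(point, normal) of the plane containing coronal + normal axes."""
        return self.origin, self.sagittal_axis


@dataclass
class SphereFit:
    """Best-fit sphere of a facet patch with residual statistics."""

    center: np.ndarray
    radius: float
    mean_abs_error: float
    mean_error_pct: float   # fraction of radius (0.02 == 2 %)
    rms_error: float
    n_points: int
    curvature_sense: str | None = None  # "concave" | "convex" | None
    converged: bool = True


@dataclass
class CrossSection:
    """Ordered polyline where a plane cuts the mesh."""

    points: np.ndarray          # (k, 3) ordered along the section
    plane_point: np.ndarray
    plane_normal: np.ndarray
    arc_length: float = field(init=False)

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=np.float64)
        seg = np.diff(self.points, axis=0)
        self.arc_length = float(np.linalg.norm(seg, axis=1).sum())


# ---------------------------------------------------------------------------
# frames
# ---------------------------------------------------------------------------

def _canonical_sign(v: np.ndarray) -> np.ndarray:
    """Flip an eigenvector so its largest-magnitude component is positive."""
    i = int(np.argmax(np.abs(v)))
    return v if v[i] >= 0 else -v


def build_frame(mesh: TriangleMesh, orientation: OrientationSpec | None = None) -> AnatomicalFrame:
    """Anatomical frame from landmarks, or from vertex PCA as fallback.

    PCA path: sagittal = largest-variance axis, coronal = second, normal =
    smallest, with the normal flipped to agree with the mean outward face
    normal.  Landmark path: the supplied dorsal-volar / radial-ulnar axes
    are projected into the surface tangent plane (orthogonal to the PCA
    normal) and re-orthogonalized.
    """
    mesh.validate()
    origin = mesh.area_weighted_centroid()
    centered = mesh.vertices - mesh.vertices.mean(axis=0)
    cov = centered.T @ centered / len(centered)
    eigval, eigvec = np.linalg.eigh(cov)  # ascending
    mean_normal = mesh.mean_surface_normal()

    normal = eigvec[:, 0]
    if normal @ mean_normal < 0:
        normal = -normal

    if orientation is not None and orientation.source == "landmarks":
        dv = orientation.dorsal_volar_axis
        ru = orientation.radial_ulnar_axis
        sagittal = dv - (dv @ normal) * normal
        ns = np.linalg.norm(sagittal)
        if ns < 1e-9:
            raise AmbiguousFrameError("dorsal-volar axis is parallel to the surface normal")
        sagittal = sagittal / ns
        coronal = ru - (ru @ normal) * normal - (ru @ sagittal) * sagittal
        nc = np.linalg.norm(coronal)
        if nc < 1e-9:
            raise AmbiguousFrameError("radial-ulnar axis degenerates after projection")
        coronal = coronal / nc
    else:
        if eigval[2] > 0 and (eigval[1] - eigval[0]) / eigval[2] < 1e-9:
            raise AmbiguousFrameError(
                "vertex PCA cannot separate the surface normal from an in-plane "
                "axis; supply a landmark orientation file"
            )
        sagittal = _canonical_sign(eigvec[:, 2])
        coronal = _canonical_sign(eigvec[:, 1])
        # re-orthogonalize against the (possibly flipped) normal
        sagittal = sagittal - (sagittal @ normal) * normal
        sagittal /= np.linalg.norm(sagittal)
        coronal = coronal - (coronal @ normal) * normal - (coronal @ sagittal) * sagittal
        coronal /= np.linalg.norm(coronal)

    handedness = 1 if np.cross(sagittal, coronal) @ normal >= 0 else -1
    normal = np.cross(sagittal, coronal) * handedness
    return AnatomicalFrame(origin, sagittal, coronal, normal, handedness)


# ---------------------------------------------------------------------------
# sphere fitting
# ---------------------------------------------------------------------------

def _check_not_coplanar(points: np.ndarray) -> None:
    centered = points - points.mean(axis=0)
    eigval = np.linalg.eigvalsh(centered.T @ centered / len(centered))
    if eigval[2] <= 0 or eigval[0] / eigval[2] < COPLANARITY_RATIO:
        raise CoplanarPointsError(
            "points are coplanar within tolerance; a sphere is unidentifiable"
        )


def algebraic_sphere(points: np.ndarray) -> tuple[np.ndarray, float]:
    """Linear least-squares sphere from ||p||^2 = 2 c.p + (r^2 - ||c||^2)."""
    A = np.column_stack([2.0 * points, np.ones(len(points))])
    b = (points**2).sum(axis=1)
    sol, *_ = np.linalg.lstsq(A, b, rcond=None)
    center = sol[:3]
    r2 = sol[3] + center @ center
    if r2 <= 0:
        raise CoplanarPointsError("algebraic sphere fit produced a non-positive radius")
    return center, float(np.sqrt(r2))


def fit_sphere(
    points: np.ndarray,
    mean_normal: np.ndarray | None = None,
    centroid: np.ndarray | None = None,
) -> SphereFit:
    """Geometric least-squares sphere: minimize sum (||p_i - c|| - r)^2.

    The algebraic linear solution seeds a damped Gauss-Newton refinement
    (step halving guarantees the objective never rises above the seed's).
    Iteration stops when the relative parameter change drops below 1e-10 or
    after 100 iterations (then ``converged`` is False).

    ``mean_normal``/``centroid`` (typically the facet's mean outward surface
    normal and its centroid) enable the concave/convex call; without them
    ``curvature_sense`` is None.
    """
    points = np.asarray(points, dtype=np.float64)
    if points.ndim != 2 or points.shape[1] != 3 or len(points) < 4:
        raise DegenerateInputError("sphere fit needs >= 4 three-dimensional points")
    _check_not_coplanar(points)

    center, radius = algebraic_sphere(points)
    x = np.array([*center, radius])

    def residuals(x: np.ndarray) -> np.ndarray:
        return np.linalg.norm(points - x[:3], axis=1) - x[3]

    res = residuals(x)
    sse = res @ res
    converged = False
    for _ in range(SPHERE_FIT_MAX_ITER):
        d = np.linalg.norm(points - x[:3], axis=1)
        d[d == 0] = 1e-300
        J = np.empty((len(points), 4))
        J[:, :3] = -(points - x[:3]) / d[:, None]
        J[:, 3] = -1.0
        step, *_ = np.linalg.lstsq(J, -res, rcond=None)
        alpha = 1.0
        while alpha > 1e-12:
            x_new = x + alpha * step
            res_new = residuals(x_new)
            sse_new = res_new @ res_new
            if sse_new <= sse:
                break
            alpha *= 0.5
        else:
            converged = True  # cannot descend further: at a minimum
            break
        moved = np.linalg.norm(alpha * step) / max(np.linalg.norm(x), 1.0)
        x, res, sse = x_new, res_new, sse_new
        if moved < SPHERE_FIT_RTOL:
            converged = True
            break

    center, radius = x[:3], float(abs(x[3]))
    abs_res = np.abs(res)
    mean_abs = float(abs_res.mean())
    rms = float(np.sqrt((res**2).mean()))

    sense = None
    if mean_normal is not None:
        ref = np.asarray(centroid if centroid is not None else points.mean(axis=0))
        sense = "concave" if (center - ref) @ np.asarray(mean_normal) > 0 else "convex"

    return SphereFit(
        center=center,
        radius=radius,
        mean_abs_error=mean_abs,
        mean_error_pct=mean_abs / radius,
        rms_error=rms,
        n_points=len(points),
        curvature_sense=sense,
        converged=converged,
    )


def point_sphere_residuals(points: np.ndarray, sphere: SphereFit) -> np.ndarray:
    """Signed orthogonal distances to the sphere surface (outside positive)."""
    points = np.asarray(points, dtype=np.float64)
    return np.linalg.norm(points - sphere.center, axis=1) - sphere.radius


# ---------------------------------------------------------------------------
# cross-sections and areas
# ---------------------------------------------------------------------------

def _chain_segments(segments: np.ndarray) -> list[np.ndarray]:
    """Chain (n, 2, 3) intersection segments into ordered polylines."""
    # quantize endpoints so shared triangle edges match exactly
    scale = max(np.abs(segments).max(), 1.0)
    quant = np.round(segments / scale, decimals=9)
    flat = quant.reshape(-1, 3)
    uniq, inverse = np.unique(flat, axis=0, return_inverse=True)
    edges = inverse.reshape(-1, 2)
    coords = segments.reshape(-1, 3)
    # representative coordinate per node: first occurrence
    rep = np.zeros((len(uniq), 3))
    seen = np.zeros(len(uniq), dtype=bool)
    for idx, node in enumerate(inverse):
        if not seen[node]:
            rep[node] = coords[idx]
            seen[node] = True

    adjacency: dict[int, list[int]] = {}
    for a, b in edges:
        if a == b:
            continue
        adjacency.setdefault(int(a), []).append(int(b))
        adjacency.setdefault(int(b), []).append(int(a))
    if not adjacency:
        raise DegenerateSectionError("plane grazes the mesh: only isolated points")

    visited_edges: set[frozenset[int]] = set()
    polylines: list[np.ndarray] = []
    # open chains first (degree-1 endpoints), then any remaining loops
    endpoints = sorted(n for n, nb in adjacency.items() if len(nb) == 1)
    starts = endpoints + sorted(adjacency)
    for start in starts:
        path = [start]
        node = start
        while True:
            nxt = None
            for cand in sorted(adjacency[node]):
                e = frozenset((node, cand))
                if e not in visited_edges and node != cand:
                    nxt = cand
                    visited_edges.add(e)
                    break
            if nxt is None:
                break
            path.append(nxt)
            node = nxt
        if len(path) > 1:
            polylines.append(rep[path])
    if not polylines:
        raise DegenerateSectionError("plane grazes the mesh: only isolated points")
    return polylines


def cross_section(
    mesh: TriangleMesh, plane_point: np.ndarray, plane_normal: np.ndarray
) -> CrossSection:
    """Cut the mesh with a plane; return the longest connected polyline.

    Triangle-plane intersection segments are chained end to end; when
    several disconnected polylines result, the one with the greatest arc
    length wins (ties broken by chaining order, which is deterministic).
    """
    plane_point = np.asarray(plane_point, dtype=np.float64)
    plane_normal = np.asarray(plane_normal, dtype=np.float64)
    plane_normal = plane_normal / np.linalg.norm(plane_normal)
    segments = trimesh.intersections.mesh_plane(mesh.to_trimesh(), plane_normal, plane_point)
    if len(segments) == 0:
        raise NoIntersectionError("cutting plane does not intersect the mesh")
    lengths = np.linalg.norm(segments[:, 1] - segments[:, 0], axis=1)
    segments = segments[lengths > 1e-12]
    if len(segments) == 0:
        raise DegenerateSectionError("plane grazes the mesh: only isolated points")
    polylines = _chain_segments(np.asarray(segments, dtype=np.float64))
    best = max(
        range(len(polylines)),
        key=lambda i: np.linalg.norm(np.diff(polylines[i], axis=0), axis=1).sum(),
    )
    return CrossSection(polylines[best], plane_point, plane_normal)


def surface_area(mesh: TriangleMesh) -> float:
    """Total triangle area in mm^2."""
    return float(mesh.face_areas().sum())


# ---------------------------------------------------------------------------
# circles, angles, planes
# ---------------------------------------------------------------------------

def three_point_roc(p1: np.ndarray, p2: np.ndarray, p3: np.ndarray) -> float:
    """Radius of the circle through three points: R = abc / (4K)."""
    p1, p2, p3 = (np.asarray(p, dtype=np.float64) for p in (p1, p2, p3))
    a = np.linalg.norm(p2 - p3)
    b = np.linalg.norm(p1 - p3)
    c = np.linalg.norm(p1 - p2)
    area = 0.5 * np.linalg.norm(np.cross(p2 - p1, p3 - p1))
    if area < 1e-12:
        raise CollinearPointsError("three points are collinear; circle radius undefined")
    return float(a * b * c / (4.0 * area))


def angle_between(
    u: np.ndarray, v: np.ndarray, plane_normal: np.ndarray | None = None
) -> float:
    """Angle between two vectors in degrees, in [0, 180].

    With ``plane_normal`` given, both vectors are first projected onto that
    plane (this is how mid-coronal-plane angles are measured).
    """
    u = np.asarray(u, dtype=np.float64)
    v = np.asarray(v, dtype=np.float64)
    if plane_normal is not None:
        n = np.asarray(plane_normal, dtype=np.float64)
        n = n / np.linalg.norm(n)
        u = u - (u @ n) * n
        v = v - (v @ n) * n
    nu, nv = np.linalg.norm(u), np.linalg.norm(v)
    if nu < 1e-12 or nv < 1e-12:
        raise UndefinedAngleError("angle undefined for a zero vector (possibly after projection)")
    # atan2 form is numerically exact near 0 and 180 degrees
    return float(np.degrees(np.arctan2(np.linalg.norm(np.cross(u, v)), u @ v)))


def fit_plane(points: np.ndarray) -> tuple[np.ndarray, np.ndarray, float]:
    """Total-least-squares plane: (centroid, unit normal, rms distance)."""
    points = np.asarray(points, dtype=np.float64)
    if points.ndim != 2 or points.shape[1] != 3 or len(points) < 3:
        raise DegenerateInputError("plane fit needs >= 3 three-dimensional points")
    centroid = points.mean(axis=0)
    centered = points - centroid
    cov = centered.T @ centered / len(centered)
    eigval, eigvec = np.linalg.eigh(cov)
    if eigval[1] <= max(eigval[2], 1e-300) * 1e-12:
        raise CollinearPointsError("points are collinear; plane undefined")
    normal = _canonical_sign(eigvec[:, 0])
    rms = float(np.sqrt(np.maximum(eigval[0], 0.0)))
    return centroid, normal, rms


def fit_line(points: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Total-least-squares line: (centroid, unit direction)."""
    points = np.asarray(points, dtype=np.float64)
    if len(points) < 2:
        raise DegenerateInputError("line fit needs >= 2 points")
    centroid = points.mean(axis=0)
    centered = points - centroid
    _, _, vt = np.linalg.svd(centered, full_matrices=False)
    return centroid, _canonical_sign(vt[0])
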