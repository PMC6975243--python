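"""Ground-truthed synthetic articular surfaces.

The laser-scanned facet patches behind the published measurements were
never deposited, so this module generates stand-ins with known geometry:

* spherical caps (optionally elongated so length exceeds width, as the
  published facets are) for single-condyle surfaces,
* the outer union of two overlapping spheres for bicondylar surfaces, with
  the requested divergence angle and ulnar area fraction hit by internal
  calibration,
* caps whose dorsal portion is replaced by its tangent plane, emulating
  the dorsally flattened fourth-carpometacarpal facets,
* planar facet pairs at a known dihedral for inter-facet angle tests, and
* a whole simulated study cohort.

Noise is radial Gaussian displacement along the vertex normal with a
default standard deviation of 0.1 mm, modelling the scanner's stated
±100 µm depth accuracy.  Every vertex of a noise-free surface lies exactly
on its generating sphere (or plane), so fits can be checked against exact
ground truth.  All randomness flows through a single seeded generator:
identical spec + seed gives bit-identical output.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from typing import Any

import numpy as np
from scipy.optimize import brentq
from scipy.spatial import Delaunay

from . import geom_core
from .errors import InfeasibleSpecError, ValidationError
from .mesh_io import TriangleMesh

GENERATOR_VERSION = "facetmorph-synth-1"

#: default target edge length, mm
DEFAULT_RESOLUTION = 0.15
#: default radial noise sd, mm (scanner ±100 µm read as one sd)
DEFAULT_NOISE_SD = 0.1
#: default boundary elongation along the sagittal axis
DEFAULT_ELONGATION = 1.6


@dataclass
class CapSpec:
    """Specification of a (possibly elongated) spherical-cap facet."""

    radius: float                      # mm
    cap_angle: float = 60.0            # degrees, half-angle of the cap
    resolution: float = DEFAULT_RESOLUTION
    noise_sd: float = DEFAULT_NOISE_SD
    sense: str = "convex"              # {"concave", "convex"}
    elongation: float = DEFAULT_ELONGATION
    seed: int = 0

    def validate(self) -> None:
        if not self.radius > 0:
            raise ValidationError("cap radius must be positive")
        if not 0 < self.cap_angle <= 90:
            raise ValidationError("cap_angle must be in (0, 90] degrees")
        if self.noise_sd < 0:
            raise ValidationError("noise_sd must be non-negative")
        if not self.resolution > 0:
            raise ValidationError("resolution must be positive")
        if self.elongation < 1:
            raise ValidationError("elongation must be >= 1")
        if self.sense not in {"concave", "convex"}:
            raise ValidationError("sense must be 'concave' or 'convex'")


@dataclass
class BicondylarSpec:
    """Specification of a two-sphere (bicondylar) facet."""

    radial_radius: float               # mm
    ulnar_radius: float                # mm
    divergence: float = 21.4           # degrees, between condylar center rays
    ulnar_area_target: float = 30.0    # percent of total facet area
    overlap: float = 0.5               # ridge blend width, mm (mesh-resolution scale)
    noise_sd: float = DEFAULT_NOISE_SD
    resolution: float = DEFAULT_RESOLUTION
    sense: str = "convex"
    seed: int = 0

    def validate(self) -> None:
        if not (self.radial_radius > 0 and self.ulnar_radius > 0):
            raise ValidationError("both condylar radii must be positive")
        if not 0 <= self.divergence < 90:
            raise ValidationError("divergence must be in [0, 90) degrees")
        if not 5 < self.ulnar_area_target < 95:
            raise ValidationError("ulnar_area_target must be in (5, 95) percent")
        if self.noise_sd < 0 or self.resolution <= 0:
            raise ValidationError("noise_sd >= 0 and resolution > 0 required")
        if self.sense not in {"concave", "convex"}:
            raise ValidationError("sense must be 'concave' or 'convex'")


@dataclass
class GroundTruth:
    """What the generator knows about an emitted surface."""

    spec: Any
    analytic_area: float = 0.0
    condyle_labels: np.ndarray | None = None   # per-vertex: 0 radial, 1 ulnar
    flat_vertices: np.ndarray | None = None    # indices of flattened vertices
    version: str = GENERATOR_VERSION
    extras: dict = field(default_factory=dict)


# ---------------------------------------------------------------------------
# spherical caps
# ---------------------------------------------------------------------------

def _ellipse_perimeter(a: float, b: float) -> float:
    # Ramanujan's approximation; exact enough to size sampling rings
    h = ((a - b) / (a + b)) ** 2 if (a + b) > 0 else 0.0
    return math.pi * (a + b) * (1 + 3 * h / (10 + math.sqrt(4 - 3 * h)))


def _cap_vertices(spec: CapSpec) -> tuple[np.ndarray, np.ndarray]:
    """Sample the cap in angle space; return (param2d, xyz on sphere)."""
    theta_c = math.radians(spec.cap_angle)
    R, e = spec.radius, spec.elongation
    n_rings = max(3, int(round(R * theta_c / spec.resolution)))
    params = [np.zeros((1, 2))]
    for i in range(1, n_rings + 1):
        t = i / n_rings
        a, b = e * theta_c * t, theta_c * t
        m = max(6, int(math.ceil(_ellipse_perimeter(R * a, R * b) / spec.resolution)))
        psi = 2 * math.pi * np.arange(m) / m + 0.35 * i  # stagger rings
        params.append(np.column_stack([a * np.cos(psi), b * np.sin(psi)]))
    param = np.vstack(params)
    theta = np.hypot(param[:, 0], param[:, 1])
    phi = np.arctan2(param[:, 1], param[:, 0])
    xyz = R * np.column_stack(
        [np.sin(theta) * np.cos(phi), np.sin(theta) * np.sin(phi), np.cos(theta)]
    )
    return param, xyz


def _orient_outward(vertices: np.ndarray, faces: np.ndarray, outward_ref: np.ndarray) -> np.ndarray:
    """Fix triangle winding so normals point along per-face reference."""
    tri = vertices[faces]
    normals = np.cross(tri[:, 1] - tri[:, 0], tri[:, 2] - tri[:, 0])
    flip = (normals * outward_ref[faces].mean(axis=1)).sum(axis=1) < 0
    faces = faces.copy()
    faces[flip] = faces[flip][:, [0, 2, 1]]
    return faces


def generate_cap(spec: CapSpec) -> tuple[TriangleMesh, GroundTruth]:
    """Triangulated spherical cap, pole on +z, sagittal (long) axis = x.

    The cap is sampled on concentric rings in angle space; elongation
    stretches the sampled region along x *in angle space* and points are
    mapped back onto the sphere, so every vertex stays exactly at distance
    ``radius`` from the origin and the ROC ground truth is exact.  Radial
    Gaussian noise (sd ``noise_sd``) is then applied along vertex normals.
    """
    spec.validate()
    param, xyz = _cap_vertices(spec)
    if len(xyz) < 50:
        raise ValidationError(
            f"resolution {spec.resolution} mm yields only {len(xyz)} vertices; "
            "refine the resolution or enlarge the cap"
        )
    tri = Delaunay(param)
    faces = np.asarray(tri.simplices, dtype=np.int64)
    # outward = radial direction (sphere centered at origin)
    faces = _orient_outward(xyz, faces, xyz / spec.radius)

    rng = np.random.default_rng(spec.seed)
    if spec.noise_sd > 0:
        offsets = rng.normal(0.0, spec.noise_sd, len(xyz))
        xyz = xyz * (1.0 + offsets / spec.radius)[:, None]

    if spec.sense == "concave":
        faces = faces[:, [0, 2, 1]]  # normals toward the sphere center

    theta_c = math.radians(spec.cap_angle)
    analytic = 2 * math.pi * spec.radius**2 * (1 - math.cos(theta_c))
    mesh = TriangleMesh(xyz, faces, name=f"cap_r{spec.radius:g}")
    truth = GroundTruth(
        spec=spec,
        analytic_area=analytic,
        extras={"center": np.zeros(3), "radius": spec.radius},
    )
    return mesh, truth


def generate_flattened_cap(
    spec: CapSpec, flat_fraction: float = 0.4
) -> tuple[TriangleMesh, GroundTruth]:
    """Cap whose dorsal portion is collapsed onto its tangent plane.

    The dorsal ``flat_fraction`` of vertices (ranked by sagittal/x
    coordinate) is orthogonally projected onto the plane tangent to the
    sphere at the flattened region's central direction.  The generator then
    verifies that the emitted surface's best single-sphere mean absolute
    error exceeds 0.25 mm — the flattening criterion used downstream —
    increasing ``flat_fraction`` in 0.05 steps if needed and failing at 0.8.
    Noise is applied after flattening.
    """
    spec.validate()
    if not 0.1 < flat_fraction < 0.8:
        raise ValidationError("flat_fraction must be in (0.1, 0.8)")

    base_spec = CapSpec(**{**asdict(spec), "noise_sd": 0.0})
    mesh0, _ = generate_cap(base_spec)

    frac = flat_fraction
    while True:
        xyz = mesh0.vertices.copy()
        cut = np.quantile(xyz[:, 0], 1.0 - frac)
        flat_idx = np.flatnonzero(xyz[:, 0] >= cut)
        center_dir = xyz[flat_idx].mean(axis=0)
        center_dir /= np.linalg.norm(center_dir)
        anchor = spec.radius * center_dir
        d = (xyz[flat_idx] - anchor) @ center_dir
        xyz[flat_idx] = xyz[flat_idx] - d[:, None] * center_dir

        fit = geom_core.fit_sphere(xyz)
        if fit.mean_abs_error > 0.25:
            break
        frac += 0.05
        if frac >= 0.8:
            raise InfeasibleSpecError(
                "flattened cap cannot reach the 0.25 mm mean-error criterion "
                f"within flat_fraction bounds (radius {spec.radius} mm, "
                f"cap angle {spec.cap_angle} deg)"
            )

    rng = np.random.default_rng(spec.seed)
    if spec.noise_sd > 0:
        # noise along the (pre-noise) vertex normals of the flattened surface
        tmp = TriangleMesh(xyz, mesh0.faces)
        normals = tmp.vertex_normals()
        xyz = xyz + rng.normal(0.0, spec.noise_sd, len(xyz))[:, None] * normals

    faces = mesh0.faces
    if spec.sense == "concave":
        faces = faces[:, [0, 2, 1]]
    mesh = TriangleMesh(xyz, faces, name=f"flatcap_r{spec.radius:g}")
    theta_c = math.radians(spec.cap_angle)
    truth = GroundTruth(
        spec=spec,
        analytic_area=2 * math.pi * spec.radius**2 * (1 - math.cos(theta_c)),
        flat_vertices=flat_idx,
        extras={
            "flat_fraction_used": frac,
            "noise_free_mean_abs_error": fit.mean_abs_error,
            "radius": spec.radius,
        },
    )
    return mesh, truth


# ---------------------------------------------------------------------------
# bicondylar surfaces
# ---------------------------------------------------------------------------

class _TwoSphereField:
    """Outer (max-height) union of two spheres with equal apex height."""

    #: rim trim: points where the surface slope exceeds acos(TRIM) from
    #: vertical are excluded (avoids near-degenerate rim triangles); the
    #: same rule is used for calibration and for meshing so the two agree.
    TRIM = 0.25

    def __init__(self, r_r: float, r_u: float, beta_r: float, beta_u: float,
                 separation: float, dz: float = 0.0):
        self.r = np.array([r_r, r_u])
        self.rho = self.r * np.sin(np.radians([beta_r, beta_u]))
        self.rho = np.minimum(self.rho, self.r * math.sqrt(1 - self.TRIM**2))
        share = self.rho / self.rho.sum()
        # centers along the coronal (y) axis; radial negative, ulnar positive
        self.cy = np.array([-separation * share[0], separation * share[1]])
        # apexes at z = 0; dz sinks the ulnar sphere, pushing the ridge
        # ulnar-ward so the ulnar patch sits off-apex (steeper divergence)
        self.cz = np.array([-r_r, -r_u - dz])

    def in_disk(self, x: np.ndarray, y: np.ndarray, k: int) -> np.ndarray:
        return x**2 + (y - self.cy[k]) ** 2 <= self.rho[k] ** 2

    def evaluate(self, x: np.ndarray, y: np.ndarray):
        """(z, label, valid) of the outer surface; label 0 radial / 1 ulnar."""
        z = np.full((2,) + np.shape(x), np.nan)
        for k in range(2):
            q = self.r[k] ** 2 - x**2 - (y - self.cy[k]) ** 2
            ok = self.in_disk(x, y, k) & (q > 0)
            zk = np.full(np.shape(x), np.nan)
            zk[ok] = self.cz[k] + np.sqrt(q[ok])
            z[k] = zk
        label = np.where(np.isnan(z[0]), 1,
                         np.where(np.isnan(z[1]), 0, (z[1] > z[0]).astype(int)))
        zs = np.where(label == 0, z[0], z[1])
        valid = np.isfinite(zs)
        # trim the steep rim of whichever sphere owns the point
        for k in range(2):
            q = self.r[k] ** 2 - x**2 - (y - self.cy[k]) ** 2
            valid &= ~((label == k) & (q < (self.TRIM * self.r[k]) ** 2))
        return zs, label, valid

    def grid_metrics(self, h: float, erode: float = 0.0) -> dict:
        """Area fractions and divergence on a numeric grid (no meshing).

        ``erode`` shrinks each region's outer boundary by that many mm,
        mimicking the half-cell rim that triangulation at a finite
        resolution cannot represent.
        """
        pad = 1e-9
        xmax = self.rho.max()
        ymin, ymax = self.cy[0] - self.rho[0], self.cy[1] + self.rho[1]
        x = np.arange(-xmax, xmax + pad, h)
        y = np.arange(ymin, ymax + pad, h)
        X, Y = np.meshgrid(x, y, indexing="ij")
        z, label, valid = self.evaluate(X, Y)
        if erode > 0:
            for k in range(2):
                d = np.hypot(X, Y - self.cy[k])
                limit = min(self.rho[k], self.r[k] * math.sqrt(1 - self.TRIM**2))
                valid &= ~((label == k) & (d > limit - erode))

        out = {"area": np.zeros(2), "centroid": np.zeros((2, 3))}
        for k in range(2):
            m = valid & (label == k)
            if not m.any():
                out["area"][k] = 0.0
                continue
            q = self.r[k] ** 2 - X[m] ** 2 - (Y[m] - self.cy[k]) ** 2
            w = self.r[k] / np.sqrt(np.maximum(q, 1e-12))  # surface area element
            out["area"][k] = (w).sum() * h * h
            pts = np.column_stack([X[m], Y[m], z[m]])
            out["centroid"][k] = (pts * w[:, None]).sum(axis=0) / w.sum()
        return out

    def divergence_of(self, metrics: dict) -> float:
        rays = []
        for k in range(2):
            c = np.array([0.0, self.cy[k], self.cz[k]])
            ray = metrics["centroid"][k] - c
            rays.append(np.array([ray[1], ray[2]]))  # project out sagittal x
        u, v = rays
        cosang = np.clip(
            (u @ v) / (np.linalg.norm(u) * np.linalg.norm(v)), -1.0, 1.0
        )
        return float(np.degrees(np.arccos(cosang)))


def _calibrate_two_spheres(
    spec: BicondylarSpec, d_target: float, a_target: float
) -> _TwoSphereField:
    """Find separation and ulnar cap angle hitting divergence + area targets.

    Works on the continuous height field (cheap numeric grid, no meshing):
    separation is root-found for the divergence, then the ulnar cap angle
    is root-found for the area fraction, alternating until both hold; the
    radial cap angle is widened stepwise when the divergence is out of
    reach.
    """
    h_cal = max(min(spec.radial_radius, spec.ulnar_radius) / 45.0, 0.05)
    erode = 0.5 * spec.resolution

    def build(beta_r: float, beta_u: float, sep: float, dz: float) -> _TwoSphereField:
        return _TwoSphereField(spec.radial_radius, spec.ulnar_radius,
                               beta_r, beta_u, sep, dz=dz)

    def divergence(beta_r, beta_u, sep, dz):
        f = build(beta_r, beta_u, sep, dz)
        return f.divergence_of(f.grid_metrics(h_cal, erode=erode))

    def ulnar_pct(beta_r, beta_u, sep, dz):
        m = build(beta_r, beta_u, sep, dz).grid_metrics(h_cal, erode=erode)
        return 100.0 * m["area"][1] / m["area"].sum()

    r_u = spec.ulnar_radius
    ladder = [(55.0, 0.0), (63.0, 0.0), (70.0, 0.0), (76.0, 0.0),
              (76.0, 0.08 * r_u), (76.0, 0.16 * r_u), (76.0, 0.28 * r_u)]
    for beta_r, dz in ladder:
        beta_u = min(beta_r, 60.0)
        sep = None
        ok = False
        for _ in range(8):
            rho_sum = (spec.radial_radius * math.sin(math.radians(beta_r))
                       + spec.ulnar_radius * math.sin(math.radians(beta_u)))
            lo, hi = 0.08 * rho_sum, 0.995 * rho_sum
            try:
                f_lo = divergence(beta_r, beta_u, lo, dz) - d_target
                f_hi = divergence(beta_r, beta_u, hi, dz) - d_target
            except (ValueError, ZeroDivisionError):
                break
            if f_lo < 0:
                break  # even tight overlap cannot diverge this much: widen beta_r
            sep = hi if f_hi > 0 else brentq(
                lambda s: divergence(beta_r, beta_u, s, dz) - d_target,
                lo, hi, xtol=2e-3 * rho_sum)
            # area: root-find the ulnar cap angle
            g = lambda b: ulnar_pct(beta_r, b, sep, dz) - a_target
            b_lo, b_hi = 12.0, 85.0
            g_lo, g_hi = g(b_lo), g(b_hi)
            if g_lo > 0 or g_hi < 0:
                beta_u = b_lo if g_lo > 0 else b_hi
            else:
                beta_u = brentq(g, b_lo, b_hi, xtol=0.05)
            d_err = abs(divergence(beta_r, beta_u, sep, dz) - d_target)
            a_err = abs(ulnar_pct(beta_r, beta_u, sep, dz) - a_target)
            if d_err < 0.25 and a_err < 1.0:
                ok = True
                break
        if ok:
            return build(beta_r, beta_u, sep, dz)
    raise InfeasibleSpecError(
        f"cannot realize divergence {d_target:.2f} deg with ulnar area "
        f"{a_target:.2f}% for radii "
        f"{spec.radial_radius}/{spec.ulnar_radius} mm"
    )


def _mesh_two_sphere_field(
    f: _TwoSphereField, resolution: float
) -> tuple[TriangleMesh, np.ndarray, np.ndarray]:
    """Triangulate the outer union surface; returns (mesh, labels, centers)."""
    h = resolution
    xmax = f.rho.max()
    ymin, ymax = f.cy[0] - f.rho[0], f.cy[1] + f.rho[1]
    gx = np.arange(-xmax, xmax + 1e-9, h)
    gy = np.arange(ymin, ymax + 1e-9, h)
    X, Y = np.meshgrid(gx, gy, indexing="ij")
    z, label, keep = f.evaluate(X, Y)
    pts2d = np.column_stack([X[keep], Y[keep]])
    if len(pts2d) < 50:
        raise InfeasibleSpecError("bicondylar spec yields too few vertices; refine resolution")
    zv = z[keep]
    labels = label[keep].astype(np.int64)

    tri = Delaunay(pts2d)
    faces = np.asarray(tri.simplices, dtype=np.int64)
    # drop sliver triangles bridging the non-convex waist of the domain
    cent = pts2d[faces].mean(axis=1)
    _, _, inside = f.evaluate(cent[:, 0], cent[:, 1])
    edge = pts2d[faces]
    elen = np.stack([
        np.linalg.norm(edge[:, 0] - edge[:, 1], axis=1),
        np.linalg.norm(edge[:, 1] - edge[:, 2], axis=1),
        np.linalg.norm(edge[:, 0] - edge[:, 2], axis=1),
    ]).max(axis=0)
    faces = faces[inside & (elen < 3.0 * h)]

    xyz = np.column_stack([pts2d, zv])
    centers = np.stack([[0.0, f.cy[k], f.cz[k]] for k in range(2)])
    radial_dirs = xyz - centers[labels]
    radial_dirs /= np.linalg.norm(radial_dirs, axis=1, keepdims=True)
    faces = _orient_outward(xyz, faces, radial_dirs)

    # drop vertices orphaned by the triangle filter
    used = np.unique(faces)
    remap = np.zeros(len(xyz), dtype=np.int64)
    remap[used] = np.arange(len(used))
    mesh = TriangleMesh(xyz[used], remap[faces], name="bicondylar")
    return mesh, labels[used], centers


def _true_divergence(centers, face_labels, areas, cents) -> float:
    rays = []
    for k in range(2):
        m = face_labels == k
        w = areas[m]
        centroid = (cents[m] * w[:, None]).sum(axis=0) / w.sum()
        ray = centroid - centers[k]
        rays.append(np.array([ray[1], ray[2]]))
    u, v = rays
    cosang = np.clip((u @ v) / (np.linalg.norm(u) * np.linalg.norm(v)), -1, 1)
    return float(np.degrees(np.arccos(cosang)))


def _mesh_truth(mesh: TriangleMesh, labels: np.ndarray, centers: np.ndarray):
    """(divergence, ulnar area %, per-face labels) of a constructed mesh."""
    face_votes = labels[mesh.faces].sum(axis=1)
    face_labels = (face_votes >= 2).astype(np.int64)
    areas = mesh.face_areas()
    ulnar_pct = float(100.0 * areas[face_labels == 1].sum() / areas.sum())
    div = _true_divergence(centers, face_labels, areas, mesh.face_centroids())
    return div, ulnar_pct, face_labels


def generate_bicondylar(spec: BicondylarSpec) -> tuple[TriangleMesh, GroundTruth]:
    """Bicondylar facet: outer union of two overlapping spheres.

    The two spheres sit side by side along the coronal (y) axis with their
    apexes at equal height; the visible surface takes the higher sphere at
    each point, so the condyles meet along the sphere-intersection ridge.
    Center separation is calibrated so the rays from each sphere center
    through its region's centroid subtend the requested divergence in the
    coronal-normal plane, and the ulnar cap angle is calibrated to the
    requested ulnar area fraction; after a fast continuous calibration the
    targets are corrected against the actual triangulation until the meshed
    surface realizes them.  Every noise-free vertex lies exactly on its
    generating sphere.
    """
    spec.validate()
    d_t, a_t = spec.divergence, spec.ulnar_area_target
    best = None
    damp = 0.6  # under-relaxed target correction; full steps oscillate
    for _ in range(10):
        f = _calibrate_two_spheres(spec, d_t, a_t)
        mesh0, labels, centers = _mesh_two_sphere_field(f, spec.resolution)
        div_m, pct_m, face_labels = _mesh_truth(mesh0, labels, centers)
        d_err = abs(div_m - spec.divergence)
        a_err = abs(pct_m - spec.ulnar_area_target)
        if best is None or d_err + 0.3 * a_err < best[0] + 0.3 * best[1]:
            best = (d_err, a_err, mesh0, labels, centers, div_m, pct_m, face_labels)
        if d_err < 0.35 and a_err < 1.0:
            break
        d_t = float(np.clip(d_t + damp * (spec.divergence - div_m), 0.0, 85.0))
        a_t = float(np.clip(a_t + damp * (spec.ulnar_area_target - pct_m), 6.0, 94.0))
    d_err, a_err, mesh0, labels, centers, div_m, pct_m, face_labels = best
    if d_err > 2.0 or a_err > 2.5:
        raise InfeasibleSpecError(
            f"bicondylar calibration stalled: divergence off by {d_err:.2f} deg, "
            f"ulnar area by {a_err:.2f} points"
        )

    rng = np.random.default_rng(spec.seed)
    verts = mesh0.vertices
    if spec.noise_sd > 0:
        dirs = verts - centers[labels]
        dirs /= np.linalg.norm(dirs, axis=1, keepdims=True)
        verts = verts + rng.normal(0.0, spec.noise_sd, len(verts))[:, None] * dirs
    fcs = mesh0.faces
    if spec.sense == "concave":
        fcs = fcs[:, [0, 2, 1]]
    mesh = TriangleMesh(verts, fcs, name="bicondylar")

    truth = GroundTruth(
        spec=spec,
        analytic_area=float(mesh0.face_areas().sum()),
        condyle_labels=labels,
        extras={
            "centers": centers,
            "radii": np.array([spec.radial_radius, spec.ulnar_radius]),
            "ulnar_area_fraction": pct_m,
            "divergence": div_m,
            "face_labels": face_labels,
        },
    )
    return mesh, truth


# ---------------------------------------------------------------------------
# planar facet pairs (inter-facet angle fixtures)
# ---------------------------------------------------------------------------

def generate_interfacet_pair(
    angle: float,
    length: float = 12.0,
    width: float = 7.0,
    gap: float = 0.4,
    resolution: float = 0.3,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> tuple[TriangleMesh, TriangleMesh]:
    """Two planar rectangular facets meeting at a known dihedral.

    Both span the sagittal (x) axis; facet A lies flat on +y, facet B on -y
    rotated by ``angle`` degrees about the sagittal axis, so a mid-coronal
    cross-section (plane normal = x) cuts both and their section lines
    subtend ``angle``.
    """
    rng = np.random.default_rng(seed)

    def rect(y0: float, y1: float, name: str) -> TriangleMesh:
        nx = max(2, int(round(length / resolution)))
        ny = max(2, int(round(abs(y1 - y0) / resolution)))
        xs = np.linspace(-length / 2, length / 2, nx)
        ys = np.linspace(y0, y1, ny)
        X, Y = np.meshgrid(xs, ys, indexing="ij")
        V = np.column_stack([X.ravel(), Y.ravel(), np.zeros(X.size)])
        faces = []
        for i in range(nx - 1):
            for j in range(ny - 1):
                a = i * ny + j
                b = (i + 1) * ny + j
                faces.append([a, b, a + 1])
                faces.append([b, b + 1, a + 1])
        return TriangleMesh(V, np.asarray(faces, dtype=np.int64), name=name)

    mesh_a = rect(gap, gap + width, "facet_a")
    mesh_b = rect(-(gap + width), -gap, "facet_b")
    # tilt facet B about the sagittal (x) axis
    alpha = math.radians(angle)
    rot = np.array(
        [[1, 0, 0],
         [0, math.cos(alpha), -math.sin(alpha)],
         [0, math.sin(alpha), math.cos(alpha)]]
    )
    mesh_b = TriangleMesh(mesh_b.vertices @ rot.T, mesh_b.faces, name="facet_b")
    if noise_sd > 0:
        for m in (mesh_a, mesh_b):
            normals = m.vertex_normals()
            m.vertices += rng.normal(0.0, noise_sd, m.n_vertices)[:, None] * normals
    return mesh_a, mesh_b


# ---------------------------------------------------------------------------
# study cohort
# ---------------------------------------------------------------------------

#: printed measurement envelopes used for cohort draws (mm, mm^2, deg, %)
COHORT_RANGES = {
    "hamate4_roc": (4.12, 21.07),
    "mc4_roc": (4.59, 19.82),
    "hamate4_area": (63.02, 89.32),
    "mc4_area": (53.37, 115.23),
    "hamate5_radial_roc": (5.99, 10.82),
    "hamate5_ulnar_roc": (7.75, 18.74),
    "mc5_radial_roc": (6.03, 8.85),
    "mc5_ulnar_roc": (5.71, 12.01),
    "hamate5_divergence": (14.3, 35.9),
    "mc5_divergence": (2.0, 18.7),
    "hamate5_ulnar_pct": (19.0, 51.14),
    "mc5_ulnar_pct": (18.9, 43.59),
    "imf4_roc": (6.97, 19.2),
    "imf5_roc": (7.9, 18.37),
}

FLATTENING_PREVALENCE = 0.6  # six of ten specimens


def _cap_angle_for_area(radius: float, area: float,
                        lo: float = 12.0, hi: float = 75.0,
                        elongation: float = DEFAULT_ELONGATION) -> float:
    """Half-angle giving a cap of the requested area, clamped to [lo, hi].

    The sampled region is stretched by ``elongation`` along the sagittal
    axis, which scales its area by roughly that factor; the half-angle is
    solved for the unstretched-equivalent area so the emitted facet's area
    lands near the request.
    """
    c = 1.0 - area / elongation / (2 * math.pi * radius**2)
    if c <= -1:
        return hi
    theta = math.degrees(math.acos(max(min(c, 1.0), -1.0)))
    return float(min(max(theta, lo), hi))


def generate_study_cohort(
    n_specimens: int,
    seed: int,
    noise_sd: float = DEFAULT_NOISE_SD,
    resolution: float = 0.25,
) -> list[dict]:
    """Simulate a study cohort of facet meshes with a ground-truth record.

    Each specimen gets: a fourth-carpometacarpal pair (concave hamate cap —
    dorsally flattened in 60% of specimens, convex metacarpal-base cap), a
    bicondylar fifth-carpometacarpal pair, and an intermetacarpal facet
    pair, with generating parameters drawn uniformly from the published
    measurement envelopes.  Deterministic per seed.  Returns one dict per
    facet: specimen, role, mesh, truth and the drawn parameters.
    """
    if n_specimens < 1:
        raise ValidationError("need at least one specimen")
    rng = np.random.default_rng(seed)
    n_flat = int(round(FLATTENING_PREVALENCE * n_specimens))
    records: list[dict] = []

    def draw(key: str) -> float:
        lo, hi = COHORT_RANGES[key]
        return float(rng.uniform(lo, hi))

    for s in range(n_specimens):
        sid = f"S{s + 1:02d}"
        flattened = s < n_flat
        sub = int(rng.integers(0, 2**31 - 1))

        # fourth CMC: hamate concave / MC base convex caps
        for role, rkey, akey, sense in (
            ("hamate4", "hamate4_roc", "hamate4_area", "concave"),
            ("mc4", "mc4_roc", "mc4_area", "convex"),
        ):
            for attempt in range(20):
                radius = draw(rkey)
                angle = _cap_angle_for_area(radius, draw(akey))
                spec = CapSpec(radius=radius, cap_angle=angle, resolution=resolution,
                               noise_sd=noise_sd, sense=sense,
                               seed=(sub + attempt) % (2**31 - 1))
                try:
                    if role == "hamate4" and flattened:
                        mesh, truth = generate_flattened_cap(spec)
                    else:
                        mesh, truth = generate_cap(spec)
                    break
                except (InfeasibleSpecError, ValidationError):
                    continue
            else:
                raise InfeasibleSpecError(f"{sid}/{role}: no feasible cap after 20 draws")
            records.append({
                "specimen": sid, "role": role, "mesh": mesh, "truth": truth,
                "true_roc": spec.radius, "flattened": role == "hamate4" and flattened,
            })

        # fifth CMC: bicondylar pair
        for role, rrk, urk, dvk, upk, sense in (
            ("hamate5", "hamate5_radial_roc", "hamate5_ulnar_roc",
             "hamate5_divergence", "hamate5_ulnar_pct", "concave"),
            ("mc5", "mc5_radial_roc", "mc5_ulnar_roc",
             "mc5_divergence", "mc5_ulnar_pct", "convex"),
        ):
            for attempt in range(20):
                spec = BicondylarSpec(
                    radial_radius=draw(rrk), ulnar_radius=draw(urk),
                    divergence=draw(dvk), ulnar_area_target=draw(upk),
                    noise_sd=noise_sd, resolution=resolution, sense=sense,
                    seed=(sub + 1000 + attempt) % (2**31 - 1),
                )
                try:
                    mesh, truth = generate_bicondylar(spec)
                    break
                except (InfeasibleSpecError, ValidationError):
                    continue
            else:
                raise InfeasibleSpecError(f"{sid}/{role}: no feasible bicondylar after 20 draws")
            records.append({
                "specimen": sid, "role": role, "mesh": mesh, "truth": truth,
                "true_radial_roc": spec.radial_radius,
                "true_ulnar_roc": spec.ulnar_radius,
                "true_divergence": truth.extras["divergence"],
                "true_ulnar_area_pct": truth.extras["ulnar_area_fraction"],
            })

        # intermetacarpal facet pair: shallow caps measured by 3-point ROC
        for role, rkey, sense in (("imf4", "imf4_roc", "concave"),
                                  ("imf5", "imf5_roc", "convex")):
            radius = draw(rkey)
            angle = _cap_angle_for_area(radius, float(rng.uniform(40.0, 80.0)),
                                        lo=12.0, hi=70.0)
            spec = CapSpec(radius=radius, cap_angle=angle, resolution=resolution,
                           noise_sd=noise_sd, sense=sense,
                           seed=(sub + 2000) % (2**31 - 1))
            mesh, truth = generate_cap(spec)
            records.append({
                "specimen": sid, "role": role, "mesh": mesh, "truth": truth,
                "true_roc": spec.radius, "flattened": False,
            })
    return records
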