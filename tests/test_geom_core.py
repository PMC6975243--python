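"""Geometric primitives: sphere/plane/circle fits, sections, frames, angles."""
import numpy as np
import pytest
from scipy.optimize import least_squares

from facetmorph import (
    CapSpec,
    CollinearPointsError,
    CoplanarPointsError,
    NoIntersectionError,
    OrientationSpec,
    UndefinedAngleError,
    angle_between,
    build_frame,
    cross_section,
    fit_plane,
    fit_sphere,
    generate_cap,
    point_sphere_residuals,
    surface_area,
    three_point_roc,
)
from facetmorph.geom_core import algebraic_sphere, fit_line

from conftest import rigid_transform


# ---------------------------------------------------------------------------
# sphere fitting
# ---------------------------------------------------------------------------

class TestFitSphere:
    def test_exact_octahedron(self):
        pts = np.array([[5, 0, 0], [-5, 0, 0], [0, 5, 0],
                        [0, -5, 0], [0, 0, 5], [0, 0, -5]], dtype=float)
        fit = fit_sphere(pts)
        assert np.allclose(fit.center, 0, atol=1e-9)
        assert fit.radius == pytest.approx(5.0, abs=1e-9)
        assert fit.mean_abs_error == pytest.approx(0.0, abs=1e-9)

    def test_exact_recovery_of_generating_radius(self):
        mesh, _ = generate_cap(CapSpec(radius=11.18, cap_angle=60.0,
                                       noise_sd=0.0, resolution=0.4))
        fit = fit_sphere(mesh.vertices)
        assert fit.radius == pytest.approx(11.18, abs=1e-6)
        assert np.linalg.norm(fit.center) < 1e-6

    def test_noise_mean_abs_error_matches_folded_normal(self):
        """Radial N(0, 0.1) residuals have mean |e| = 0.1*sqrt(2/pi)."""
        mesh, _ = generate_cap(CapSpec(radius=10.0, cap_angle=60.0,
                                       elongation=1.0, noise_sd=0.1,
                                       resolution=0.25, seed=5))
        assert mesh.n_vertices > 4000
        fit = fit_sphere(mesh.vertices)
        expect = 0.1 * np.sqrt(2 / np.pi)
        assert fit.mean_abs_error == pytest.approx(expect, rel=0.10)
        assert abs(fit.radius - 10.0) < 0.05

    def test_coplanar_points_rejected(self):
        rng = np.random.default_rng(0)
        pts = np.column_stack([rng.uniform(0, 10, 50), rng.uniform(0, 10, 50),
                               np.zeros(50)])
        with pytest.raises(CoplanarPointsError):
            fit_sphere(pts)

    def test_geometric_never_worse_than_algebraic(self):
        """The refined fit's SSE cannot exceed its algebraic seed's."""
        rng = np.random.default_rng(7)
        for _ in range(20):
            r = rng.uniform(4, 21)
            mesh, _ = generate_cap(CapSpec(
                radius=r, cap_angle=rng.uniform(30, 80), noise_sd=0.2,
                resolution=r / 12, seed=int(rng.integers(1 << 30))))
            pts = mesh.vertices
            c0, r0 = algebraic_sphere(pts)
            sse0 = ((np.linalg.norm(pts - c0, axis=1) - r0) ** 2).sum()
            fit = fit_sphere(pts)
            sse = ((np.linalg.norm(pts - fit.center, axis=1) - fit.radius) ** 2).sum()
            assert sse <= sse0 + 1e-9

    def test_matches_scipy_least_squares(self):
        """Independent optimizer reaches the same minimum."""
        mesh, _ = generate_cap(CapSpec(radius=9.0, cap_angle=55.0, noise_sd=0.15,
                                       resolution=0.6, seed=2))
        pts = mesh.vertices
        fit = fit_sphere(pts)
        c0, r0 = algebraic_sphere(pts)
        ref = least_squares(
            lambda x: np.linalg.norm(pts - x[:3], axis=1) - x[3],
            x0=[*c0, r0], method="lm")
        assert np.allclose(fit.center, ref.x[:3], atol=1e-6)
        assert fit.radius == pytest.approx(ref.x[3], abs=1e-6)

    def test_rigid_motion_equivariance(self):
        mesh, _ = generate_cap(CapSpec(radius=7.0, cap_angle=45.0, noise_sd=0.1,
                                       resolution=0.5, seed=9))
        pts = mesh.vertices
        base = fit_sphere(pts)
        rng = np.random.default_rng(1)
        for _ in range(5):
            q, t = rigid_transform(rng)
            moved = fit_sphere(pts @ q.T + t)
            assert np.allclose(moved.center, q @ base.center + t, atol=1e-7)
            assert moved.radius == pytest.approx(base.radius, abs=1e-8)
            assert moved.mean_abs_error == pytest.approx(base.mean_abs_error, abs=1e-8)

    def test_scale_equivariance(self):
        mesh, _ = generate_cap(CapSpec(radius=7.0, cap_angle=45.0, noise_sd=0.1,
                                       resolution=0.5, seed=9))
        pts = mesh.vertices
        base = fit_sphere(pts)
        s = 3.7
        scaled = fit_sphere(s * pts)
        assert scaled.radius == pytest.approx(s * base.radius, rel=1e-9)
        assert np.allclose(scaled.center, s * base.center, atol=1e-7)
        assert scaled.mean_abs_error == pytest.approx(s * base.mean_abs_error, rel=1e-7)
        assert scaled.mean_error_pct == pytest.approx(base.mean_error_pct, rel=1e-7)

    def test_curvature_sense_follows_normals(self):
        mesh, _ = generate_cap(CapSpec(radius=6.0, cap_angle=50.0, noise_sd=0.0,
                                       resolution=0.4, sense="convex"))
        args = dict(mean_normal=mesh.mean_surface_normal(),
                    centroid=mesh.area_weighted_centroid())
        assert fit_sphere(mesh.vertices, **args).curvature_sense == "convex"
        assert fit_sphere(mesh.vertices,
                          mean_normal=-args["mean_normal"],
                          centroid=args["centroid"]).curvature_sense == "concave"


def test_point_sphere_residuals_signed():
    pts = np.array([[10.2, 0, 0], [0, 10.2, 0], [0, 0, 10.2]])
    fit = fit_sphere(np.array([[10, 0, 0], [-10, 0, 0], [0, 10, 0],
                               [0, -10, 0], [0, 0, 10], [0, 0, -10]], dtype=float))
    res = point_sphere_residuals(pts, fit)
    assert np.allclose(res, 0.2, atol=1e-9)
    assert point_sphere_residuals(np.zeros((1, 3)), fit)[0] == pytest.approx(-10.0)
    on_sphere = np.array([[10, 0, 0], [0, 0, -10]], dtype=float)
    assert np.allclose(point_sphere_residuals(on_sphere, fit), 0, atol=1e-9)


# ---------------------------------------------------------------------------
# cross-sections and areas
# ---------------------------------------------------------------------------

class TestCrossSection:
    def test_hemisphere_midplane_is_semicircle(self, hemisphere):
        mesh, _ = hemisphere
        sec = cross_section(mesh, np.zeros(3), np.array([0, 1.0, 0]))
        assert sec.arc_length == pytest.approx(np.pi * 10, rel=0.005)

    def test_plane_missing_mesh(self, unit_square):
        with pytest.raises(NoIntersectionError):
            cross_section(unit_square, np.array([0, 0, 5.0]), np.array([0, 0, 1.0]))

    def test_unit_square_mid_cut(self, unit_square):
        sec = cross_section(unit_square, np.array([0, 0.5, 0]), np.array([0, 1.0, 0]))
        assert sec.arc_length == pytest.approx(1.0, abs=1e-9)

    def test_arc_length_rigid_invariance(self, noisy_cap):
        mesh, _ = noisy_cap
        base = cross_section(mesh, np.zeros(3), np.array([0, 1.0, 0])).arc_length
        rng = np.random.default_rng(4)
        q, t = rigid_transform(rng)
        from facetmorph import TriangleMesh
        moved = TriangleMesh(mesh.vertices @ q.T + t, mesh.faces)
        got = cross_section(moved, t, q @ np.array([0, 1.0, 0])).arc_length
        assert got == pytest.approx(base, rel=1e-9)


class TestSurfaceArea:
    def test_unit_square(self, unit_square):
        assert surface_area(unit_square) == pytest.approx(1.0)

    def test_hemisphere_analytic(self, hemisphere):
        mesh, truth = hemisphere
        assert truth.analytic_area == pytest.approx(2 * np.pi * 100, rel=1e-12)
        assert surface_area(mesh) == pytest.approx(628.3185, rel=0.005)

    def test_additive_over_face_partition(self, noisy_cap):
        mesh, _ = noisy_cap
        half = mesh.n_faces // 2
        a = mesh.submesh(np.arange(half))
        b = mesh.submesh(np.arange(half, mesh.n_faces))
        assert surface_area(a) + surface_area(b) == pytest.approx(
            surface_area(mesh), rel=1e-9)


# ---------------------------------------------------------------------------
# circles, angles, planes, frames
# ---------------------------------------------------------------------------

class TestThreePointRoc:
    def test_worked_examples(self):
        assert three_point_roc((0, 0, 0), (1, 1, 0), (2, 0, 0)) == pytest.approx(1.0, abs=1e-9)
        assert three_point_roc((0, 0, 0), (1, 0.2, 0), (2, 0, 0)) == pytest.approx(2.6, abs=1e-9)

    def test_collinear_rejected(self):
        with pytest.raises(CollinearPointsError):
            three_point_roc((0, 0, 0), (1, 0, 0), (2, 0, 0))

    def test_agrees_with_circumcenter_solve(self):
        """1000 random triples vs direct linear circumcenter solution."""
        rng = np.random.default_rng(12)
        checked = 0
        while checked < 1000:
            p1, p2, p3 = rng.uniform(-10, 10, (3, 3))
            n = np.cross(p2 - p1, p3 - p1)
            if np.linalg.norm(n) < 1e-6:
                continue
            A = np.array([2 * (p2 - p1), 2 * (p3 - p1), n])
            b = np.array([p2 @ p2 - p1 @ p1, p3 @ p3 - p1 @ p1, n @ p1])
            c = np.linalg.solve(A, b)
            expect = np.linalg.norm(c - p1)
            assert three_point_roc(p1, p2, p3) == pytest.approx(expect, rel=1e-9)
            checked += 1


class TestAngleBetween:
    def test_basics(self):
        assert angle_between((1, 0, 0), (0, 1, 0)) == pytest.approx(90.0)
        assert angle_between((2, 3, -1), (2, 3, -1)) == pytest.approx(0.0, abs=1e-6)

    def test_projection_merges_vectors(self):
        got = angle_between((1, 1, 1), (1, 1, -1), plane_normal=(0, 0, 1))
        assert got == pytest.approx(0.0, abs=1e-9)

    def test_zero_vector_rejected(self):
        with pytest.raises(UndefinedAngleError):
            angle_between((0, 0, 0), (1, 0, 0))
        with pytest.raises(UndefinedAngleError):
            angle_between((0, 0, 1), (1, 0, 0), plane_normal=(0, 0, 1))


class TestFitPlane:
    def test_exact_plane(self):
        rng = np.random.default_rng(3)
        pts = np.column_stack([rng.uniform(0, 5, 200), rng.uniform(0, 5, 200),
                               np.zeros(200)])
        _, normal, rms = fit_plane(pts)
        assert abs(normal[2]) == pytest.approx(1.0, abs=1e-12)
        assert rms == pytest.approx(0.0, abs=1e-12)

    def test_noisy_plane_rms_matches_generated_sd(self):
        rng = np.random.default_rng(8)
        z = rng.normal(0, 0.05, 1000)
        pts = np.column_stack([rng.uniform(0, 20, 1000), rng.uniform(0, 20, 1000), z])
        _, _, rms = fit_plane(pts)
        assert rms == pytest.approx(np.std(z), rel=0.20)

    def test_degenerate_inputs(self):
        with pytest.raises(Exception):
            fit_plane(np.array([[0, 0, 0], [1, 0, 0]], dtype=float))
        with pytest.raises(CollinearPointsError):
            fit_plane(np.array([[0, 0, 0], [1, 0, 0], [2, 0, 0], [3, 0, 0]],
                               dtype=float))


class TestAngleProperties:
    """Algebraic invariants of the angle measure, over random vectors."""

    from hypothesis import given, settings, strategies as st

    vec = st.lists(st.floats(-100, 100), min_size=3, max_size=3).filter(
        lambda v: np.linalg.norm(v) > 1e-3)

    @given(u=vec, v=vec)
    @settings(derandomize=True, max_examples=100, deadline=None)
    def test_symmetry_and_range(self, u, v):
        a = angle_between(u, v)
        assert 0.0 <= a <= 180.0
        assert a == pytest.approx(angle_between(v, u), abs=1e-9)

    @given(u=vec, v=vec, s=st.floats(0.01, 100))
    @settings(derandomize=True, max_examples=100, deadline=None)
    def test_scale_invariance(self, u, v, s):
        assert angle_between(u, v) == pytest.approx(
            angle_between(s * np.asarray(u), np.asarray(v)), abs=1e-8)

    @given(p=st.lists(st.floats(-10, 10), min_size=3, max_size=3),
           s=st.floats(0.1, 10))
    @settings(derandomize=True, max_examples=100, deadline=None)
    def test_three_point_roc_scales(self, p, s):
        p1 = np.asarray(p)
        p2 = p1 + [1.0, 0.3, 0.0]
        p3 = p1 + [2.0, 0.0, 0.1]
        base = three_point_roc(p1, p2, p3)
        scaled = three_point_roc(s * p1, s * p2, s * p3)
        assert scaled == pytest.approx(s * base, rel=1e-9)


def test_fit_line_direction():
    t = np.linspace(0, 1, 50)
    d = np.array([1.0, 2.0, -0.5])
    pts = np.outer(t, d) + np.array([3, 1, 0])
    _, direction = fit_line(pts)
    cosang = abs(direction @ d / np.linalg.norm(d))
    assert cosang == pytest.approx(1.0, abs=1e-12)


class TestBuildFrame:
    def test_pca_sagittal_follows_long_axis(self):
        mesh, _ = generate_cap(CapSpec(radius=10, cap_angle=45, elongation=1.8,
                                       noise_sd=0, resolution=0.4))
        frame = build_frame(mesh)
        assert abs(frame.sagittal_axis @ np.array([1.0, 0, 0])) > np.cos(np.radians(1))
        assert frame.normal_axis @ np.array([0, 0, 1.0]) > 0.9

    def test_circular_cap_normal_still_defined(self):
        mesh, _ = generate_cap(CapSpec(radius=10, cap_angle=45, elongation=1.0,
                                       noise_sd=0, resolution=0.4))
        frame = build_frame(mesh)
        assert abs(frame.normal_axis @ np.array([0, 0, 1.0])) > 0.99

    def test_landmark_axes_pass_through(self):
        mesh, _ = generate_cap(CapSpec(radius=10, cap_angle=45, elongation=1.3,
                                       noise_sd=0, resolution=0.4))
        spec = OrientationSpec(dorsal_volar_axis=np.array([0, 1.0, 0]),
                               radial_ulnar_axis=np.array([1.0, 0, 0]),
                               source="landmarks")
        frame = build_frame(mesh, spec)
        # supplied axes survive tangent-plane projection (tangent ~ xy plane)
        assert abs(frame.sagittal_axis @ np.array([0, 1.0, 0])) > 0.99
        assert abs(frame.coronal_axis @ np.array([1.0, 0, 0])) > 0.99
        assert np.allclose(np.cross(frame.sagittal_axis, frame.coronal_axis)
                           * frame.handedness, frame.normal_axis, atol=1e-9)
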