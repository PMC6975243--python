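"""Shared fixtures: canonical frames and cached synthetic surfaces."""
import numpy as np
import pytest

from facetmorph import AnatomicalFrame, CapSpec, TriangleMesh, generate_cap


@pytest.fixture(scope="session")
def canonical_frame():
    """Frame with sagittal=x, coronal=y, normal=z at the origin."""
    return AnatomicalFrame(
        np.zeros(3), np.array([1.0, 0, 0]), np.array([0, 1.0, 0]),
        np.array([0, 0, 1.0]))


@pytest.fixture(scope="session")
def unit_square():
    """1 mm x 1 mm planar square of two triangles."""
    vertices = np.array([[0, 0, 0], [1, 0, 0], [1, 1, 0], [0, 1, 0]], dtype=float)
    faces = np.array([[0, 1, 2], [0, 2, 3]])
    return TriangleMesh(vertices, faces, name="unit_square")


@pytest.fixture(scope="session")
def hemisphere():
    """Noise-free hemisphere of radius 10 mm at moderate resolution."""
    mesh, truth = generate_cap(
        CapSpec(radius=10.0, cap_angle=90.0, elongation=1.0, noise_sd=0.0,
                resolution=0.2))
    return mesh, truth


@pytest.fixture(scope="session")
def noisy_cap():
    """Radius-10 cap with 0.1 mm radial noise, ~4000 vertices."""
    mesh, truth = generate_cap(
        CapSpec(radius=10.0, cap_angle=60.0, elongation=1.0, noise_sd=0.1,
                resolution=0.3, seed=11))
    return mesh, truth


def rigid_transform(rng):
    """Random rotation + translation for invariance tests."""
    A = rng.normal(size=(3, 3))
    q, _ = np.linalg.qr(A)
    if np.linalg.det(q) < 0:
        q[:, 0] = -q[:, 0]
    t = rng.uniform(-50, 50, 3)
    return q, t
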