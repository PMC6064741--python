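import numpy as np
import pytest

from neuritemorph import SurfaceMesh, fixtures

CUBE_VERTICES = np.array([
    [0, 0, 0], [1, 0, 0], [1, 1, 0], [0, 1, 0],
    [0, 0, 1], [1, 0, 1], [1, 1, 1], [0, 1, 1],
], dtype=float)

# outward-wound unit cube, 12 triangles
CUBE_FACES = np.array([
    [0, 2, 1], [0, 3, 2], [4, 5, 6], [4, 6, 7],
    [0, 1, 5], [0, 5, 4], [1, 2, 6], [1, 6, 5],
    [2, 3, 7], [2, 7, 6], [3, 0, 4], [3, 4, 7],
])


@pytest.fixture
def unit_cube() -> SurfaceMesh:
    return SurfaceMesh("cube", CUBE_VERTICES.copy(), CUBE_FACES.copy())


@pytest.fixture
def open_cube() -> SurfaceMesh:
    """Unit cube missing its bottom face (first two triangles)."""
    return SurfaceMesh("open_cube", CUBE_VERTICES.copy(), CUBE_FACES[2:].copy())


@pytest.fixture(scope="session")
def icosphere4() -> SurfaceMesh:
    return fixtures.make_icosphere(radius=1.0, subdivisions=4)


@pytest.fixture(scope="session")
def straight_tube():
    """Straight cylinder r=0.3, L=10 with its true centerline."""
    spec = fixtures.TubeSpec(length=10.0, base_radius=0.3,
                             axial_samples=80, radial_samples=48)
    mesh, cl, rfn = fixtures.make_bulged_tube(spec)
    return mesh, cl, rfn


@pytest.fixture(scope="session")
def bulged_tube():
    """Tube with a Gaussian bulge peaking at r=0.3 around t=5."""
    spec = fixtures.TubeSpec(length=10.0, base_radius=0.15, bulge_height=0.15,
                             bulge_center=5.0, bulge_width=0.5,
                             axial_samples=120, radial_samples=48)
    mesh, cl, rfn = fixtures.make_bulged_tube(spec)
    return spec, mesh, cl, rfn


def random_rotation(seed: int) -> np.ndarray:
    rng = np.random.default_rng(seed)
    q, _ = np.linalg.qr(rng.normal(size=(3, 3)))
    if np.linalg.det(q) < 0:
        q[:, 0] *= -1
    return q
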