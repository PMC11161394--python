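import numpy as np
import pytest

from surfload.mesh import SurfaceMesh, generate_icosphere, triangulated_grid


@pytest.fixture(scope="session")
def icosahedron():
    return generate_icosphere(0, 1.0)


@pytest.fixture(scope="session")
def icosphere2():
    return generate_icosphere(2, 1.0)


@pytest.fixture(scope="session")
def grid_mesh():
    return triangulated_grid(6, 6, spacing=2.0)


@pytest.fixture
def single_triangle():
    coords = np.array([[0.0, 0.0, 0.0], [1.0, 0.0, 0.0],
                       [0.5, np.sqrt(3) / 2, 0.0]])
    return SurfaceMesh(coords, np.array([[0, 1, 2]]))


def random_delaunay_mesh(rng, n_points=30):
    """Connected planar test mesh from a Delaunay triangulation."""
    from scipy.spatial import Delaunay

    pts = rng.random((n_points, 2)) * 10.0
    tri = Delaunay(pts)
    coords = np.column_stack([pts, np.zeros(len(pts))])
    return SurfaceMesh(coords, tri.simplices.astype(np.int64))


@pytest.fixture
def delaunay_factory():
    return random_delaunay_mesh
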