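import numpy as np
import pytest

from dotmap.fixtures import make_disc_gradient, make_sphere
from dotmap.mesh_core import SurfaceMesh, VolumeMesh


@pytest.fixture(scope="session")
def ref_triangle():
    """Reference right triangle in the z=0 plane."""
    return (
        np.array([0.0, 0.0, 0.0]),
        np.array([1.0, 0.0, 0.0]),
        np.array([0.0, 1.0, 0.0]),
    )


@pytest.fixture(scope="session")
def ref_tetrahedron():
    return (
        np.array([0.0, 0.0, 0.0]),
        np.array([1.0, 0.0, 0.0]),
        np.array([0.0, 1.0, 0.0]),
        np.array([0.0, 0.0, 1.0]),
    )


@pytest.fixture
def square_mesh():
    """Unit square split into two triangles, with a point field "S"."""
    return SurfaceMesh(
        vertices=[[0, 0, 0], [1, 0, 0], [1, 1, 0], [0, 1, 0]],
        triangles=[[0, 1, 2], [0, 2, 3]],
        point_data={"S": np.array([0.0, 1.0, 2.0, 3.0])},
    )


@pytest.fixture
def single_tet_mesh():
    return VolumeMesh(
        vertices=[[0, 0, 0], [1, 0, 0], [0, 1, 0], [0, 0, 1]],
        tetrahedra=[[0, 1, 2, 3]],
        point_data={"S": np.array([0.0, 0.0, 0.0, 4.0])},
    )


@pytest.fixture(scope="session")
def disc16():
    return make_disc_gradient(resolution=16)


@pytest.fixture(scope="session")
def sphere2():
    return make_sphere(radius=10.0, subdivisions=2)
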