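import numpy as np
import pytest
import trimesh

from carpalfem.anatomy import ShapeConfig, generate_reduced_wrist
from carpalfem.mesh import SurfaceMesh, tetrahedralize


@pytest.fixture(scope="session")
def default_model():
    """One surrogate wrist shared by the whole suite (seed 1)."""
    model = generate_reduced_wrist(ShapeConfig(), seed=1)
    model.validate()
    return model


@pytest.fixture(scope="session")
def cube_mesh():
    """Unit cube tet4 mesh, edge ~0.5 mm."""
    box = trimesh.creation.box(extents=[1.0, 1.0, 1.0])
    return tetrahedralize(SurfaceMesh(box.vertices, box.faces), 0.5,
                          part="cube")


@pytest.fixture(scope="session")
def sphere_surface():
    ico = trimesh.creation.icosphere(subdivisions=3, radius=5.0)
    return SurfaceMesh(ico.vertices, ico.faces)


@pytest.fixture()
def rng():
    return np.random.default_rng(20220124)
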