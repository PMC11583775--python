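import numpy as np
import pytest
import trimesh.creation

from printqa.mesh import TriMesh
from printqa.phantom import generate_benchy
from printqa.study import StudyConfig, StudyRunner


@pytest.fixture(scope="session")
def benchy():
    """Coarse phantom shared by geometry-level tests."""
    return generate_benchy(1, 42)


@pytest.fixture(scope="session")
def runner():
    """Study runner under the default study conditions (shared CT cache)."""
    return StudyRunner(StudyConfig())


@pytest.fixture(scope="session")
def unit_cube():
    box = trimesh.creation.box(extents=[1.0, 1.0, 1.0])
    return TriMesh.from_trimesh(box)


@pytest.fixture(scope="session")
def tetrahedron():
    vertices = np.array(
        [[0.0, 0.0, 0.0], [1.0, 0.0, 0.0], [0.0, 1.0, 0.0], [0.0, 0.0, 1.0]]
    )
    faces = np.array([[0, 2, 1], [0, 1, 3], [0, 3, 2], [1, 2, 3]])
    return TriMesh(vertices, faces)


def icosphere(radius: float, subdivisions: int = 4) -> TriMesh:
    return TriMesh.from_trimesh(
        trimesh.creation.icosphere(subdivisions=subdivisions, radius=radius)
    )
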