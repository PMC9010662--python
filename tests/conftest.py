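import json

import numpy as np
import pytest

import tetmc

# A unit tetrahedralized cube: 8 nodes, 12 surface triangles, 6 tetrahedra
# sharing the 1-8 main diagonal; node indices 1-based as stored in files.
CUBE_VERTICES = [[0, 0, 0], [0, 0, 1], [0, 1, 0], [0, 1, 1],
                 [1, 0, 0], [1, 0, 1], [1, 1, 0], [1, 1, 1]]
CUBE_TRIANGLES = [[5, 7, 8], [1, 7, 5], [7, 3, 8], [1, 3, 7], [3, 4, 8],
                  [1, 4, 3], [4, 2, 8], [1, 2, 4], [2, 6, 8], [1, 6, 2],
                  [6, 5, 8], [1, 5, 6]]
CUBE_TETS = [[1, 5, 7, 8], [1, 7, 3, 8], [1, 3, 4, 8], [1, 4, 2, 8],
             [1, 2, 6, 8], [1, 6, 5, 8]]


@pytest.fixture
def cube_doc_text():
    """Plain-JSON JMesh text of the unit cube (the canonical worked example)."""
    return json.dumps({
        "MeshVertex3": CUBE_VERTICES,
        "MeshTri3": CUBE_TRIANGLES,
        "MeshTet4": CUBE_TETS,
    })


@pytest.fixture
def cube_mesh():
    """The same unit cube as an in-memory TetMesh."""
    corners = np.array([[x, y, z] for x in (0, 1) for y in (0, 1)
                        for z in (0, 1)], dtype=float)
    return tetmc.cube_to_tets(corners)


@pytest.fixture(scope="session")
def skinvessel_scene():
    """SkinVessel benchmark scene: 1 mm cube, three slabs, embedded vessel."""
    return tetmc.build_benchmark("skinvessel").scene


@pytest.fixture(scope="session")
def box_mesh_1mm():
    """Homogeneous 1 mm box mesh (single region) at 0.25 mm pitch."""
    sc = tetmc.build_scene(
        tetmc.Box((0, 0, 0), (1, 1, 1)), 1.0,
        [tetmc.Region(1, tetmc.Box((0, 0, 0), (1, 1, 1)))])
    return tetmc.tetrahedralize_scene(
        sc, tetmc.MeshingOptions(pitch_override=0.25))
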