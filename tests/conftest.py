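import numpy as np
import pytest

import fascitrace as ft

# ---------------------------------------------------------------------------
# small meshes
# ---------------------------------------------------------------------------


@pytest.fixture
def unit_triangle():
    """Unit right triangle P1=(0,0), P2=(1,0), P3=(0,1) as one element."""
    nodes = np.array([[0.0, 0.0], [1.0, 0.0], [0.0, 1.0]])
    return ft.finalize_mesh(nodes, np.array([[0, 1, 2]]))


@pytest.fixture
def unit_tet():
    nodes = np.array(
        [[0.0, 0.0, 0.0], [1.0, 0.0, 0.0], [0.0, 1.0, 0.0], [0.0, 0.0, 1.0]]
    )
    return ft.finalize_mesh(nodes, np.array([[0, 1, 2, 3]]))


@pytest.fixture(scope="session")
def unit_cube_mesh():
    m = ft.make_box3d(1.0, 1.0, 1.0, 0.34)
    return m


@pytest.fixture(scope="session")
def rect_mesh():
    return ft.make_rect2d(10.0, 1.0, 0.25)


@pytest.fixture(scope="session")
def rect_field(rect_mesh):
    bc = ft.make_uniform_flux_bc(rect_mesh, "origin", "insertion", 1.0)
    return ft.solve_potential(rect_mesh, bc)


# ---------------------------------------------------------------------------
# Gmsh fixture files (single tetrahedron, 4 tagged boundary triangles)
# ---------------------------------------------------------------------------

MSH22_SINGLE_TET = """$MeshFormat
2.2 0 8
$EndMeshFormat
$PhysicalNames
4
2 1 "prox"
2 2 "dist"
2 3 "side"
3 4 "vol"
$EndPhysicalNames
$Nodes
4
1 0 0 0
2 1 0 0
3 0 1 0
4 0 0 1
$EndNodes
$Elements
5
1 2 2 1 1 1 2 3
2 2 2 2 2 1 2 4
3 2 2 3 3 1 3 4
4 2 2 3 3 2 3 4
5 4 2 4 1 1 2 3 4
$EndElements
"""

MSH41_SINGLE_TET = """$MeshFormat
4.1 0 8
$EndMeshFormat
$PhysicalNames
4
2 1 "prox"
2 2 "dist"
2 3 "side"
3 4 "vol"
$EndPhysicalNames
$Entities
0 0 4 1
1 0 0 0 1 1 0 1 1 0
2 0 0 0 1 0 1 1 2 0
3 0 0 0 1 1 1 1 3 0
4 0 0 0 1 1 1 1 3 0
1 0 0 0 1 1 1 1 4 4 1 2 3 4
$EndEntities
$Nodes
1 4 1 4
3 1 0 4
1
2
3
4
0 0 0
1 0 0
0 1 0
0 0 1
$EndNodes
$Elements
4 5 1 5
2 1 2 1
1 1 2 3
2 2 2 1
2 1 2 4
2 3 2 2
3 1 3 4
4 2 3 4
3 1 4 1
5 1 2 3 4
$EndElements
"""

# same mesh but the face (2,3,4) is in no physical surface group
MSH22_UNTAGGED = MSH22_SINGLE_TET.replace(
    "4 2 2 3 3 2 3 4\n", ""
).replace("$Elements\n5\n", "$Elements\n4\n")


@pytest.fixture
def msh22_path(tmp_path):
    p = tmp_path / "tet22.msh"
    p.write_text(MSH22_SINGLE_TET)
    return p


@pytest.fixture
def msh41_path(tmp_path):
    p = tmp_path / "tet41.msh"
    p.write_text(MSH41_SINGLE_TET)
    return p


@pytest.fixture
def msh22_untagged_path(tmp_path):
    p = tmp_path / "tet22_untagged.msh"
    p.write_text(MSH22_UNTAGGED)
    return p


# ---------------------------------------------------------------------------
# helpers
# ---------------------------------------------------------------------------


def read_vtk_points(path):
    """Minimal legacy-VTK ASCII point reader for round-trip tests."""
    pts = []
    with open(path) as fh:
        lines = fh.readlines()
    for i, line in enumerate(lines):
        if line.startswith("POINTS"):
            n = int(line.split()[1])
            j = i + 1
            while len(pts) < n:
                pts.append([float(v) for v in lines[j].split()])
                j += 1
            break
    return np.asarray(pts)


def read_vtk_lines_count(path):
    with open(path) as fh:
        for line in fh:
            if line.startswith("LINES"):
                return int(line.split()[1])
    return 0
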