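"""Simplicial mesh data model, topology construction, geometry and file I/O.

Supports 2D triangle meshes and 3D tetrahedral meshes through one code path
parameterized by the spatial dimension ``n``.  Faces (edges in 2D, triangles
in 3D) are identified by their sorted node tuple; the adjacent element with
the lower index is the *owner* and the stored integrated face normal points
outward from it.  All coordinates are millimetres and all indices are
0-based.
"""

from __future__ import annotations

import struct
from dataclasses import dataclass, field

import numpy as np

from .errors import MeshFormatError, MeshTopologyError, PatchError

__all__ = [
    "SimplexMesh",
    "finalize_mesh",
    "read_gmsh_msh",
    "read_stl",
    "select_patch_faces",
    "write_vtk",
    "write_tracts_vtk",
]

BOUNDARY = -1  # face_neighbor marker for boundary faces


@dataclass
class SimplexMesh:
    """Finalized simplicial mesh with face adjacency and geometric quantities.

    Attributes
    ----------
    dim : int
        Spatial dimension, 2 or 3.
    nodes : (N, dim) float array
        Node coordinates in mm.
    elements : (E, dim+1) int array
        Node indices of each simplex, oriented with positive signed volume.
    faces : (F, dim) int array
        Node indices of each face (sorted ascending).
    face_owner, face_neighbor : (F,) int arrays
        Adjacent element indices; ``face_neighbor`` is ``-1`` on the boundary.
    face_normal : (F, dim) float array
        Integrated (area-weighted) face normal, outward from the owner;
        its Euclidean norm equals the face measure.
    element_faces : (E, dim+1) int array
        Face index opposite each local vertex.
    element_face_sign : (E, dim+1) int array
        +1 where the element owns the face (stored normal is outward for this
        element), -1 where it is the neighbor.
    patches : dict[str, ndarray]
        Boundary patch label -> sorted boundary-face indices.  May be empty
        until :meth:`set_patches` is called.
    """

    dim: int
    nodes: np.ndarray
    elements: np.ndarray
    element_volume: np.ndarray
    element_centroid: np.ndarray
    faces: np.ndarray
    face_owner: np.ndarray
    face_neighbor: np.ndarray
    face_normal: np.ndarray
    face_area: np.ndarray
    face_centroid: np.ndarray
    element_faces: np.ndarray
    element_face_sign: np.ndarray
    patches: dict[str, np.ndarray] = field(default_factory=dict)

    # -- basic queries -----------------------------------------------------
    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def n_elements(self) -> int:
        return len(self.elements)

    @property
    def n_faces(self) -> int:
        return len(self.faces)

    @property
    def boundary_faces(self) -> np.ndarray:
        """Sorted indices of boundary faces."""
        return np.flatnonzero(self.face_neighbor == BOUNDARY)

    @property
    def interior_faces(self) -> np.ndarray:
        return np.flatnonzero(self.face_neighbor != BOUNDARY)

    def is_boundary_face(self, f: int) -> bool:
        return self.face_neighbor[f] == BOUNDARY

    def patch_of_face(self, f: int) -> str | None:
        """Patch label containing boundary face ``f``, or None if untagged."""
        for label, idx in self.patches.items():
            if f in self._patch_sets[label]:
                return label
        return None

    @property
    def _patch_sets(self) -> dict[str, frozenset]:
        cache = getattr(self, "_patch_sets_cache", None)
        if cache is None or set(cache) != set(self.patches):
            cache = {k: frozenset(int(i) for i in v) for k, v in self.patches.items()}
            object.__setattr__(self, "_patch_sets_cache", cache)
        return cache

    def patch_area(self, label: str) -> float:
        return float(self.face_area[self.patches[label]].sum())

    # -- patch assignment --------------------------------------------------
    def set_patches(self, mapping: dict[str, np.ndarray]) -> None:
        """Assign boundary patches; they must partition the boundary faces."""
        boundary = set(self.boundary_faces.tolist())
        seen: set[int] = set()
        clean: dict[str, np.ndarray] = {}
        for label, idx in mapping.items():
            arr = np.unique(np.asarray(list(idx), dtype=int))
            if arr.size and (np.any(self.face_neighbor[arr] != BOUNDARY)):
                raise PatchError(f"patch {label!r} contains interior faces")
            overlap = seen.intersection(arr.tolist())
            if overlap:
                raise PatchError(f"patch overlap: faces {sorted(overlap)[:5]}")
            seen.update(arr.tolist())
            clean[label] = arr
        missing = boundary - seen
        if missing:
            raise MeshFormatError(
                f"untagged boundary: {len(missing)} boundary faces in no patch"
            )
        extra = seen - boundary
        if extra:
            raise PatchError("patch faces are not boundary faces")
        self.patches = clean
        if hasattr(self, "_patch_sets_cache"):
            object.__delattr__(self, "_patch_sets_cache")

    # -- validation --------------------------------------------------------
    def validate(self) -> None:
        """Check all structural invariants; raise on violation."""
        if np.any(self.element_volume <= 0):
            raise MeshTopologyError("degenerate element: non-positive volume")
        # closed-polytope identity
        signed = (
            self.face_normal[self.element_faces]
            * self.element_face_sign[..., None]
        )
        closure = np.abs(signed.sum(axis=1)).max()
        scale = max(self.face_area.max(), 1.0)
        if closure > 1e-10 * scale:
            raise MeshTopologyError(f"closed-polytope identity violated: {closure}")
        # faces subset of adjacent element node sets
        for f in range(self.n_faces):
            fset = set(self.faces[f].tolist())
            if not fset <= set(self.elements[self.face_owner[f]].tolist()):
                raise MeshTopologyError(f"face {f} not in owner node set")
            nb = self.face_neighbor[f]
            if nb != BOUNDARY and not fset <= set(self.elements[nb].tolist()):
                raise MeshTopologyError(f"face {f} not in neighbor node set")
        if self.patches:
            self.set_patches(self.patches)  # re-validates the partition


# ---------------------------------------------------------------------------
# construction
# ---------------------------------------------------------------------------

def _signed_volumes(nodes: np.ndarray, elements: np.ndarray) -> np.ndarray:
    dim = nodes.shape[1]
    x = nodes[elements]  # (E, dim+1, dim)
    edges = x[:, 1:, :] - x[:, :1, :]  # (E, dim, dim)
    if dim == 2:
        det = edges[:, 0, 0] * edges[:, 1, 1] - edges[:, 0, 1] * edges[:, 1, 0]
        return det / 2.0
    det = np.linalg.det(edges)
    return det / 6.0


def finalize_mesh(
    nodes,
    elements,
    boundary_tags: dict[str, object] | None = None,
    default_patch: str | None = None,
) -> SimplexMesh:
    """Build a :class:`SimplexMesh` from raw nodes and simplices.

    Parameters
    ----------
    nodes, elements
        Coordinates ``(N, n)`` and simplex connectivity ``(E, n+1)``.
    boundary_tags
        Optional mapping ``label -> iterable of node tuples`` identifying
        boundary faces per patch.  When given, every boundary face must be
        covered (or fall into ``default_patch``).
    default_patch
        Label receiving boundary faces not listed in ``boundary_tags``.

    Negative-volume elements are repaired by swapping their last two nodes.
    """
    nodes = np.ascontiguousarray(np.asarray(nodes, dtype=float))
    elements = np.ascontiguousarray(np.asarray(elements, dtype=np.int64))
    if nodes.ndim != 2 or nodes.shape[1] not in (2, 3):
        raise MeshFormatError("unsupported mesh: nodes must be (N, 2) or (N, 3)")
    dim = nodes.shape[1]
    npe = dim + 1
    if elements.ndim != 2 or elements.shape[1] != npe:
        raise MeshFormatError(
            f"unsupported mesh: elements must be (E, {npe}) for dim={dim}"
        )
    if elements.size and (elements.min() < 0 or elements.max() >= len(nodes)):
        raise MeshTopologyError("element references an invalid node index")

    vol = _signed_volumes(nodes, elements)
    flip = vol < 0
    if np.any(flip):
        elements = elements.copy()
        elements[flip, -2], elements[flip, -1] = (
            elements[flip, -1].copy(),
            elements[flip, -2].copy(),
        )
        vol = _signed_volumes(nodes, elements)
    bbox = nodes.max(axis=0) - nodes.min(axis=0) if len(nodes) else np.ones(dim)
    vol_tol = 1e-14 * float(np.prod(np.maximum(bbox, 1e-300)))
    if np.any(vol <= vol_tol):
        bad = int(np.argmin(vol))
        raise MeshTopologyError(f"degenerate element {bad}: volume {vol[bad]:g}")

    n_el = len(elements)
    face_index: dict[tuple, int] = {}
    faces_list: list[tuple] = []
    owner: list[int] = []
    neighbor: list[int] = []
    owner_slot: list[int] = []
    element_faces = np.empty((n_el, npe), dtype=np.int64)
    element_face_sign = np.empty((n_el, npe), dtype=np.int8)
    local_masks = [tuple(j for j in range(npe) if j != i) for i in range(npe)]

    for e in range(n_el):
        elem = elements[e]
        for i in range(npe):
            key = tuple(sorted(int(elem[j]) for j in local_masks[i]))
            f = face_index.get(key)
            if f is None:
                f = len(faces_list)
                face_index[key] = f
                faces_list.append(key)
                owner.append(e)
                neighbor.append(BOUNDARY)
                owner_slot.append(i)
                element_faces[e, i] = f
                element_face_sign[e, i] = 1
            else:
                if neighbor[f] != BOUNDARY:
                    raise MeshTopologyError(
                        f"non-manifold mesh: face {key} shared by >2 elements"
                    )
                neighbor[f] = e
                element_faces[e, i] = f
                element_face_sign[e, i] = -1

    faces = np.asarray(faces_list, dtype=np.int64)
    face_owner = np.asarray(owner, dtype=np.int64)
    face_neighbor = np.asarray(neighbor, dtype=np.int64)
    owner_slot_arr = np.asarray(owner_slot, dtype=np.int64)

    fx = nodes[faces]  # (F, dim, dim)
    face_centroid = fx.mean(axis=1)
    if dim == 2:
        t = fx[:, 1, :] - fx[:, 0, :]
        normal = np.stack([t[:, 1], -t[:, 0]], axis=1)
    else:
        normal = 0.5 * np.cross(fx[:, 1, :] - fx[:, 0, :], fx[:, 2, :] - fx[:, 0, :])
    # orient outward from owner: away from the opposite vertex
    opp = nodes[elements[face_owner, owner_slot_arr]]
    flip_n = np.einsum("ij,ij->i", normal, face_centroid - opp) < 0
    normal[flip_n] *= -1.0
    face_area = np.linalg.norm(normal, axis=1)

    mesh = SimplexMesh(
        dim=dim,
        nodes=nodes,
        elements=elements,
        element_volume=vol,
        element_centroid=nodes[elements].mean(axis=1),
        faces=faces,
        face_owner=face_owner,
        face_neighbor=face_neighbor,
        face_normal=normal,
        face_area=face_area,
        face_centroid=face_centroid,
        element_faces=element_faces,
        element_face_sign=element_face_sign,
    )

    if boundary_tags is not None:
        mapping: dict[str, set[int]] = {}
        for label, tuples in boundary_tags.items():
            sel: set[int] = set()
            for tup in tuples:
                key = tuple(sorted(int(v) for v in tup))
                f = face_index.get(key)
                if f is None or face_neighbor[f] != BOUNDARY:
                    raise MeshFormatError(f"tagged face {key} is not a boundary face")
                sel.add(f)
            mapping[label] = sel
        covered: set[int] = set().union(*mapping.values()) if mapping else set()
        rest = set(mesh.boundary_faces.tolist()) - covered
        if rest:
            if default_patch is None:
                raise MeshFormatError(
                    f"untagged boundary: {len(rest)} faces not covered"
                )
            mapping.setdefault(default_patch, set()).update(rest)
        mesh.set_patches({k: np.array(sorted(v)) for k, v in mapping.items()})
    return mesh


def select_patch_faces(mesh: SimplexMesh, predicate) -> np.ndarray:
    """Boundary faces whose centroid satisfies ``predicate``.

    ``predicate`` takes one centroid coordinate vector and returns a truthy
    value.  Interior faces are never selected.  Raises ``PatchError`` when no
    boundary face matches.
    """
    sel = [int(f) for f in mesh.boundary_faces if predicate(mesh.face_centroid[f])]
    if not sel:
        raise PatchError("empty patch: predicate selects no boundary face")
    return np.asarray(sel, dtype=np.int64)


# ---------------------------------------------------------------------------
# Gmsh MSH reader (ASCII v2.2 and v4.1)
# ---------------------------------------------------------------------------

_VOLUMETRIC = {2: "triangle", 4: "tetra"}
_FACE_TYPES = {1: "line", 2: "triangle"}
_NODES_PER_TYPE = {1: 2, 2: 3, 4: 4, 15: 1}


def _read_sections(path) -> dict[str, list[str]]:
    sections: dict[str, list[str]] = {}
    current = None
    with open(path, "r", errors="replace") as fh:
        for raw in fh:
            line = raw.strip()
            if not line:
                continue
            if line.startswith("$End"):
                current = None
            elif line.startswith("$"):
                current = line[1:]
                sections[current] = []
            elif current is not None:
                sections[current].append(line)
    if "MeshFormat" not in sections:
        raise MeshFormatError("unsupported format: missing $MeshFormat")
    return sections


def _parse_physical_names(sections) -> dict[int, str]:
    names: dict[int, str] = {}
    for line in sections.get("PhysicalNames", [])[1:]:
        parts = line.split(maxsplit=2)
        if len(parts) < 3:
            continue
        names[int(parts[1])] = parts[2].strip().strip('"')
    return names


def _parse_msh2(sections):
    node_lines = sections.get("Nodes", [])
    n_nodes = int(node_lines[0])
    ids = np.empty(n_nodes, dtype=np.int64)
    coords = np.empty((n_nodes, 3), dtype=float)
    for i, line in enumerate(node_lines[1 : 1 + n_nodes]):
        parts = line.split()
        ids[i] = int(parts[0])
        coords[i] = [float(parts[1]), float(parts[2]), float(parts[3])]
    elem_lines = sections.get("Elements", [])
    n_elem = int(elem_lines[0])
    cells: list[tuple[int, int, list[int]]] = []  # (etype, physical, node ids)
    for line in elem_lines[1 : 1 + n_elem]:
        parts = [int(p) for p in line.split()]
        etype = parts[1]
        ntags = parts[2]
        phys = parts[3] if ntags >= 1 else 0
        conn = parts[3 + ntags :]
        cells.append((etype, phys, conn))
    return ids, coords, cells


def _parse_msh4(sections):
    # entity (dim, tag) -> first physical tag
    ent_phys: dict[tuple[int, int], int] = {}
    ent_lines = sections.get("Entities", [])
    if ent_lines:
        counts = [int(v) for v in ent_lines[0].split()]
        pos = 1
        for edim, n_ent in enumerate(counts):
            for _ in range(n_ent):
                parts = ent_lines[pos].split()
                pos += 1
                tag = int(parts[0])
                if edim == 0:
                    n_phys = int(parts[4])
                    phys = [int(v) for v in parts[5 : 5 + n_phys]]
                else:
                    n_phys = int(parts[7])
                    phys = [int(v) for v in parts[8 : 8 + n_phys]]
                ent_phys[(edim, tag)] = phys[0] if phys else 0

    node_lines = sections.get("Nodes", [])
    header = node_lines[0].split()
    n_blocks = int(header[0])
    ids: list[int] = []
    coords: list[list[float]] = []
    pos = 1
    for _ in range(n_blocks):
        edim, etag, parametric, n_in_block = (int(v) for v in node_lines[pos].split())
        pos += 1
        tags = [int(node_lines[pos + i]) for i in range(n_in_block)]
        pos += n_in_block
        for i in range(n_in_block):
            parts = node_lines[pos + i].split()
            ids.append(tags[i])
            coords.append([float(parts[0]), float(parts[1]), float(parts[2])])
        pos += n_in_block

    elem_lines = sections.get("Elements", [])
    n_blocks = int(elem_lines[0].split()[0])
    cells: list[tuple[int, int, list[int]]] = []
    pos = 1
    for _ in range(n_blocks):
        edim, etag, etype, n_in_block = (int(v) for v in elem_lines[pos].split())
        pos += 1
        phys = ent_phys.get((edim, etag), 0)
        for i in range(n_in_block):
            parts = [int(v) for v in elem_lines[pos + i].split()]
            cells.append((etype, phys, parts[1:]))
        pos += n_in_block
    return (
        np.asarray(ids, dtype=np.int64),
        np.asarray(coords, dtype=float),
        cells,
    )


def read_gmsh_msh(
    path,
    patch_name_map: dict[str, str] | None = None,
) -> SimplexMesh:
    """Read an ASCII Gmsh MSH (v2.2 or v4.1) file with physical groups.

    The file must contain exactly one volumetric element family (all
    triangles or all tetrahedra); lower-dimensional tagged elements define
    the boundary patches.  Physical-group names are renamed through
    ``patch_name_map`` (unmapped names are kept; the special key ``"*"``
    provides a default patch for untagged boundary faces).
    """
    patch_name_map = dict(patch_name_map or {})
    sections = _read_sections(path)
    version = sections["MeshFormat"][0].split()[0]
    if version.startswith("2"):
        ids, coords, cells = _parse_msh2(sections)
    elif version.startswith("4.1"):
        ids, coords, cells = _parse_msh4(sections)
    else:
        raise MeshFormatError(f"unsupported format: MSH version {version}")

    phys_names = _parse_physical_names(sections)
    id_map = {int(i): k for k, i in enumerate(ids)}

    vol_types = sorted({t for t, _, _ in cells if t in (2, 4, 5, 6, 7)})
    if 4 in vol_types:
        if any(t in (5, 6, 7) for t, _, _ in cells):
            raise MeshFormatError("unsupported mesh: mixed element families")
        vol_type, bnd_type, dim = 4, 2, 3
    elif 2 in vol_types:
        if any(t in (3, 5, 6, 7) for t, _, _ in cells):
            raise MeshFormatError("unsupported mesh: mixed element families")
        vol_type, bnd_type, dim = 2, 1, 2
    else:
        raise MeshFormatError("unsupported mesh: no triangles or tetrahedra found")

    elements = []
    bnd_tuples: dict[str, list[tuple]] = {}
    for etype, phys, conn in cells:
        if etype == vol_type:
            elements.append([id_map[c] for c in conn])
        elif etype == bnd_type:
            name = phys_names.get(phys, str(phys) if phys else "")
            label = patch_name_map.get(name, name)
            if not label:
                continue  # untagged boundary element: handled by coverage check
            bnd_tuples.setdefault(label, []).append(tuple(id_map[c] for c in conn))
    if not elements:
        raise MeshFormatError("unsupported mesh: no volumetric elements")
    elements = np.asarray(elements, dtype=np.int64)

    # drop unreferenced nodes
    used = np.unique(elements)
    renum = -np.ones(len(coords), dtype=np.int64)
    renum[used] = np.arange(len(used))
    nodes = coords[used][:, :dim]
    if dim == 2 and np.abs(coords[used][:, 2]).max(initial=0.0) > 1e-9:
        raise MeshFormatError("unsupported mesh: 2D mesh with non-zero z coordinates")
    elements = renum[elements]
    boundary_tags = {
        label: [tuple(int(renum[v]) for v in tup) for tup in tuples]
        for label, tuples in bnd_tuples.items()
    }
    default = patch_name_map.get("*")
    return finalize_mesh(nodes, elements, boundary_tags, default_patch=default)


# ---------------------------------------------------------------------------
# STL reader (untagged geometry, visualization only)
# ---------------------------------------------------------------------------

def read_stl(path):
    """Read an STL surface (ASCII or binary) as ``(points, triangles)``.

    Vertices are deduplicated exactly.  The result is untagged geometry for
    display only — it is *not* a volume mesh.
    """
    with open(path, "rb") as fh:
        head = fh.read(5)
        fh.seek(0)
        data = fh.read()
    tri_pts: list[tuple] = []
    if head == b"solid" and b"facet" in data[:2000]:
        for line in data.decode(errors="replace").splitlines():
            parts = line.split()
            if parts[:1] == ["vertex"]:
                tri_pts.append(tuple(float(v) for v in parts[1:4]))
    else:
        if len(data) < 84:
            raise MeshFormatError("unsupported format: truncated STL")
        (n_tri,) = struct.unpack_from("<I", data, 80)
        expected = 84 + 50 * n_tri
        if len(data) < expected:
            raise MeshFormatError("unsupported format: truncated binary STL")
        for i in range(n_tri):
            off = 84 + 50 * i + 12
            vals = struct.unpack_from("<9f", data, off)
            tri_pts.extend((vals[0:3], vals[3:6], vals[6:9]))
    if len(tri_pts) % 3:
        raise MeshFormatError("unsupported format: STL vertex count not divisible by 3")
    uniq: dict[tuple, int] = {}
    tris = []
    for i in range(0, len(tri_pts), 3):
        idx = []
        for p in tri_pts[i : i + 3]:
            key = tuple(p)
            idx.append(uniq.setdefault(key, len(uniq)))
        tris.append(idx)
    points = np.asarray(list(uniq.keys()), dtype=float)
    return points, np.asarray(tris, dtype=np.int64)


# ---------------------------------------------------------------------------
# legacy-VTK writers
# ---------------------------------------------------------------------------

def _fmt(x: float) -> str:
    return format(float(x), ".17g")


def _pad3(points: np.ndarray) -> np.ndarray:
    if points.shape[1] == 3:
        return points
    out = np.zeros((len(points), 3))
    out[:, : points.shape[1]] = points
    return out


def write_vtk(mesh: SimplexMesh, path, tracts=None, fields=None) -> None:
    """Write the volume mesh (with optional per-element data) as legacy VTK.

    ``fields`` maps array names to per-element scalars ``(E,)`` or vectors
    ``(E, dim)``.  When ``tracts`` is given, the polylines are written next
    to ``path`` with a ``_tracts`` suffix (see :func:`write_tracts_vtk`).
    """
    import os

    path = os.fspath(path)
    try:
        with open(path, "w") as fh:
            fh.write("# vtk DataFile Version 3.0\nfascitrace mesh\nASCII\n")
            fh.write("DATASET UNSTRUCTURED_GRID\n")
            pts = _pad3(mesh.nodes)
            fh.write(f"POINTS {len(pts)} double\n")
            for p in pts:
                fh.write(" ".join(_fmt(v) for v in p) + "\n")
            npe = mesh.dim + 1
            fh.write(f"CELLS {mesh.n_elements} {mesh.n_elements * (npe + 1)}\n")
            for elem in mesh.elements:
                fh.write(f"{npe} " + " ".join(str(int(v)) for v in elem) + "\n")
            ctype = 5 if mesh.dim == 2 else 10
            fh.write(f"CELL_TYPES {mesh.n_elements}\n")
            fh.write("\n".join([str(ctype)] * mesh.n_elements) + "\n")
            if fields:
                fh.write(f"CELL_DATA {mesh.n_elements}\n")
                for name, arr in fields.items():
                    arr = np.asarray(arr, dtype=float)
                    if arr.ndim == 1:
                        fh.write(f"SCALARS {name} double 1\nLOOKUP_TABLE default\n")
                        for v in arr:
                            fh.write(_fmt(v) + "\n")
                    else:
                        fh.write(f"VECTORS {name} double\n")
                        for v in _pad3(arr):
                            fh.write(" ".join(_fmt(c) for c in v) + "\n")
    except OSError as exc:  # pragma: no cover - environment dependent
        raise MeshFormatError(f"write failed: {exc}") from exc
    if tracts is not None:
        root, ext = os.path.splitext(path)
        write_tracts_vtk(tracts, root + "_tracts" + (ext or ".vtk"))


def write_tracts_vtk(tracts, path, cell_data: dict | None = None) -> None:
    """Write tract polylines as legacy-VTK poly-data.

    ``tracts`` is a sequence of ``(m_i, dim)`` point arrays (or objects with
    a ``points`` attribute).  ``cell_data`` maps names to per-tract scalars.
    """
    polylines = [
        np.asarray(getattr(t, "points", t), dtype=float) for t in tracts
    ]
    try:
        with open(path, "w") as fh:
            fh.write("# vtk DataFile Version 3.0\nfascitrace tracts\nASCII\n")
            fh.write("DATASET POLYDATA\n")
            n_pts = sum(len(p) for p in polylines)
            fh.write(f"POINTS {n_pts} double\n")
            for poly in polylines:
                for p in _pad3(poly):
                    fh.write(" ".join(_fmt(v) for v in p) + "\n")
            size = sum(len(p) + 1 for p in polylines)
            fh.write(f"LINES {len(polylines)} {size}\n")
            offset = 0
            for poly in polylines:
                idx = " ".join(str(offset + i) for i in range(len(poly)))
                fh.write(f"{len(poly)} {idx}\n")
                offset += len(poly)
            if cell_data:
                fh.write(f"CELL_DATA {len(polylines)}\n")
                for name, arr in cell_data.items():
                    fh.write(f"SCALARS {name} double 1\nLOOKUP_TABLE default\n")
                    for v in np.asarray(arr, dtype=float):
                        fh.write(_fmt(v) + "\n")
    except OSError as exc:  # pragma: no cover
        raise MeshFormatError(f"write failed: {exc}") from exc
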