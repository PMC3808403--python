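"""Deterministic generators of tagged synthetic test geometries plus
closed-form oracles and random simplex fixtures for the tracer.

The archetypes (strip, fan, annulus sector, box) cover the parallel, fanned
and curved architecture classes; every generated mesh is finalized and its
boundary partitioned into ``origin`` / ``insertion`` / ``belly`` patches.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import permutations

import numpy as np

from .errors import MeshTopologyError, PatchError
from .laplace_fv import BoundaryFluxSpec, make_per_face_flux_bc
from .mesh_core import SimplexMesh, finalize_mesh, select_patch_faces

__all__ = [
    "GeometrySpec",
    "build_geometry",
    "make_rect2d",
    "make_fan2d",
    "make_annulus_sector2d",
    "make_box3d",
    "random_flux_simplex",
    "annulus_closed_form",
    "annulus_flux_bc",
]

_TOL = 1e-9

SHAPES = ("rect2d", "fan2d", "annulus_sector2d", "box3d")


@dataclass
class GeometrySpec:
    """Named synthetic shape with parameters and target edge length."""

    shape: str
    h: float
    params: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.shape not in SHAPES:
            raise MeshTopologyError(f"invalid geometry: unknown shape {self.shape!r}")
        if self.h <= 0:
            raise MeshTopologyError("invalid geometry: h must be positive")


_DEFAULTS = {
    "rect2d": {"L": 10.0, "W": 1.0},
    "fan2d": {"base_width": 4.0, "tip_width": 1.0, "height": 3.0},
    "annulus_sector2d": {"r_inner": 1.0, "r_outer": 2.0, "theta": np.pi / 2},
    "box3d": {"L": 10.0, "W": 4.0, "H": 4.0},
}


def build_geometry(spec: GeometrySpec) -> SimplexMesh:
    params = dict(_DEFAULTS[spec.shape])
    params.update(spec.params)
    if spec.shape == "rect2d":
        return make_rect2d(params["L"], params["W"], spec.h)
    if spec.shape == "fan2d":
        return make_fan2d(
            params["base_width"], params["tip_width"], params["height"], spec.h
        )
    if spec.shape == "annulus_sector2d":
        return make_annulus_sector2d(
            params["r_inner"], params["r_outer"], params["theta"], spec.h
        )
    return make_box3d(params["L"], params["W"], params["H"], spec.h)


# ---------------------------------------------------------------------------
# 2D generators (crossed-diagonal triangulations of mapped grids)
# ---------------------------------------------------------------------------

def _crossed_grid_2d(corner_xy, nx: int, ny: int):
    """Triangulate an (nx, ny) logical grid into 4 triangles per cell.

    ``corner_xy(i, j)`` maps logical grid indices to physical coordinates.
    Cell centers are the averages of the four mapped corners.
    """
    nodes = []
    idx = {}
    for j in range(ny + 1):
        for i in range(nx + 1):
            idx[(i, j)] = len(nodes)
            nodes.append(corner_xy(i, j))
    elements = []
    for j in range(ny):
        for i in range(nx):
            a = idx[(i, j)]
            b = idx[(i + 1, j)]
            c = idx[(i + 1, j + 1)]
            d = idx[(i, j + 1)]
            m = len(nodes)
            nodes.append(
                0.25 * (np.asarray(nodes[a]) + nodes[b] + nodes[c] + nodes[d])
            )
            elements += [[a, b, m], [b, c, m], [c, d, m], [d, a, m]]
    return np.asarray(nodes, dtype=float), np.asarray(elements, dtype=np.int64)


def _tag_2d(mesh: SimplexMesh, origin_pred, insertion_pred) -> SimplexMesh:
    origin = select_patch_faces(mesh, origin_pred)
    insertion = select_patch_faces(mesh, insertion_pred)
    rest = sorted(
        set(mesh.boundary_faces.tolist()) - set(origin.tolist()) - set(insertion.tolist())
    )
    if not rest:
        raise PatchError("empty patch: no belly faces remain")
    mesh.set_patches(
        {"origin": origin, "insertion": insertion, "belly": np.asarray(rest)}
    )
    return mesh


def make_rect2d(L: float, W: float, h: float) -> SimplexMesh:
    """Rectangular strip: origin at the x=0 edge, insertion at x=L."""
    if min(L, W) <= 0 or h <= 0:
        raise MeshTopologyError("invalid geometry: non-positive dimensions")
    if h >= min(L, W):
        raise MeshTopologyError("resolution too coarse: h >= min(L, W)")
    nx = int(np.ceil(L / h))
    ny = int(np.ceil(W / h))
    nodes, elements = _crossed_grid_2d(
        lambda i, j: np.array([L * i / nx, W * j / ny]), nx, ny
    )
    mesh = finalize_mesh(nodes, elements)
    tol = _TOL * (1.0 + L + W)
    return _tag_2d(
        mesh,
        lambda c: abs(c[0]) < tol,
        lambda c: abs(c[0] - L) < tol,
    )


def make_fan2d(base_width: float, tip_width: float, height: float, h: float) -> SimplexMesh:
    """Trapezoidal fan: broad origin (base, y=0), narrow insertion (tip)."""
    if min(base_width, tip_width, height) <= 0 or h <= 0:
        raise MeshTopologyError("invalid geometry: non-positive dimensions")
    if tip_width >= base_width:
        raise MeshTopologyError("not a fan: tip_width must be < base_width")
    if h >= min(tip_width, height):
        raise MeshTopologyError("resolution too coarse")
    nx = int(np.ceil(base_width / h))
    ny = int(np.ceil(height / h))

    def corner(i, j):
        eta = j / ny
        w = base_width + (tip_width - base_width) * eta
        return np.array([(i / nx - 0.5) * w, eta * height])

    nodes, elements = _crossed_grid_2d(corner, nx, ny)
    mesh = finalize_mesh(nodes, elements)
    tol = _TOL * (1.0 + base_width + height)
    return _tag_2d(
        mesh,
        lambda c: abs(c[1]) < tol,
        lambda c: abs(c[1] - height) < tol,
    )


def make_annulus_sector2d(
    r_inner: float, r_outer: float, theta: float, h: float
) -> SimplexMesh:
    """Annulus sector: origin on the theta=0 radial edge, insertion on
    theta=Theta, belly on the two circular arcs.  Grid nodes sit exactly on
    the polar lattice.

    Radial node spacing is graded geometrically (uniform in log r) so cells
    stay self-similar as the arc length grows with r, and quads are split
    along alternating diagonals for isotropic element quality.
    """
    if not (0 < r_inner < r_outer) or not (0 < theta < 2 * np.pi):
        raise MeshTopologyError("invalid geometry: bad radii or angle")
    if h <= 0 or h >= (r_outer - r_inner):
        raise MeshTopologyError("resolution too coarse")
    nr = int(np.ceil((r_outer - r_inner) / h))
    r_mid = 0.5 * (r_inner + r_outer)
    nt = max(2, int(np.ceil(r_mid * theta / h)))

    nodes = []
    idx = {}
    ratio = r_outer / r_inner
    for j in range(nr + 1):
        r = r_inner * ratio ** (j / nr)
        for i in range(nt + 1):
            th = theta * i / nt
            idx[(i, j)] = len(nodes)
            nodes.append([r * np.cos(th), r * np.sin(th)])
    elements = []
    for j in range(nr):
        for i in range(nt):
            a = idx[(i, j)]
            b = idx[(i + 1, j)]
            c = idx[(i + 1, j + 1)]
            d = idx[(i, j + 1)]
            if (i + j) % 2:
                elements += [[a, b, c], [a, c, d]]
            else:
                elements += [[a, b, d], [b, c, d]]
    mesh = finalize_mesh(
        np.asarray(nodes, dtype=float), np.asarray(elements, dtype=np.int64)
    )
    ang_tol = _TOL

    def angle(c):
        return float(np.arctan2(c[1], c[0]))

    return _tag_2d(
        mesh,
        lambda c: abs(angle(c)) < ang_tol,
        lambda c: abs(angle(c) - theta) < ang_tol,
    )


# ---------------------------------------------------------------------------
# 3D generator (Kuhn/Freudenthal 6-tet split)
# ---------------------------------------------------------------------------

def make_box3d(L: float, W: float, H: float, h: float) -> SimplexMesh:
    """Structured box of tetrahedra: origin at the x=0 wall, insertion at
    x=L, belly on the four side walls.  Each grid cell is split into six
    tetrahedra (Kuhn split), which tessellates the box exactly and is
    conforming across cells."""
    if min(L, W, H) <= 0 or h <= 0:
        raise MeshTopologyError("invalid geometry: non-positive dimensions")
    if h >= min(L, W, H):
        raise MeshTopologyError("resolution too coarse: h >= min(L, W, H)")
    nx, ny, nz = (int(np.ceil(v / h)) for v in (L, W, H))

    def nid(i, j, k):
        return (k * (ny + 1) + j) * (nx + 1) + i

    xs = np.linspace(0.0, L, nx + 1)
    ys = np.linspace(0.0, W, ny + 1)
    zs = np.linspace(0.0, H, nz + 1)
    gz, gy, gx = np.meshgrid(zs, ys, xs, indexing="ij")
    nodes = np.column_stack([gx.ravel(), gy.ravel(), gz.ravel()])

    basis = np.eye(3, dtype=int)
    elements = []
    for k in range(nz):
        for j in range(ny):
            for i in range(nx):
                v0 = np.array([i, j, k])
                for perm in permutations(range(3)):
                    p = v0.copy()
                    tet = [nid(*p)]
                    for ax in perm:
                        p = p + basis[ax]
                        tet.append(nid(*p))
                    elements.append(tet)
    mesh = finalize_mesh(nodes, np.asarray(elements, dtype=np.int64))
    tol = _TOL * (1.0 + L + W + H)
    origin = select_patch_faces(mesh, lambda c: abs(c[0]) < tol)
    insertion = select_patch_faces(mesh, lambda c: abs(c[0] - L) < tol)
    rest = sorted(
        set(mesh.boundary_faces.tolist()) - set(origin.tolist()) - set(insertion.tolist())
    )
    mesh.set_patches(
        {"origin": origin, "insertion": insertion, "belly": np.asarray(rest)}
    )
    return mesh


# ---------------------------------------------------------------------------
# tracer fixtures and analytic oracles
# ---------------------------------------------------------------------------

def random_flux_simplex(dim: int, rng_seed: int):
    """Random non-degenerate simplex with fluxes induced by a random unit
    vector ``v`` (so they sum to zero to machine precision).

    Returns ``(mesh, fluxes, v)`` where ``mesh`` is a single-element
    :class:`SimplexMesh` and ``fluxes[i]`` is the outward flux ``v . N_i``
    through the face opposite local vertex ``i``.
    """
    if dim not in (2, 3):
        raise MeshTopologyError("invalid geometry: dim must be 2 or 3")
    rng = np.random.default_rng(rng_seed)
    while True:
        verts = rng.random((dim + 1, dim))
        vol = _simplex_volume(verts)
        if abs(vol) > 1e-3:
            break
    v = rng.normal(size=dim)
    v /= np.linalg.norm(v)
    mesh = finalize_mesh(verts, np.arange(dim + 1)[None, :])
    # outward integrated normals per local slot
    normals = mesh.face_normal[mesh.element_faces[0]] * mesh.element_face_sign[0][:, None]
    fluxes = normals @ v
    return mesh, fluxes, v


def _simplex_volume(verts: np.ndarray) -> float:
    d = verts[1:] - verts[0]
    n = verts.shape[1]
    return float(np.linalg.det(d)) / (2.0 if n == 2 else 6.0)


@dataclass
class AnnulusOracle:
    """Closed-form harmonic field on the annulus sector: ``phi = c * theta``,
    ``v = (c/r) e_theta``, radial-edge flux density ``c/r``."""

    r_inner: float
    r_outer: float
    theta: float
    c: float

    def phi(self, r, th):
        return self.c * np.asarray(th, dtype=float)

    def speed(self, r):
        return self.c / np.asarray(r, dtype=float)

    def velocity_xy(self, points):
        points = np.atleast_2d(np.asarray(points, dtype=float))
        r2 = (points**2).sum(axis=1)
        # (c/r) e_theta = (c/r^2) (-y, x)
        out = np.column_stack([-points[:, 1], points[:, 0]]) * (self.c / r2)[:, None]
        return out if out.shape[0] > 1 else out[0]

    def edge_density(self, r, side: str):
        """Signed outward flux density on a radial edge at radius ``r``."""
        g = self.c / np.asarray(r, dtype=float)
        return -g if side == "inflow" else g

    def streamline_length(self, r):
        return np.asarray(r, dtype=float) * self.theta


def annulus_closed_form(r_inner: float, r_outer: float, theta: float, c: float):
    if not (0 < r_inner < r_outer) or not (0 < theta < 2 * np.pi) or c == 0:
        raise MeshTopologyError("invalid geometry: bad oracle parameters")
    return AnnulusOracle(r_inner, r_outer, theta, c)


def annulus_flux_bc(mesh: SimplexMesh, oracle: AnnulusOracle) -> BoundaryFluxSpec:
    """Per-face 1/r boundary condition matching the annulus oracle.

    The inflow edge (origin patch, theta=0) gets density ``-c/r`` and the
    outflow edge ``+c/r`` evaluated at each face centroid; the symmetric face
    layout makes the global balance exact to machine precision.
    """
    table = {}
    for f in mesh.patches["origin"]:
        r = float(np.linalg.norm(mesh.face_centroid[f]))
        table[int(f)] = float(oracle.edge_density(r, "inflow"))
    for f in mesh.patches["insertion"]:
        r = float(np.linalg.norm(mesh.face_centroid[f]))
        table[int(f)] = float(oracle.edge_density(r, "outflow"))
    return make_per_face_flux_bc(mesh, table)
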