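"""Flux-consistent streamline tracing in barycentric coordinates.

Inside each simplex the constant velocity implied by the conservative face
fluxes moves every barycentric coordinate at the constant rate
``d(lambda_i)/dt = -f_i / (n V)``; the tract leaves through the face whose
coordinate first reaches zero (the minimum non-negative intersection time).
Because each step is consistent with the shared face fluxes, tracts cannot
terminate inside the volume or on a zero-flux (belly) boundary.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import PatchError, TracingError
from .laplace_fv import PotentialField
from .mesh_core import BOUNDARY, SimplexMesh

__all__ = [
    "BarycentricState",
    "Tract",
    "barycentric_coords",
    "intersection_times",
    "advance_through_element",
    "trace_fascicle",
    "seed_patch_centroids",
]

_TIE_TOL = 1e-12
_NUDGE = 1e-10
_SNAP = 1e-12


@dataclass
class BarycentricState:
    """Position inside an element expressed in barycentric coordinates."""

    element: int
    lam: np.ndarray
    face: int | None = None  # boundary face the state sits on, if any

    def point(self, mesh: SimplexMesh) -> np.ndarray:
        return self.lam @ mesh.nodes[mesh.elements[self.element]]


@dataclass
class Tract:
    """Raw element-by-element fascicle polyline."""

    seed_id: str
    points: np.ndarray               # (m, dim) entry point + one exit per element
    elements: np.ndarray             # (m-1,) element trail
    taus: np.ndarray                 # (m-1,) per-element times of flight
    start_patch: str | None
    end_patch: str | None
    status: str                      # reached-attachment | max-steps | stagnant
    seed_face: int | None = None
    seed_end: str = "start"          # which polyline end carries the seed

    @property
    def raw_length(self) -> float:
        return float(np.linalg.norm(np.diff(self.points, axis=0), axis=1).sum())


def barycentric_coords(mesh: SimplexMesh, element: int, point) -> np.ndarray:
    """Barycentric coordinates of ``point`` in ``element``.

    Components within 1e-12 of the [0, 1] bounds are clipped and the result
    renormalized; a point farther than ~1e-9 of the element diameter outside
    raises ``TracingError``.
    """
    verts = mesh.nodes[mesh.elements[element]]
    a = (verts[1:] - verts[0]).T
    rhs = np.asarray(point, dtype=float) - verts[0]
    lam_tail = np.linalg.solve(a, rhs)
    lam = np.empty(mesh.dim + 1)
    lam[1:] = lam_tail
    lam[0] = 1.0 - lam_tail.sum()
    # physical offset delta maps to a lambda error of ~ delta * A_i / (n V)
    diam = np.linalg.norm(verts.max(axis=0) - verts.min(axis=0))
    a_max = float(mesh.face_area[mesh.element_faces[element]].max())
    nv = mesh.dim * float(mesh.element_volume[element])
    tol = max(1e-12, 1e-9 * diam * a_max / nv)
    if lam.min() < -tol or lam.max() > 1.0 + tol:
        raise TracingError(
            f"point not in element {element}: lambda={np.array2string(lam)}"
        )
    lam = np.clip(lam, 0.0, 1.0)
    lam[np.abs(lam) < _SNAP] = 0.0
    return lam / lam.sum()


def intersection_times(lam, fluxes, volume: float, dim: int) -> np.ndarray:
    """Per-coordinate intersection times.

    Coordinate ``i`` decreases at rate ``f_i/(n V)`` when its outward flux is
    positive, so ``t_i = lam_i * n * V / f_i``; non-positive fluxes never
    drive the coordinate to zero and yield ``+inf``.
    """
    lam = np.asarray(lam, dtype=float)
    fluxes = np.asarray(fluxes, dtype=float)
    nv = dim * volume
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(fluxes > 0.0, lam * nv / fluxes, np.inf)
    return t


def _element_outward_fluxes(mesh: SimplexMesh, face_flux: np.ndarray, e: int):
    return face_flux[mesh.element_faces[e]] * mesh.element_face_sign[e]


def _neutralize(fluxes: np.ndarray) -> np.ndarray:
    # Shift so the local sum is exactly zero; the residual left by the solver
    # is spread evenly over the n+1 faces, preserving the shared global field.
    return fluxes - fluxes.sum() / len(fluxes)


def _transfer_to_neighbor(
    mesh: SimplexMesh, e: int, lam_exit: np.ndarray, exit_local: int, nb: int
) -> np.ndarray:
    """Re-express an exit state on a shared face in the neighbor element."""
    nodes_e = mesh.elements[e]
    nodes_nb = mesh.elements[nb]
    lam_nb = np.zeros(mesh.dim + 1)
    pos_in_e = {int(n): i for i, n in enumerate(nodes_e)}
    for j, n in enumerate(nodes_nb):
        i = pos_in_e.get(int(n))
        if i is not None and i != exit_local:
            lam_nb[j] = lam_exit[i]
    s = lam_nb.sum()
    if s <= 0:
        raise TracingError("degenerate face transfer")
    return lam_nb / s


def _nudge_interior(lam: np.ndarray, delta: float = _NUDGE) -> np.ndarray:
    npe = len(lam)
    lam = (1.0 - delta) * lam + delta / npe
    return lam / lam.sum()


@dataclass
class StepResult:
    tau: float
    exit_face: int
    exit_point: np.ndarray
    next_state: BarycentricState | None  # None when the exit face is boundary


def advance_through_element(
    mesh: SimplexMesh,
    state: BarycentricState,
    fld: PotentialField | np.ndarray,
) -> StepResult:
    """Advance a streamline through one element.

    ``fld`` may be a :class:`PotentialField` or a bare per-face flux array.
    The time of flight is the minimum non-negative intersection time; ties
    within 1e-12 resolve to the lower local face index and the transferred
    state is nudged slightly into the interior of the next element.
    """
    face_flux = fld.face_flux if isinstance(fld, PotentialField) else fld
    e = state.element
    q = _neutralize(_element_outward_fluxes(mesh, face_flux, e))
    vol = float(mesh.element_volume[e])
    t = intersection_times(state.lam, q, vol, mesh.dim)
    finite = np.isfinite(t)
    if not finite.any():
        raise TracingError(f"stagnant element {e}")
    tmin = float(t[finite].min())
    ties = np.flatnonzero(t - tmin <= _TIE_TOL * max(1.0, tmin))
    exit_local = int(ties.min())
    tau = float(t[exit_local])

    nv = mesh.dim * vol
    lam_exit = state.lam - tau * q / nv
    lam_exit = np.clip(lam_exit, 0.0, 1.0)
    lam_exit[exit_local] = 0.0
    lam_exit /= lam_exit.sum()
    exit_point = lam_exit @ mesh.nodes[mesh.elements[e]]

    f = int(mesh.element_faces[e, exit_local])
    own = int(mesh.face_owner[f])
    nb = int(mesh.face_neighbor[f])
    if nb == BOUNDARY:
        return StepResult(tau=tau, exit_face=f, exit_point=exit_point, next_state=None)
    nxt = nb if own == e else own
    lam_nb = _transfer_to_neighbor(mesh, e, lam_exit, exit_local, nxt)
    lam_nb = _nudge_interior(lam_nb)
    lam_nb[lam_nb < _SNAP] = 0.0
    lam_nb /= lam_nb.sum()
    return StepResult(
        tau=tau,
        exit_face=f,
        exit_point=exit_point,
        next_state=BarycentricState(element=nxt, lam=lam_nb),
    )


def _seed_face_of_state(mesh: SimplexMesh, state: BarycentricState) -> int:
    if state.face is not None:
        return int(state.face)
    zeros = np.flatnonzero(state.lam <= _SNAP)
    for i in zeros:
        f = int(mesh.element_faces[state.element, i])
        if mesh.face_neighbor[f] == BOUNDARY:
            return f
    raise TracingError("invalid seed: state is not on a boundary face")


def trace_fascicle(
    mesh: SimplexMesh,
    fld: PotentialField,
    seed: BarycentricState,
    direction: str = "downstream",
    max_steps: int | None = None,
    attachment_patches: tuple[str, str] = ("origin", "insertion"),
) -> Tract:
    """Trace one fascicle tract from a seed on an attachment boundary face.

    The tract runs element by element until it exits through a boundary face
    of an attachment patch.  For ``direction='upstream'`` all fluxes are
    negated and the resulting polyline is reversed so tracts always run from
    the first attachment patch toward the second.
    """
    if direction not in ("downstream", "upstream"):
        raise TracingError(f"invalid direction {direction!r}")
    seed_face = _seed_face_of_state(mesh, seed)
    seed_patch = mesh.patch_of_face(seed_face)
    if seed_patch not in attachment_patches:
        raise TracingError(
            f"invalid seed: face {seed_face} is on patch {seed_patch!r}, "
            f"not an attachment"
        )
    face_flux = fld.face_flux if direction == "downstream" else -fld.face_flux
    if max_steps is None:
        max_steps = 10 * mesh.n_elements

    attachment_faces = set()
    for label in attachment_patches:
        if label in mesh.patches:
            attachment_faces.update(int(f) for f in mesh.patches[label])

    seed_point = seed.point(mesh)
    state = BarycentricState(seed.element, _nudge_interior(seed.lam.copy()))
    points = [seed_point]
    trail: list[int] = []
    taus: list[float] = []
    status = "max-steps"
    end_patch: str | None = None
    for _ in range(max_steps):
        try:
            step = advance_through_element(mesh, state, face_flux)
        except TracingError as exc:
            if "stagnant" in str(exc):
                status = "stagnant"
                break
            raise
        trail.append(state.element)
        taus.append(step.tau)
        points.append(step.exit_point)
        if step.next_state is None:
            if step.exit_face in attachment_faces:
                status = "reached-attachment"
                end_patch = mesh.patch_of_face(step.exit_face)
            else:
                raise TracingError(
                    "invalid termination: tract left through non-attachment "
                    f"boundary face {step.exit_face} "
                    f"(patch {mesh.patch_of_face(step.exit_face)!r})"
                )
            break
        state = step.next_state

    pts = np.asarray(points)
    trail_arr = np.asarray(trail, dtype=np.int64)
    taus_arr = np.asarray(taus)
    seed_end = "start"
    start_patch, final_patch = seed_patch, end_patch
    if direction == "upstream":
        pts = pts[::-1].copy()
        trail_arr = trail_arr[::-1].copy()
        taus_arr = taus_arr[::-1].copy()
        seed_end = "end"
        start_patch, final_patch = end_patch, seed_patch
    return Tract(
        seed_id=f"f{seed_face}",
        points=pts,
        elements=trail_arr,
        taus=taus_arr,
        start_patch=start_patch,
        end_patch=final_patch,
        status=status,
        seed_face=seed_face,
        seed_end=seed_end,
    )


# ---------------------------------------------------------------------------
# seeding
# ---------------------------------------------------------------------------

def _face_offset_table(n_face_verts: int, count: int) -> list[np.ndarray]:
    """Deterministic interior barycentric offsets on a face.

    The first entry is the face centroid; further entries come from interior
    lattice points of successively finer uniform subdivisions, in
    lexicographic order, with duplicates removed.
    """
    out: list[np.ndarray] = []
    seen: set[tuple] = set()
    level = n_face_verts  # start at the centroid level
    while len(out) < count:
        denom = level
        if n_face_verts == 2:
            combos = [(i, denom - i) for i in range(1, denom)]
        else:
            combos = [
                (i, j, denom - i - j)
                for i in range(1, denom - 1)
                for j in range(1, denom - i)
            ]
        for combo in combos:
            w = tuple(round(c / denom, 12) for c in combo)
            if w in seen:
                continue
            seen.add(w)
            out.append(np.asarray(w, dtype=float))
            if len(out) == count:
                break
        level += 1
    return out


def seed_patch_centroids(
    mesh: SimplexMesh, patch: str, per_face: int = 1
) -> list[BarycentricState]:
    """Deterministic seeds on a boundary patch, in face-index order.

    ``per_face = 1`` places one seed at each face centroid; larger values add
    seeds at fixed interior barycentric offsets of the face.
    """
    if per_face < 1:
        raise PatchError(f"invalid density: per_face={per_face}")
    if patch not in mesh.patches or len(mesh.patches[patch]) == 0:
        raise PatchError(f"empty patch: {patch!r}")
    offsets = _face_offset_table(mesh.dim, per_face)
    seeds: list[BarycentricState] = []
    for f in sorted(int(v) for v in mesh.patches[patch]):
        e = int(mesh.face_owner[f])
        elem_nodes = mesh.elements[e]
        pos = {int(n): i for i, n in enumerate(elem_nodes)}
        face_nodes = mesh.faces[f]
        for w in offsets:
            lam = np.zeros(mesh.dim + 1)
            for wk, n in zip(w, face_nodes):
                lam[pos[int(n)]] = wk
            seeds.append(BarycentricState(element=e, lam=lam, face=f))
    return seeds
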