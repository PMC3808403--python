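"""Cell-centered finite-volume solver for the Laplace equation with
Neumann flux boundary conditions.

The discretization balances fluxes across element faces: the implicit part
is a two-point approximation along the owner-neighbor centroid line
(over-relaxed decomposition of the face normal), and mesh non-orthogonality
is handled by a deferred correction computed from least-squares cell
gradients, re-assembled and re-solved until the two-norm of the per-element
flux-balance residual drops below ``outer_tol`` times the total inflow.

The pure-Neumann nullspace (potential defined up to a constant) is removed
by pinning one element's potential.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from .errors import BoundaryConditionError, PatchError, SolverError
from .mesh_core import BOUNDARY, SimplexMesh

__all__ = [
    "BoundaryFluxSpec",
    "PotentialField",
    "BalanceReport",
    "make_uniform_flux_bc",
    "make_per_face_flux_bc",
    "solve_potential",
    "element_vectors",
    "check_balance",
]


@dataclass
class BoundaryFluxSpec:
    """Per-face Neumann flux densities (positive = outflow).

    ``face_density`` has one entry per mesh face and is zero on interior
    faces.  ``face_flux`` is the integrated flux ``g * A`` per face.
    """

    face_density: np.ndarray

    def face_flux(self, mesh: SimplexMesh) -> np.ndarray:
        return self.face_density * mesh.face_area

    def total_inflow(self, mesh: SimplexMesh) -> float:
        flux = self.face_flux(mesh)
        return float(np.maximum(-flux, 0.0).sum())

    def imbalance(self, mesh: SimplexMesh) -> float:
        """Signed global balance defect Σ g·A."""
        return float(self.face_flux(mesh).sum())

    def negated(self) -> "BoundaryFluxSpec":
        return BoundaryFluxSpec(-self.face_density)

    def validate(self, mesh: SimplexMesh, rtol: float = 1e-12) -> None:
        interior = mesh.interior_faces
        if np.any(self.face_density[interior] != 0.0):
            raise BoundaryConditionError("flux density set on interior faces")
        inflow = self.total_inflow(mesh)
        if inflow <= 0:
            raise BoundaryConditionError("incompatible boundary conditions: no inflow")
        if abs(self.imbalance(mesh)) > rtol * inflow:
            raise BoundaryConditionError(
                "incompatible boundary conditions: global flux balance "
                f"{self.imbalance(mesh):g} exceeds {rtol:g} x inflow"
            )


def make_uniform_flux_bc(
    mesh: SimplexMesh,
    inflow_patch: str,
    outflow_patch: str,
    total_flux: float,
) -> BoundaryFluxSpec:
    """Uniform-density flux BC: ``-Q/A_in`` on the inflow patch, ``+Q/A_out``
    on the outflow patch, zero elsewhere (muscle belly).

    Outflow densities are renormalized last so the global balance holds to
    machine precision.
    """
    if total_flux <= 0:
        raise BoundaryConditionError("total_flux must be positive")
    for label in (inflow_patch, outflow_patch):
        if label not in mesh.patches or len(mesh.patches[label]) == 0:
            raise PatchError(f"empty patch: {label!r}")
    fin = mesh.patches[inflow_patch]
    fout = mesh.patches[outflow_patch]
    if np.intersect1d(fin, fout).size:
        raise PatchError("patch overlap between inflow and outflow")
    g = np.zeros(mesh.n_faces)
    a_in = float(mesh.face_area[fin].sum())
    a_out = float(mesh.face_area[fout].sum())
    g[fin] = -total_flux / a_in
    g[fout] = total_flux / a_out
    # absorb rounding in the outflow side
    inflow_sum = float((g[fin] * mesh.face_area[fin]).sum())
    outflow_sum = float((g[fout] * mesh.face_area[fout]).sum())
    if outflow_sum != 0.0:
        g[fout] *= -inflow_sum / outflow_sum
    return BoundaryFluxSpec(g)


def make_per_face_flux_bc(mesh: SimplexMesh, density_by_face: dict) -> BoundaryFluxSpec:
    """Explicit per-face flux-density table for non-uniform conditions.

    Faces absent from the table get zero density (belly).  No renormalization
    is applied; the caller is responsible for global balance.
    """
    g = np.zeros(mesh.n_faces)
    boundary = set(mesh.boundary_faces.tolist())
    for f, density in density_by_face.items():
        if int(f) not in boundary:
            raise BoundaryConditionError(f"face {f} is not a boundary face")
        g[int(f)] = float(density)
    return BoundaryFluxSpec(g)


@dataclass
class PotentialField:
    """Solution of the Laplace problem on a mesh.

    ``phi`` is the per-element potential (up to the pinned constant),
    ``face_flux`` the single-valued per-face flux (positive along the stored
    owner-outward normal), and ``vectors`` the per-element constant gradient
    used as fascicle orientation.
    """

    phi: np.ndarray
    face_flux: np.ndarray
    vectors: np.ndarray
    report: dict = field(default_factory=dict)


@dataclass
class BalanceReport:
    residuals: np.ndarray           # per-element signed outward flux sums
    two_norm: float                 # ||r||_2 / total inflow
    max_norm: float                 # max |r_e| / total inflow
    boundary_balance: float         # |sum of boundary fluxes| / total inflow
    total_inflow: float
    passed: bool


# ---------------------------------------------------------------------------
# gradients and assembly helpers
# ---------------------------------------------------------------------------

def _ls_gradients(mesh: SimplexMesh, phi: np.ndarray, g_density: np.ndarray):
    """Weighted least-squares cell gradients.

    Interior faces contribute directional-difference rows to both adjacent
    cells; boundary faces contribute the imposed normal derivative (the flux
    density), which makes the reconstruction exact for linear fields.
    """
    dim = mesh.dim
    n_el = mesh.n_elements
    ata = np.zeros((n_el, dim, dim))
    atb = np.zeros((n_el, dim))

    interior = mesh.interior_faces
    P = mesh.face_owner[interior]
    N = mesh.face_neighbor[interior]
    d = mesh.element_centroid[N] - mesh.element_centroid[P]
    w2 = 1.0 / np.maximum(np.einsum("ij,ij->i", d, d), 1e-300)
    dphi = phi[N] - phi[P]
    outer = w2[:, None, None] * d[:, :, None] * d[:, None, :]
    rhs = (w2 * dphi)[:, None] * d
    np.add.at(ata, P, outer)
    np.add.at(atb, P, rhs)
    np.add.at(ata, N, outer)
    np.add.at(atb, N, rhs)

    bfaces = mesh.boundary_faces
    owner = mesh.face_owner[bfaces]
    nhat = mesh.face_normal[bfaces] / mesh.face_area[bfaces][:, None]
    np.add.at(ata, owner, nhat[:, :, None] * nhat[:, None, :])
    np.add.at(atb, owner, g_density[bfaces][:, None] * nhat)

    try:
        return np.linalg.solve(ata, atb[..., None])[..., 0]
    except np.linalg.LinAlgError:  # isolated singular cell: fall back to pinv
        grads = np.empty((n_el, dim))
        for e in range(n_el):
            grads[e] = np.linalg.pinv(ata[e]) @ atb[e]
        return grads


def solve_potential(
    mesh: SimplexMesh,
    bc: BoundaryFluxSpec,
    inner_rtol: float = 1e-8,
    outer_tol: float = 1e-8,
    max_outer: int = 50,
    pin_element: int = 0,
    pin_value: float = 0.0,
) -> PotentialField:
    """Solve the compatible Neumann Laplace problem on ``mesh``.

    Returns a :class:`PotentialField` whose face fluxes satisfy the imposed
    boundary fluxes exactly and whose per-element flux-balance residual
    two-norm (normalized by total inflow) is below ``outer_tol`` unless the
    correction loop hit ``max_outer`` (then ``report['converged']`` is
    False).
    """
    bc.validate(mesh)
    n_el = mesh.n_elements
    if not (0 <= pin_element < n_el):
        raise SolverError(f"pin_element {pin_element} out of range")
    q_in = bc.total_inflow(mesh)
    g_flux = bc.face_flux(mesh)
    g_density = bc.face_density

    interior = mesh.interior_faces
    P = mesh.face_owner[interior]
    N = mesh.face_neighbor[interior]
    d = mesh.element_centroid[N] - mesh.element_centroid[P]
    nvec = mesh.face_normal[interior]
    dn = np.einsum("ij,ij->i", nvec, d)
    if np.any(dn <= 0):
        raise SolverError("solver failure: inverted owner-neighbor geometry")
    a_f = np.einsum("ij,ij->i", nvec, nvec) / dn       # transmissibility
    e_vec = d * (a_f)[:, None]                          # over-relaxed part
    t_vec = nvec - e_vec                                # non-orthogonal part

    # graph Laplacian L phi = b
    rows = np.concatenate([P, N, P, N])
    cols = np.concatenate([P, N, N, P])
    vals = np.concatenate([a_f, a_f, -a_f, -a_f])
    L = sp.csr_matrix((vals, (rows, cols)), shape=(n_el, n_el))

    # per-element sum of imposed boundary fluxes
    b_bnd = np.zeros(n_el)
    bfaces = mesh.boundary_faces
    np.add.at(b_bnd, mesh.face_owner[bfaces], g_flux[bfaces])

    keep = np.ones(n_el, dtype=bool)
    keep[pin_element] = False
    Lrr = L[keep][:, keep].tocsr()
    Lrp = np.asarray(L[keep][:, [pin_element]].todense()).ravel()
    diag = Lrr.diagonal()
    if np.any(diag <= 0):
        raise SolverError("singular system: disconnected mesh")
    M = sp.diags(1.0 / diag)

    phi = np.zeros(n_el)
    corr = np.zeros(len(interior))
    prev_delta = None
    omega = 1.0
    res_norm = np.inf
    outer_iters = 0
    converged = False
    for outer_iters in range(1, max_outer + 1):
        b = b_bnd.copy()
        np.add.at(b, P, corr)
        np.add.at(b, N, -corr)
        rhs = b[keep] - Lrp * pin_value
        rtol = min(inner_rtol, max(1e-12, 1e-2 * min(res_norm, 1.0)))
        x0 = phi[keep]
        x, info = spla.cg(Lrr, rhs, x0=x0, rtol=rtol, atol=0.0, M=M,
                          maxiter=20 * n_el)
        if info > 0:
            raise SolverError(f"solver failure: CG did not converge (info={info})")
        if info < 0:
            raise SolverError("solver failure: CG breakdown")
        phi = np.empty(n_el)
        phi[keep] = x
        phi[pin_element] = pin_value
        grads = _ls_gradients(mesh, phi, g_density)
        gbar = 0.5 * (grads[P] + grads[N])
        corr_target = np.einsum("ij,ij->i", gbar, t_vec)
        flux_int = a_f * (phi[N] - phi[P]) + corr_target
        r = b_bnd.copy()
        np.add.at(r, P, flux_int)
        np.add.at(r, N, -flux_int)
        res_norm = float(np.linalg.norm(r)) / q_in
        if res_norm < outer_tol:
            corr = corr_target
            converged = True
            break
        # Aitken (Irons-Tuck) acceleration of the linear fixed-point iteration
        delta = corr_target - corr
        if prev_delta is not None:
            dd = delta - prev_delta
            denom = float(dd @ dd)
            if denom > 0:
                omega = float(np.clip(-omega * (prev_delta @ dd) / denom, 0.2, 50.0))
        corr = corr + omega * delta
        prev_delta = delta

    face_flux = g_flux.copy()
    face_flux[interior] = flux_int
    vectors = element_vectors(mesh, face_flux, tol_balance=None)
    report = {
        "outer_iterations": outer_iters,
        "residual_two_norm": res_norm,
        "inner_rtol": inner_rtol,
        "outer_tol": outer_tol,
        "converged": converged,
        "total_inflow": q_in,
        "pin_element": int(pin_element),
        "pin_value": float(pin_value),
    }
    if not converged:
        report["warning"] = "non-orthogonality correction hit max_outer"
    return PotentialField(phi=phi, face_flux=face_flux, vectors=vectors,
                          report=report)


def element_vectors(
    mesh: SimplexMesh,
    face_fluxes: np.ndarray,
    tol_balance: float | None = None,
) -> np.ndarray:
    """Constant per-element gradient vectors from conservative face fluxes.

    For each element, with ``f_i`` the outward flux through the face opposite
    local vertex ``i`` (at coordinates ``x_i``), the unique constant vector
    reproducing the fluxes is ``v = -(1/(n V)) * sum_i f_i x_i``; it is
    translation-invariant because the fluxes sum to zero.
    """
    signed = face_fluxes[mesh.element_faces] * mesh.element_face_sign
    resid = signed.sum(axis=1)
    if tol_balance is not None and np.abs(resid).max(initial=0.0) > tol_balance:
        raise SolverError(
            "non-conservative flux field: max element imbalance "
            f"{np.abs(resid).max():g} > {tol_balance:g}"
        )
    coords = mesh.nodes[mesh.elements]  # (E, n+1, dim)
    nv = mesh.dim * mesh.element_volume
    return -(signed[:, :, None] * coords).sum(axis=1) / nv[:, None]


def check_balance(
    mesh: SimplexMesh,
    fld: PotentialField,
    tol: float = 1e-8,
) -> BalanceReport:
    """Diagnostic conservation report for a computed field."""
    signed = fld.face_flux[mesh.element_faces] * mesh.element_face_sign
    residuals = signed.sum(axis=1)
    bflux = fld.face_flux[mesh.boundary_faces]
    q_in = float(np.maximum(-bflux, 0.0).sum())
    q_in = q_in if q_in > 0 else 1.0
    two_norm = float(np.linalg.norm(residuals)) / q_in
    max_norm = float(np.abs(residuals).max(initial=0.0)) / q_in
    boundary_balance = abs(float(bflux.sum())) / q_in
    return BalanceReport(
        residuals=residuals,
        two_norm=two_norm,
        max_norm=max_norm,
        boundary_balance=boundary_balance,
        total_inflow=q_in,
        passed=two_norm <= tol,
    )
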