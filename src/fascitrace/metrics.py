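"""Tract post-processing: spline smoothing/resampling, fascicle length,
pennation angle and per-muscle summary tables.

Raw tracts are locally non-smooth because of the linear discretization, so
they are subsampled, fitted with a parametric cubic smoothing spline and
resampled to a fixed number of equidistant (equal arc-length) points before
any metric is computed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.interpolate import splev, splprep

from .errors import PatchError, TractError
from .mesh_core import BOUNDARY, SimplexMesh
from .tracer import Tract

__all__ = [
    "SmoothedTract",
    "TractMetrics",
    "smooth_resample",
    "fascicle_length",
    "seed_tangent_normal",
    "pennation_angle",
    "summarize_tracts",
]

_ENDPOINT_WEIGHT = 1e4


@dataclass
class SmoothedTract:
    """Equal-arc-length resampled tract."""

    points: np.ndarray          # (n_points, dim)
    arc_length: float
    source: Tract | None = None

    @property
    def n_points(self) -> int:
        return len(self.points)


@dataclass
class TractMetrics:
    seed_id: str
    length_mm: float
    pennation_deg: float
    seed_face: int | None
    patch: str | None
    status: str = "reached-attachment"


def _subsample_indices(m: int, target: int) -> np.ndarray:
    target = int(np.clip(target, 4, m))
    return np.unique(np.round(np.linspace(0, m - 1, target)).astype(int))


def smooth_resample(
    tract: Tract | np.ndarray,
    n_points: int = 100,
    subsample_target: int = 30,
    smoothing: float | None = None,
) -> SmoothedTract:
    """Smooth a raw tract and resample it at equal arc-length stations.

    The raw polyline is subsampled to about ``subsample_target`` control
    points (endpoints always kept), fitted with a chord-length parameterized
    cubic smoothing spline whose endpoints are pinned by large weights, then
    evaluated densely and resampled at ``n_points`` equidistant stations.

    When ``smoothing`` is None the smoothing factor is reduced automatically
    until the spline's maximum deviation from the control points is at most
    half the local (median) raw segment length.
    """
    source = tract if isinstance(tract, Tract) else None
    raw = np.asarray(getattr(tract, "points", tract), dtype=float)
    if source is not None and source.status != "reached-attachment":
        raise TractError(f"tract too short: status {source.status!r}")
    if len(raw) < 4:
        raise TractError(f"tract too short: {len(raw)} raw points")
    if n_points < 2:
        raise TractError("n_points must be at least 2")
    seglen = np.linalg.norm(np.diff(raw, axis=0), axis=1)
    total = float(seglen.sum())
    if total <= 0:
        raise TractError("degenerate tract: zero length")

    idx = _subsample_indices(len(raw), subsample_target)
    ctrl = raw[idx]
    # collapse exactly coincident consecutive control points (splprep rejects them)
    keep = np.ones(len(ctrl), dtype=bool)
    keep[1:] = np.linalg.norm(np.diff(ctrl, axis=0), axis=1) > 1e-14 * max(total, 1.0)
    ctrl = ctrl[keep]
    if len(ctrl) < 4:
        raise TractError("tract too short: fewer than 4 distinct control points")
    u = np.concatenate([[0.0], np.cumsum(np.linalg.norm(np.diff(ctrl, axis=0), axis=1))])
    u /= u[-1]
    w = np.ones(len(ctrl))
    w[0] = w[-1] = _ENDPOINT_WEIGHT

    h_local = float(np.median(seglen[seglen > 0]))
    max_dev = 0.5 * h_local
    if smoothing is None:
        s = len(ctrl) * max_dev**2
        for _ in range(60):
            tck, _ = splprep(ctrl.T, u=u, w=w, s=s, k=3)
            fit = np.asarray(splev(u, tck)).T
            if np.linalg.norm(fit - ctrl, axis=1).max() <= max_dev or s < 1e-30:
                break
            s *= 0.25
    else:
        tck, _ = splprep(ctrl.T, u=u, w=w, s=float(smoothing), k=3)

    dense = max(4000, 20 * n_points)
    ud = np.linspace(0.0, 1.0, dense)
    pd_ = np.asarray(splev(ud, tck)).T
    cum = np.concatenate([[0.0], np.cumsum(np.linalg.norm(np.diff(pd_, axis=0), axis=1))])
    arc = float(cum[-1])
    if arc <= 0:
        raise TractError("degenerate tract: zero spline length")
    stations = np.linspace(0.0, arc, n_points)
    out = np.column_stack(
        [np.interp(stations, cum, pd_[:, k]) for k in range(pd_.shape[1])]
    )
    return SmoothedTract(points=out, arc_length=arc, source=source)


def fascicle_length(tract: SmoothedTract | np.ndarray) -> float:
    """Sum of Euclidean distances between consecutive tract points (mm)."""
    pts = np.asarray(getattr(tract, "points", tract), dtype=float)
    if len(pts) < 2:
        raise TractError("degenerate tract: fewer than 2 points")
    return float(np.linalg.norm(np.diff(pts, axis=0), axis=1).sum())


def seed_tangent_normal(
    mesh: SimplexMesh,
    seed_face: int,
    adjacency: str = "vertex",
    same_patch: bool = True,
) -> np.ndarray:
    """Averaged outward unit normal of a boundary face and its neighbors.

    Neighboring boundary faces share at least one node with the seed face
    (``adjacency='vertex'``, the default) or a full sub-face
    (``adjacency='edge'``: ``dim - 1`` shared nodes).  With ``same_patch``
    (default) the average stays on the seed face's own patch — the tangent
    plane belongs to the attachment surface, so faces across a crease onto
    another patch must not tilt it.
    """
    if mesh.face_neighbor[seed_face] != BOUNDARY:
        raise PatchError(f"not a boundary face: {seed_face}")
    if adjacency not in ("vertex", "edge"):
        raise PatchError(f"unknown adjacency {adjacency!r}")
    need = 1 if adjacency == "vertex" else mesh.dim - 1
    seed_patch = mesh.patch_of_face(seed_face) if same_patch else None
    seed_nodes = set(mesh.faces[seed_face].tolist())
    total = np.zeros(mesh.dim)
    for f in mesh.boundary_faces:
        if seed_patch is not None and mesh.patch_of_face(int(f)) != seed_patch:
            continue
        shared = len(seed_nodes.intersection(mesh.faces[f].tolist()))
        if f == seed_face or shared >= need:
            total += mesh.face_normal[f] / mesh.face_area[f]
    norm = np.linalg.norm(total)
    if norm <= 0:
        raise PatchError("degenerate tangent normal: neighbor normals cancel")
    return total / norm


def pennation_angle(tract: SmoothedTract | np.ndarray, plane_normal) -> float:
    """Pennation angle (degrees) at the seed end of a resampled tract.

    For each of the five tract points following the seed point, the angle
    between the chord from the seed and the attachment tangent plane is
    ``arcsin(|chord . n| / |chord|)``; the five angles are averaged.  On a
    100-point tract the five steps span 5% of the fascicle length.
    """
    pts = np.asarray(getattr(tract, "points", tract), dtype=float)
    if len(pts) < 6:
        raise TractError("tract too short: pennation needs at least 6 points")
    n_hat = np.asarray(plane_normal, dtype=float)
    n_hat = n_hat / np.linalg.norm(n_hat)
    angles = []
    for k in range(1, 6):
        chord = pts[k] - pts[0]
        norm = np.linalg.norm(chord)
        if norm <= 0:
            raise TractError("degenerate tract head: coincident leading points")
        s = abs(float(chord @ n_hat)) / norm
        angles.append(np.degrees(np.arcsin(np.clip(s, 0.0, 1.0))))
    return float(np.clip(np.mean(angles), 0.0, 90.0))


def summarize_tracts(metrics) -> pd.DataFrame:
    """One row per tract plus aggregate rows (mean/SD/min/max per patch)."""
    metrics = list(metrics)
    if not metrics:
        raise TractError("no tracts")
    rows = [
        {
            "seed_id": m.seed_id,
            "patch": m.patch,
            "length_mm": m.length_mm,
            "pennation_deg": m.pennation_deg,
            "status": m.status,
            "kind": "tract",
        }
        for m in metrics
    ]
    df = pd.DataFrame(rows)
    aggs = []
    for patch, grp in df.groupby("patch", dropna=False):
        for stat, fn in (
            ("mean", np.mean),
            ("sd", lambda v: float(np.std(v, ddof=0))),
            ("min", np.min),
            ("max", np.max),
        ):
            aggs.append(
                {
                    "seed_id": f"{stat}",
                    "patch": patch,
                    "length_mm": float(fn(grp["length_mm"].to_numpy())),
                    "pennation_deg": float(fn(grp["pennation_deg"].to_numpy())),
                    "status": "",
                    "kind": f"aggregate-{stat}",
                }
            )
    return pd.concat([df, pd.DataFrame(aggs)], ignore_index=True)
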