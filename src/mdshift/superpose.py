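"""Rigid-body superposition (Kabsch) and RMSD.

The overlay operator used everywhere downstream: weighted least-squares fit
of one coordinate set onto another over proper rotations and translations.
Reflections are excluded by the determinant correction in the SVD branch so
chirality is always preserved.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .errors import GeometryError, SelectionError
from .model import (
    CA_SELECTION,
    Selection,
    Structure,
    Trajectory,
    resolve_selection,
)

__all__ = [
    "SuperpositionResult",
    "kabsch",
    "rmsd",
    "rmsd_series",
    "fit_frames",
]


@dataclass
class SuperpositionResult:
    """Optimal proper rotation + translation and the RMSD at that optimum.

    The fitted mobile coordinates are ``mobile @ rotation.T + translation``.
    """

    rotation: np.ndarray
    translation: np.ndarray
    rmsd: float

    def apply(self, coords: np.ndarray) -> np.ndarray:
        return np.asarray(coords) @ self.rotation.T + self.translation


def _normalized_weights(weights, n: int) -> np.ndarray:
    if weights is None:
        return np.full(n, 1.0 / n)
    w = np.asarray(weights, dtype=float)
    if w.shape != (n,):
        raise ValueError(f"weights shape {w.shape} != ({n},)")
    if np.any(w < 0) or w.sum() <= 0:
        raise ValueError("weights must be non-negative with positive sum")
    return w / w.sum()


def _kabsch_batch(
    mobile: np.ndarray, target: np.ndarray, weights: np.ndarray
):
    """Vectorized Kabsch for a batch of frames against one target.

    mobile: (F, N, 3); target: (N, 3); weights: (N,) summing to 1.
    Returns rotations (F, 3, 3), translations (F, 3), rmsds (F,).
    """
    w = weights[None, :, None]
    cm = (mobile * w).sum(axis=1)  # (F, 3)
    ct = (target * weights[:, None]).sum(axis=0)  # (3,)
    m_c = mobile - cm[:, None, :]
    t_c = target - ct
    # Cross-covariance H[f] = sum_n w_n m_c[f,n] (x) t_c[n]
    h = np.einsum("fni,nj->fij", m_c * w, t_c)
    u, s, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(u @ vt))
    corr = np.repeat(np.eye(3)[None], mobile.shape[0], axis=0)
    corr[:, 2, 2] = d
    # R maximizes tr(R H) over SO(3)
    rot = np.transpose(u @ corr @ vt, (0, 2, 1))
    fitted = np.einsum("fij,fnj->fni", rot, m_c)
    sq = ((fitted - t_c[None]) ** 2).sum(axis=2)
    rmsds = np.sqrt((sq * weights[None]).sum(axis=1))
    trans = ct[None, :] - np.einsum("fij,fj->fi", rot, cm)
    return rot, trans, rmsds, s


def kabsch(
    mobile: np.ndarray,
    target: np.ndarray,
    weights=None,
) -> SuperpositionResult:
    """Optimal weighted overlay of ``mobile`` onto ``target``.

    Minimizes the weighted RMSD over all proper rotations + translations.
    Requires at least three points.  For rank-deficient configurations
    (e.g. both point sets collinear) the minimal RMSD is still returned but
    the rotation is not unique; a warning is emitted.
    """
    mobile = np.asarray(mobile, dtype=float)
    target = np.asarray(target, dtype=float)
    if mobile.shape != target.shape or mobile.ndim != 2 or mobile.shape[1] != 3:
        raise GeometryError(
            f"coordinate shapes {mobile.shape} vs {target.shape} invalid"
        )
    n = mobile.shape[0]
    if n < 3:
        raise GeometryError(f"need at least 3 points, got {n}")
    w = _normalized_weights(weights, n)
    rot, trans, rmsds, s = _kabsch_batch(mobile[None], target, w)
    sv = s[0]
    if sv[0] <= 0 or sv[1] < 1e-12 * sv[0]:
        warnings.warn(
            "degenerate (collinear) configuration: minimal RMSD is valid "
            "but the rotation is not unique",
            stacklevel=2,
        )
    return SuperpositionResult(rot[0], trans[0], float(rmsds[0]))


def rmsd(a: np.ndarray, b: np.ndarray, weights=None) -> float:
    """Plain RMSD between two coordinate sets; no superposition performed."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise GeometryError(f"shape mismatch {a.shape} vs {b.shape}")
    w = _normalized_weights(weights, a.shape[0])
    sq = ((a - b) ** 2).sum(axis=1)
    return float(np.sqrt((sq * w).sum()))


def _matched_indices(
    traj: Trajectory, reference: Structure, sel: Selection
) -> tuple[np.ndarray, np.ndarray]:
    idx_t = resolve_selection(traj.topology, sel)
    idx_r = resolve_selection(reference, sel)
    if idx_t.shape != idx_r.shape:
        raise SelectionError(
            f"selection {sel.to_string()!r} resolves to {idx_t.size} atoms "
            f"on the trajectory but {idx_r.size} on the reference"
        )
    return idx_t, idx_r


def fit_frames(
    traj: Trajectory,
    reference: Structure,
    fit_sel: Selection = CA_SELECTION,
    frames: np.ndarray | None = None,
) -> np.ndarray:
    """Superpose every frame onto the reference over ``fit_sel`` atoms.

    Returns the transformed full-topology frames, shape (F, N, 3).
    ``frames`` optionally restricts to a subset of frame coordinates.
    """
    idx_t, idx_r = _matched_indices(traj, reference, fit_sel)
    coords = traj.frames if frames is None else np.asarray(frames, dtype=float)
    w = np.full(idx_t.size, 1.0 / idx_t.size)
    rot, trans, _, _ = _kabsch_batch(
        coords[:, idx_t, :], reference.coords[idx_r], w
    )
    return np.einsum("fij,fnj->fni", rot, coords) + trans[:, None, :]


def rmsd_series(
    traj: Trajectory,
    reference: Structure,
    fit_sel: Selection = CA_SELECTION,
    report_sel: Selection | None = None,
) -> np.ndarray:
    """Per-frame RMSD to a fixed reference after per-frame superposition.

    Each frame is fitted on ``fit_sel`` atoms; the RMSD is then reported
    over ``report_sel`` atoms (default: same as the fit selection).  This is
    the standard structural-drift diagnostic: a flat series means the fold
    is stable over the sampled interval.
    """
    if report_sel is None:
        report_sel = fit_sel
    fitted = fit_frames(traj, reference, fit_sel)
    idx_t, idx_r = _matched_indices(traj, reference, report_sel)
    diff = fitted[:, idx_t, :] - reference.coords[idx_r][None]
    return np.sqrt((diff**2).sum(axis=2).mean(axis=1))
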