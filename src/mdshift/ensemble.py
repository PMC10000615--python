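"""Per-residue fluctuation profiles and window-averaged mean structures.

RMSF here follows the standard definition: after every frame is superposed
onto a common reference, each alpha-carbon's fluctuation is measured about
its own time-mean position (not about the reference position).  Replicate
averaging happens at the profile level — the mean of per-replicate RMSF
curves — not by pooling frames, so replicates with different lengths
contribute equally.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .errors import AlignmentError, MDShiftError, WindowError
from .model import CA_SELECTION, Selection, Structure, Trajectory
from .superpose import fit_frames

__all__ = [
    "RMSFProfile",
    "AverageStructure",
    "rmsf_profile",
    "average_rmsf",
    "average_structure",
]


@dataclass
class RMSFProfile:
    """Per-residue Calpha fluctuation amplitudes in Angstrom."""

    residue_numbers: np.ndarray
    values: np.ndarray
    n_frames: int
    replicate_count: int = 1

    def __post_init__(self):
        self.residue_numbers = np.asarray(self.residue_numbers, dtype=int)
        self.values = np.asarray(self.values, dtype=float)
        if self.residue_numbers.shape != self.values.shape:
            raise ValueError("residue_numbers and values length mismatch")
        if not np.all(np.isfinite(self.values)) or np.any(self.values < 0):
            raise ValueError("RMSF values must be finite and >= 0")
        if self.replicate_count < 1:
            raise ValueError("replicate_count must be >= 1")

    def window_mean(self, start: int, end: int) -> float:
        """Mean RMSF over residues in the inclusive range [start, end]."""
        mask = (self.residue_numbers >= start) & (self.residue_numbers <= end)
        if not np.any(mask):
            raise AlignmentError(f"no residues in window {start}-{end}")
        return float(self.values[mask].mean())


@dataclass
class AverageStructure:
    """Coordinate-wise mean of superposed frames over a frame window."""

    structure: Structure
    frame_window: tuple[int, int]
    source_condition: str | None = None

    @property
    def coords(self) -> np.ndarray:
        return self.structure.coords


def _check_window(window, n_frames: int) -> tuple[int, int]:
    start, end = int(window[0]), int(window[1])
    if start > end:
        raise WindowError(f"window start {start} > end {end}")
    if start < 0 or end >= n_frames:
        raise WindowError(
            f"window [{start}, {end}] outside 0..{n_frames - 1}"
        )
    return start, end


def rmsf_profile(
    traj: Trajectory,
    reference: Structure,
    fit_sel: Selection = CA_SELECTION,
) -> RMSFProfile:
    """Per-residue Calpha RMSF after superposing every frame on the reference.

    RMSF_i = sqrt( <|r_i(t) - <r_i>|^2> ), the root-mean-square deviation of
    atom i from its own time-mean position, summed over x, y, z.
    """
    if traj.n_frames < 2:
        raise MDShiftError("RMSF needs at least 2 frames")
    fitted = fit_frames(traj, reference, fit_sel)
    ca = traj.topology.ca_indices()
    if ca.size == 0:
        raise AlignmentError("topology has no CA atoms")
    coords = fitted[:, ca, :]
    mean = coords.mean(axis=0)
    values = np.sqrt(((coords - mean[None]) ** 2).sum(axis=2).mean(axis=0))
    resnums = traj.topology.residue_numbers[ca]
    return RMSFProfile(resnums, values, n_frames=traj.n_frames)


def average_rmsf(profiles: Sequence[RMSFProfile]) -> RMSFProfile:
    """Element-wise mean of replicate RMSF profiles.

    Profiles are aligned by residue number (order-insensitive); differing
    residue sets raise :class:`AlignmentError`.  The result's
    ``replicate_count`` is the sum of the inputs' counts and ``n_frames``
    the total frame count, for bookkeeping.
    """
    if not profiles:
        raise ValueError("need at least one profile")
    ref_order = np.sort(profiles[0].residue_numbers)
    aligned = []
    for p in profiles:
        order = np.argsort(p.residue_numbers, kind="stable")
        resnums = p.residue_numbers[order]
        if not np.array_equal(resnums, ref_order):
            raise AlignmentError("profiles cover different residue sets")
        aligned.append(p.values[order])
    mean = np.mean(aligned, axis=0)
    return RMSFProfile(
        ref_order,
        mean,
        n_frames=sum(p.n_frames for p in profiles),
        replicate_count=sum(p.replicate_count for p in profiles),
    )


def average_structure(
    traj: Trajectory,
    window: tuple[int, int],
    reference: Structure,
    fit_sel: Selection = CA_SELECTION,
    source_condition: str | None = None,
) -> AverageStructure:
    """Mean structure over an inclusive 0-based frame window.

    Every in-window frame is first superposed onto the reference over
    ``fit_sel`` atoms, then coordinates are averaged atom-wise.  Without the
    overlay step, per-frame rigid-body motion would smear the average toward
    the centroid; with it, the average converges on the underlying mean
    conformation.
    """
    start, end = _check_window(window, traj.n_frames)
    fitted = fit_frames(
        traj, reference, fit_sel, frames=traj.frames[start : end + 1]
    )
    mean_coords = fitted.mean(axis=0)
    return AverageStructure(
        traj.topology.with_coords(mean_coords),
        (start, end),
        source_condition=source_condition,
    )
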