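"""Per-residue shift distances between two mean structures and their
saturated [0, 1] mapping.

The statistic: superpose condition B's average structure onto condition A's
over all selected alpha-carbons, take the per-Calpha Euclidean distance
("shift distance"), then map distances to shift values in [0, 1].  The
mapping deliberately saturates: the half of the residues with the largest
distances all receive the value 1, and only the remaining half is spread
over [0, 1).  This keeps a few dramatically displaced regions from
compressing the color scale and hiding small but systematic shifts
elsewhere.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import AlignmentError, MDShiftError
from .ensemble import AverageStructure
from .model import CA_SELECTION, Selection, Structure, resolve_selection
from .superpose import kabsch

__all__ = ["ShiftMap", "shift_distances", "map_shift_values"]


@dataclass
class ShiftMap:
    """Per-residue shift distances (Angstrom) and mapped values in [0, 1]."""

    residue_numbers: np.ndarray
    shift_distance: np.ndarray
    shift_value: np.ndarray
    saturated: np.ndarray

    def __post_init__(self):
        self.residue_numbers = np.asarray(self.residue_numbers, dtype=int)
        self.shift_distance = np.asarray(self.shift_distance, dtype=float)
        self.shift_value = np.asarray(self.shift_value, dtype=float)
        self.saturated = np.asarray(self.saturated, dtype=bool)
        n = self.residue_numbers.size
        if not (
            self.shift_distance.size
            == self.shift_value.size
            == self.saturated.size
            == n
        ):
            raise ValueError("field lengths mismatch")
        if not np.array_equal(self.saturated, self.shift_value == 1.0):
            raise ValueError("saturated flag must mark exactly the values == 1")
        unsat = self.shift_value[~self.saturated]
        if unsat.size and (np.any(unsat < 0) or np.any(unsat >= 1)):
            raise ValueError("non-saturated shift values must lie in [0, 1)")

    def as_value_map(self) -> dict[int, float]:
        return {
            int(r): float(v)
            for r, v in zip(self.residue_numbers, self.shift_value)
        }


def _structure_of(obj) -> Structure:
    return obj.structure if isinstance(obj, AverageStructure) else obj


def shift_distances(
    avg_a,
    avg_b,
    fit_sel: Selection = CA_SELECTION,
) -> tuple[np.ndarray, np.ndarray]:
    """Per-Calpha displacement between two (average) structures.

    ``avg_b`` is superposed onto ``avg_a`` over all ``fit_sel`` atoms
    (optimal rigid overlay), then for each selected atom the Euclidean
    distance is taken.  Returns ``(residue_numbers, distances)``.
    """
    sa = _structure_of(avg_a)
    sb = _structure_of(avg_b)
    idx_a = resolve_selection(sa, fit_sel)
    idx_b = resolve_selection(sb, fit_sel)
    if idx_a.shape != idx_b.shape or not np.array_equal(
        sa.residue_numbers[idx_a], sb.residue_numbers[idx_b]
    ):
        raise AlignmentError("selections resolve to different residue sets")
    ca = sa.coords[idx_a]
    cb = sb.coords[idx_b]
    fit = kabsch(cb, ca)
    dist = np.linalg.norm(fit.apply(cb) - ca, axis=1)
    return sa.residue_numbers[idx_a], dist


def map_shift_values(
    distances: np.ndarray,
    residue_numbers: np.ndarray | None = None,
    variant: str = "rank",
) -> ShiftMap:
    """Map shift distances to saturated shift values in [0, 1].

    The k = floor(N/2) largest distances saturate at 1.  The remaining
    m = N - k distances are sorted ascending and mapped to [0, 1):

    - ``variant="rank"`` (default): equal rank spacing, the i-th smallest
      (1-based) gets (i - 1) / m — robust to the distance scale entirely.
    - ``variant="minmax"``: linear in the distance value between the
      smallest unsaturated distance and the saturation threshold (the
      smallest saturated distance), clipped just below 1 on boundary ties.

    Ties are broken stably by position (residue order), so with all
    distances equal exactly k entries saturate and they are the
    highest-positioned ones.
    """
    distances = np.asarray(distances, dtype=float)
    n = distances.size
    if n < 2:
        raise MDShiftError("need at least 2 distances")
    if not np.all(np.isfinite(distances)) or np.any(distances < 0):
        raise ValueError("distances must be finite and >= 0")
    if residue_numbers is None:
        residue_numbers = np.arange(1, n + 1)
    residue_numbers = np.asarray(residue_numbers, dtype=int)
    if residue_numbers.size != n:
        raise ValueError("residue_numbers length mismatch")

    k = n // 2
    m = n - k
    order = np.argsort(distances, kind="stable")  # ascending, stable ties
    values = np.empty(n, dtype=float)
    values[order[m:]] = 1.0
    unsat = order[:m]
    if variant == "rank":
        values[unsat] = np.arange(m) / m
    elif variant == "minmax":
        d = distances[unsat]
        threshold = distances[order[m]] if k > 0 else d.max()
        span = threshold - d.min()
        if span <= 0:
            values[unsat] = 0.0
        else:
            v = (d - d.min()) / span
            # boundary ties with the threshold stay just below saturation
            values[unsat] = np.where(v >= 1.0, np.nextafter(1.0, 0.0), v)
    else:
        raise ValueError(f"unknown variant {variant!r}")
    saturated = values == 1.0
    return ShiftMap(residue_numbers, distances, values, saturated)
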