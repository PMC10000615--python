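"""Core in-memory containers: atoms, structures, trajectories, selections.

Coordinates are in Angstrom throughout.  Residue numbering is 1-based author
numbering and is preserved verbatim; nothing in the package renumbers.
"""
from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from .errors import SelectionError

# Bondi-style van der Waals radii (Angstrom).  Unknown elements fall back to
# DEFAULT_VDW_RADIUS with a warning.
VDW_RADII = {
    "H": 1.20,
    "C": 1.70,
    "N": 1.55,
    "O": 1.52,
    "F": 1.47,
    "P": 1.80,
    "S": 1.80,
    "CL": 1.75,
    "BR": 1.85,
    "I": 1.98,
    "SE": 1.90,
    "ZN": 1.39,
    "MG": 1.73,
    "NA": 2.27,
    "K": 2.75,
    "CA2": 2.31,  # calcium ion; "CA" the element collides with the atom name
    "FE": 1.52,
}
DEFAULT_VDW_RADIUS = 1.5


def vdw_radius(element: str) -> float:
    """Van der Waals radius for an element symbol (case-insensitive)."""
    key = element.strip().upper()
    if key in VDW_RADII:
        return VDW_RADII[key]
    warnings.warn(
        f"unknown element {element!r}: using default vdW radius "
        f"{DEFAULT_VDW_RADIUS} A",
        stacklevel=2,
    )
    return DEFAULT_VDW_RADIUS


@dataclass(frozen=True)
class Atom:
    """One atom of a topology.

    ``vdw_radius`` is carried explicitly so callers may override the
    element-table value (e.g. for synthetic cage pseudo-atoms); it is not
    representable in PDB output and reverts to the table on re-read.
    """

    serial: int
    atom_name: str
    residue_name: str
    chain_id: str
    residue_number: int
    element: str
    vdw_radius: float

    def __post_init__(self):
        if self.vdw_radius <= 0:
            raise ValueError("vdw_radius must be positive")


@dataclass
class Structure:
    """A fixed topology plus one coordinate set (N, 3) in Angstrom."""

    atoms: tuple[Atom, ...]
    coords: np.ndarray

    def __post_init__(self):
        self.atoms = tuple(self.atoms)
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.shape != (len(self.atoms), 3):
            raise ValueError(
                f"coords shape {self.coords.shape} does not match "
                f"{len(self.atoms)} atoms"
            )
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("coordinates must be finite")
        keys = [(a.chain_id, a.residue_number, a.atom_name) for a in self.atoms]
        if len(set(keys)) != len(keys):
            raise ValueError(
                "(chain_id, residue_number, atom_name) must be unique"
            )

    def __len__(self) -> int:
        return len(self.atoms)

    @property
    def residue_numbers(self) -> np.ndarray:
        return np.array([a.residue_number for a in self.atoms], dtype=int)

    @property
    def atom_names(self) -> list[str]:
        return [a.atom_name for a in self.atoms]

    @property
    def vdw_radii(self) -> np.ndarray:
        return np.array([a.vdw_radius for a in self.atoms], dtype=float)

    def ca_indices(self) -> np.ndarray:
        """Indices of alpha-carbon atoms (atom_name exactly "CA")."""
        return np.array(
            [i for i, a in enumerate(self.atoms) if a.atom_name == "CA"],
            dtype=int,
        )

    def with_coords(self, coords: np.ndarray) -> "Structure":
        return Structure(self.atoms, coords)


@dataclass
class Trajectory:
    """Ordered coordinate frames (F, N, 3) over a fixed topology.

    ``time_per_frame`` (ns) maps frame indices to simulated time; it is
    optional and purely metadata.
    """

    topology: Structure
    frames: np.ndarray
    time_per_frame: float | None = None

    def __post_init__(self):
        self.frames = np.asarray(self.frames, dtype=float)
        if self.frames.ndim != 3 or self.frames.shape[1:] != (
            len(self.topology),
            3,
        ):
            raise ValueError(
                f"frames shape {self.frames.shape} does not match topology "
                f"of {len(self.topology)} atoms"
            )
        if self.frames.shape[0] < 1:
            raise ValueError("trajectory needs at least one frame")
        if self.time_per_frame is not None and self.time_per_frame < 0:
            raise ValueError("time_per_frame must be >= 0")

    @property
    def n_frames(self) -> int:
        return int(self.frames.shape[0])

    def times_ns(self) -> np.ndarray:
        dt = self.time_per_frame if self.time_per_frame is not None else 1.0
        return np.arange(self.n_frames) * dt


_RANGE_RE = re.compile(r"^(-?\d+)(?:-(-?\d+))?$")


@dataclass(frozen=True)
class Selection:
    """Residue-range + atom-name selection.

    ``residue_ranges`` are inclusive (start, end) pairs of author residue
    numbers; an empty tuple selects every residue.  ``atom_names`` empty
    selects every atom of the selected residues.
    """

    residue_ranges: tuple[tuple[int, int], ...] = ()
    atom_names: frozenset[str] = frozenset()

    def __post_init__(self):
        object.__setattr__(
            self, "residue_ranges", tuple(tuple(r) for r in self.residue_ranges)
        )
        object.__setattr__(self, "atom_names", frozenset(self.atom_names))
        for start, end in self.residue_ranges:
            if start > end:
                raise ValueError(f"range start {start} > end {end}")

    @classmethod
    def from_string(cls, text: str) -> "Selection":
        """Parse a compact selection string such as ``"118-125,203-211:CA"``.

        Grammar: comma-separated inclusive residue ranges (``start-end`` or a
        single number), optionally followed by ``:`` and comma-separated atom
        names.  ``"all"`` or an empty range part selects every residue.
        """
        text = text.strip()
        if ":" in text:
            range_part, name_part = text.split(":", 1)
            names = frozenset(
                n.strip() for n in name_part.split(",") if n.strip()
            )
        else:
            range_part, names = text, frozenset()
        range_part = range_part.strip()
        ranges: list[tuple[int, int]] = []
        if range_part and range_part.lower() != "all":
            for token in range_part.split(","):
                token = token.strip()
                m = _RANGE_RE.match(token)
                if not m:
                    raise ValueError(f"cannot parse residue range {token!r}")
                start = int(m.group(1))
                end = int(m.group(2)) if m.group(2) is not None else start
                ranges.append((start, end))
        return cls(tuple(ranges), names)

    def to_string(self) -> str:
        if self.residue_ranges:
            rng = ",".join(
                f"{s}-{e}" if s != e else str(s)
                for s, e in self.residue_ranges
            )
        else:
            rng = "all"
        if self.atom_names:
            return rng + ":" + ",".join(sorted(self.atom_names))
        return rng


CA_SELECTION = Selection(atom_names=frozenset({"CA"}))
BACKBONE_SELECTION = Selection(atom_names=frozenset({"N", "CA", "C", "O"}))


def resolve_selection(structure: Structure, sel: Selection) -> np.ndarray:
    """Resolve a :class:`Selection` to atom indices in topology order.

    The result is duplicate-free and strictly increasing.  Raises
    :class:`SelectionError` when nothing matches.
    """
    if len(structure) == 0:
        raise SelectionError("structure is empty")
    resnums = structure.residue_numbers
    if sel.residue_ranges:
        mask = np.zeros(len(structure), dtype=bool)
        for start, end in sel.residue_ranges:
            mask |= (resnums >= start) & (resnums <= end)
    else:
        mask = np.ones(len(structure), dtype=bool)
    if sel.atom_names:
        names = np.array(structure.atom_names)
        mask &= np.isin(names, sorted(sel.atom_names))
    indices = np.nonzero(mask)[0]
    if indices.size == 0:
        raise SelectionError(f"selection {sel.to_string()!r} matched no atoms")
    return indices
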