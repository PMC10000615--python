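"""PDB reading/writing behind the package's containers.

Multi-model PDB is the canonical trajectory interchange format here: it is
plain text, bit-inspectable and diffable, which matters more for ensemble
fixtures than compactness.  Parsing and formatting of the fixed-column
records is delegated to biotite; this module only converts to and from the
:class:`~mdshift.model.Structure` / :class:`~mdshift.model.Trajectory`
containers and applies the package's conventions (first altloc wins, vdW
radii from the bundled element table, per-residue scalar annotations in the
B-factor column).
"""
from __future__ import annotations

import io
import os
from pathlib import Path
from typing import Mapping

import numpy as np
import biotite.structure as struc
import biotite.structure.io.pdb as pdb

from .errors import FormatError, SelectionError
from .model import Atom, Structure, Trajectory, vdw_radius

__all__ = [
    "read_structure",
    "read_trajectory",
    "write_structure",
    "write_trajectory",
    "write_annotated_pdb",
    "read_bfactor_annotations",
]


def _as_text(source) -> str:
    """Accept raw PDB text, a path, or a file-like object."""
    if hasattr(source, "read"):
        return source.read()
    if isinstance(source, (Path, os.PathLike)):
        return Path(source).read_text()
    text = str(source)
    # Heuristic: a path has no newline and exists on disk.
    if "\n" not in text and os.path.exists(text):
        return Path(text).read_text()
    return text


def _infer_element(atom_name: str) -> str:
    stripped = "".join(c for c in atom_name if c.isalpha())
    return stripped[:1].upper() if stripped else "C"


def _parse(source) -> struc.AtomArrayStack:
    text = _as_text(source)
    if not any(
        line.startswith(("ATOM", "HETATM")) for line in text.splitlines()
    ):
        raise FormatError("no ATOM/HETATM records found")
    try:
        pdb_file = pdb.PDBFile.read(io.StringIO(text))
        stack = pdb_file.get_structure(
            model=None, altloc="first", extra_fields=["atom_id", "b_factor"]
        )
    except FormatError:
        raise
    except Exception as exc:  # biotite raises InvalidFileError subclasses
        raise FormatError(f"cannot parse PDB input: {exc}") from exc
    return stack


def _atoms_from_array(arr: struc.AtomArray) -> tuple[Atom, ...]:
    atoms = []
    for i in range(arr.array_length()):
        element = str(arr.element[i]).strip() or _infer_element(
            str(arr.atom_name[i])
        )
        atoms.append(
            Atom(
                serial=int(arr.atom_id[i]),
                atom_name=str(arr.atom_name[i]).strip(),
                residue_name=str(arr.res_name[i]).strip(),
                chain_id=str(arr.chain_id[i]).strip() or "A",
                residue_number=int(arr.res_id[i]),
                element=element,
                vdw_radius=vdw_radius(element),
            )
        )
    return tuple(atoms)


def read_structure(source, chain: str | None = None) -> Structure:
    """Read one structure (first model) from PDB text or a path.

    ``chain`` keeps only that chain's atoms, in file order; ``None`` keeps
    everything.  Raises :class:`FormatError` for record-free input and
    :class:`SelectionError` when the requested chain is absent.
    """
    stack = _parse(source)
    arr = stack[0]
    if chain is not None:
        mask = arr.chain_id == chain
        if not np.any(mask):
            present = sorted(set(arr.chain_id))
            raise SelectionError(
                f"chain {chain!r} not present (chains: {present})"
            )
        arr = arr[mask]
    return Structure(_atoms_from_array(arr), np.array(arr.coord, dtype=float))


def read_trajectory(source, time_per_frame: float | None = None) -> Trajectory:
    """Read a multi-model PDB as a trajectory (one frame per MODEL).

    A file without MODEL records yields a one-frame trajectory.  Models with
    inconsistent atom counts raise :class:`FormatError`.
    """
    stack = _parse(source)
    topo = Structure(
        _atoms_from_array(stack[0]), np.array(stack[0].coord, dtype=float)
    )
    frames = np.array(stack.coord, dtype=float)
    return Trajectory(topo, frames, time_per_frame=time_per_frame)


def _to_atom_array(structure: Structure, b_factors=None) -> struc.AtomArray:
    n = len(structure)
    arr = struc.AtomArray(n)
    arr.coord = np.asarray(structure.coords, dtype=np.float32)
    arr.chain_id = np.array([a.chain_id for a in structure.atoms])
    arr.res_id = np.array(
        [a.residue_number for a in structure.atoms], dtype=int
    )
    arr.res_name = np.array([a.residue_name for a in structure.atoms])
    arr.atom_name = np.array([a.atom_name for a in structure.atoms])
    arr.element = np.array([a.element for a in structure.atoms])
    arr.hetero = np.zeros(n, dtype=bool)
    arr.set_annotation(
        "atom_id", np.array([a.serial for a in structure.atoms], dtype=int)
    )
    if b_factors is None:
        b_factors = np.zeros(n)
    arr.set_annotation("b_factor", np.asarray(b_factors, dtype=float))
    return arr


def _render(obj) -> str:
    pdb_file = pdb.PDBFile()
    pdb_file.set_structure(obj)
    buf = io.StringIO()
    pdb_file.write(buf)
    return buf.getvalue()


def write_structure(structure: Structure, path=None) -> str:
    """Serialize a structure to single-model PDB text (optionally to a file)."""
    text = _render(_to_atom_array(structure))
    if path is not None:
        Path(path).write_text(text)
    return text


def write_trajectory(traj: Trajectory, path=None) -> str:
    """Serialize a trajectory to multi-model PDB text (optionally to a file)."""
    arr = _to_atom_array(traj.topology)
    n = traj.n_frames
    stack = struc.stack([arr] * n)
    stack.coord = np.asarray(traj.frames, dtype=np.float32)
    text = _render(stack)
    if path is not None:
        Path(path).write_text(text)
    return text


def write_annotated_pdb(
    structure: Structure,
    per_residue_values: Mapping[int, float],
    path=None,
) -> str:
    """Write a PDB with per-residue scalar values in the B-factor column.

    Every atom of an annotated residue carries the residue's value (two
    decimals, PDB B-factor precision); residues without a value get 0.00.
    Values must lie in [0, 1] — the column is meant for normalized scores
    such as shift values, which visualization tools map to color.
    """
    for res, val in per_residue_values.items():
        if not (0.0 <= float(val) <= 1.0):
            raise ValueError(
                f"value {val} for residue {res} outside [0, 1]"
            )
    b = np.array(
        [
            float(per_residue_values.get(a.residue_number, 0.0))
            for a in structure.atoms
        ]
    )
    text = _render(_to_atom_array(structure, b_factors=b))
    if path is not None:
        Path(path).write_text(text)
    return text


def read_bfactor_annotations(source) -> dict[int, float]:
    """Recover a per-residue value map from an annotated PDB's B-factors.

    The first atom of each residue defines the residue's value.
    """
    stack = _parse(source)
    arr = stack[0]
    values: dict[int, float] = {}
    for i in range(arr.array_length()):
        res = int(arr.res_id[i])
        values.setdefault(res, float(arr.b_factor[i]))
    return values
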