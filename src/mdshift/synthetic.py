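"""Seeded generator of two-condition, multi-replicate toy ensembles.

The generator emulates, with known ground truth, every statistical feature
the downstream analysis probes:

- a Calpha-only toy chain ("helix" or "line" base geometry, 3.8 A spacing);
- independent per-frame Gaussian positional noise with a per-residue sigma
  (per axis), elevated inside declared flexible windows;
- an optional slow displacement event: a residue window ramps linearly to a
  target offset across a frame window, then holds;
- optional per-frame global rigid-body motion (uniform SO(3) rotations via
  normalized quaternions, plus Gaussian translations) which superposition-
  based statistics must remove;
- an optional rigid spherical atom cage enclosing an empty cavity of known
  radius, standing in for a binding pocket.

This is deliberately non-physical — no force field, no autocorrelated
dynamics — because it is an oracle for the analysis code, not a simulator.
Replicate r draws from seed + r; local-noise and global-motion streams are
separate so toggling global motion never changes the local draws.
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from .errors import SpecValidationError
from .model import Atom, Structure, Trajectory

__all__ = [
    "PocketCage",
    "DisplacementEvent",
    "SyntheticSpec",
    "ConditionSet",
    "base_structure",
    "generate_condition",
    "paired_experiment",
]

CA_SPACING = 3.8  # Angstrom between consecutive Calpha in the toy chain
# Ideal alpha-helix Calpha trace: ~100 deg turn and 1.5 A rise per residue;
# radius chosen so consecutive Calpha sit CA_SPACING apart.
HELIX_TURN = np.deg2rad(100.0)
HELIX_RISE = 1.5


@dataclass(frozen=True)
class PocketCage:
    """Rigid spherical shell of pseudo-atoms enclosing an empty cavity.

    Atom centers sit on a sphere of ``cage_radius`` around ``center``; each
    pseudo-atom carries vdW radius (cage_radius - cavity_radius), so at
    probe radius 0 the enclosed free void is a ball of ``cavity_radius``.
    """

    center: tuple[float, float, float]
    cage_radius: float
    cavity_radius: float
    atom_count: int = 350

    def __post_init__(self):
        if not (0 < self.cavity_radius < self.cage_radius):
            raise SpecValidationError(
                "need 0 < cavity_radius < cage_radius"
            )
        if self.atom_count < 20:
            raise SpecValidationError("cage needs at least 20 atoms")


@dataclass(frozen=True)
class DisplacementEvent:
    """Linear ramp of a residue window to a target offset, then hold."""

    residue_range: tuple[int, int]
    offset: tuple[float, float, float]
    frame_range: tuple[int, int]


@dataclass(frozen=True)
class SyntheticSpec:
    """Full description of one synthetic condition (see module docstring)."""

    n_residues: int
    n_frames: int
    seed: int
    base_geometry: str = "helix"
    sigma: float = 0.25  # base per-axis positional noise, Angstrom
    flexible_windows: tuple = ()  # ((start, end), sigma_multiplier), ...
    displacement_event: DisplacementEvent | None = None
    global_motion: bool = True
    global_translation_sigma: float = 3.0  # Angstrom, per axis
    pocket_cage: PocketCage | None = None
    replicates: int = 2
    time_per_frame: float | None = None  # ns

    def __post_init__(self):
        if self.n_residues < 10:
            raise SpecValidationError("need n_residues >= 10")
        if self.n_frames < 2:
            raise SpecValidationError("need n_frames >= 2")
        if self.replicates < 1:
            raise SpecValidationError("need replicates >= 1")
        if self.sigma < 0:
            raise SpecValidationError("sigma must be >= 0")
        if self.base_geometry not in ("helix", "line"):
            raise SpecValidationError(
                f"unknown base_geometry {self.base_geometry!r}"
            )
        for (start, end), mult in self.flexible_windows:
            if start > end or mult < 0:
                raise SpecValidationError("invalid flexible window")
        ev = self.displacement_event
        if ev is not None:
            f0, f1 = ev.frame_range
            if not (0 <= f0 <= f1 < self.n_frames):
                raise SpecValidationError("event frame range out of bounds")

    def sigma_profile(self) -> np.ndarray:
        """Per-residue, per-axis noise amplitude in Angstrom."""
        prof = np.full(self.n_residues, float(self.sigma))
        for (start, end), mult in self.flexible_windows:
            lo = max(start - 1, 0)
            hi = min(end, self.n_residues)
            prof[lo:hi] *= mult
        return prof


@dataclass
class ConditionSet:
    """One labeled condition: replicate trajectories over a shared topology."""

    label: str
    replicates: list[Trajectory]
    spec: SyntheticSpec
    base: Structure

    def __post_init__(self):
        if len(self.replicates) != self.spec.replicates:
            raise SpecValidationError("replicate count does not match spec")


def _chain_coords(spec: SyntheticSpec) -> np.ndarray:
    n = spec.n_residues
    i = np.arange(n)
    if spec.base_geometry == "line":
        return np.stack(
            [i * CA_SPACING, np.zeros(n), np.zeros(n)], axis=1
        )
    radius = np.sqrt(
        (CA_SPACING**2 - HELIX_RISE**2) / (2 * (1 - np.cos(HELIX_TURN)))
    )
    return np.stack(
        [
            radius * np.cos(i * HELIX_TURN),
            radius * np.sin(i * HELIX_TURN),
            i * HELIX_RISE,
        ],
        axis=1,
    )


def _fibonacci_sphere(n: int) -> np.ndarray:
    """Near-uniform unit-sphere point set (Fibonacci lattice)."""
    i = np.arange(n) + 0.5
    phi = np.arccos(1 - 2 * i / n)
    theta = np.pi * (1 + np.sqrt(5)) * i
    return np.stack(
        [
            np.sin(phi) * np.cos(theta),
            np.sin(phi) * np.sin(theta),
            np.cos(phi),
        ],
        axis=1,
    )


def base_structure(spec: SyntheticSpec) -> Structure:
    """Noise-free base topology+coordinates, chain then (optional) cage."""
    coords = _chain_coords(spec)
    atoms = [
        Atom(
            serial=i + 1,
            atom_name="CA",
            residue_name="ALA",
            chain_id="A",
            residue_number=i + 1,
            element="C",
            vdw_radius=1.70,
        )
        for i in range(spec.n_residues)
    ]
    cage = spec.pocket_cage
    if cage is not None:
        shell = (
            np.asarray(cage.center)
            + cage.cage_radius * _fibonacci_sphere(cage.atom_count)
        )
        r_atom = cage.cage_radius - cage.cavity_radius
        for j in range(cage.atom_count):
            atoms.append(
                Atom(
                    serial=spec.n_residues + j + 1,
                    atom_name="C",
                    residue_name="CAG",
                    chain_id="A",
                    residue_number=spec.n_residues + j + 1,
                    element="C",
                    vdw_radius=r_atom,
                )
            )
        coords = np.vstack([coords, shell])
    return Structure(tuple(atoms), coords)


def _event_ramp(ev: DisplacementEvent, n_frames: int) -> np.ndarray:
    f0, f1 = ev.frame_range
    t = np.arange(n_frames, dtype=float)
    if f1 == f0:
        return (t >= f0).astype(float)
    return np.clip((t - f0) / (f1 - f0), 0.0, 1.0)


def _random_rotations(rng: np.random.Generator, n: int) -> np.ndarray:
    """n uniform SO(3) rotations from normalized Gaussian quaternions."""
    q = rng.standard_normal((n, 4))
    q /= np.linalg.norm(q, axis=1, keepdims=True)
    w, x, y, z = q.T
    return np.stack(
        [
            np.stack([1 - 2 * (y * y + z * z), 2 * (x * y - z * w), 2 * (x * z + y * w)], axis=1),
            np.stack([2 * (x * y + z * w), 1 - 2 * (x * x + z * z), 2 * (y * z - x * w)], axis=1),
            np.stack([2 * (x * z - y * w), 2 * (y * z + x * w), 1 - 2 * (x * x + y * y)], axis=1),
        ],
        axis=1,
    )


def _generate_replicate(
    spec: SyntheticSpec, base: Structure, replicate: int
) -> Trajectory:
    noise_rng = np.random.default_rng([spec.seed + replicate, 0])
    motion_rng = np.random.default_rng([spec.seed + replicate, 1])
    nres = spec.n_residues
    natoms = len(base)
    frames = np.broadcast_to(
        base.coords, (spec.n_frames, natoms, 3)
    ).copy()

    sigma = spec.sigma_profile()
    if np.any(sigma > 0):
        noise = noise_rng.standard_normal((spec.n_frames, nres, 3))
        frames[:, :nres, :] += noise * sigma[None, :, None]

    ev = spec.displacement_event
    if ev is not None:
        ramp = _event_ramp(ev, spec.n_frames)
        lo = max(ev.residue_range[0] - 1, 0)
        hi = min(ev.residue_range[1], nres)
        frames[:, lo:hi, :] += (
            ramp[:, None, None] * np.asarray(ev.offset)[None, None, :]
        )

    if spec.global_motion:
        rot = _random_rotations(motion_rng, spec.n_frames)
        trans = motion_rng.standard_normal(
            (spec.n_frames, 3)
        ) * spec.global_translation_sigma
        frames = (
            np.einsum("fij,fnj->fni", rot, frames) + trans[:, None, :]
        )

    return Trajectory(base, frames, time_per_frame=spec.time_per_frame)


def generate_condition(spec: SyntheticSpec, label: str = "cond") -> ConditionSet:
    """Generate all replicates of one condition, deterministically from seed."""
    base = base_structure(spec)
    reps = [
        _generate_replicate(spec, base, r) for r in range(spec.replicates)
    ]
    return ConditionSet(label, reps, spec, base)


def _spec_deltas(spec_a: SyntheticSpec, spec_b: SyntheticSpec) -> list[dict]:
    """Manifest of declared differences between two condition specs."""
    deltas: list[dict] = []
    wins_a = {tuple(w): m for w, m in spec_a.flexible_windows}
    wins_b = {tuple(w): m for w, m in spec_b.flexible_windows}
    for win in sorted(set(wins_a) | set(wins_b)):
        ma = wins_a.get(win, 1.0)
        mb = wins_b.get(win, 1.0)
        if ma != mb:
            deltas.append(
                {
                    "kind": "rmsf_window",
                    "residues": f"{win[0]}-{win[1]}",
                    "magnitude": mb / ma if ma else float("inf"),
                    "lower_in": "b" if mb < ma else "a",
                }
            )
    if spec_a.sigma != spec_b.sigma:
        deltas.append(
            {
                "kind": "base_sigma",
                "residues": "all",
                "magnitude": spec_b.sigma - spec_a.sigma,
                "lower_in": "b" if spec_b.sigma < spec_a.sigma else "a",
            }
        )
    for name, ev, present_in in (
        ("a", spec_a.displacement_event, "a"),
        ("b", spec_b.displacement_event, "b"),
    ):
        other = spec_b if name == "a" else spec_a
        if ev is not None and ev != other.displacement_event:
            deltas.append(
                {
                    "kind": "distance_event",
                    "residues": f"{ev.residue_range[0]}-{ev.residue_range[1]}",
                    "frames": f"{ev.frame_range[0]}-{ev.frame_range[1]}",
                    "magnitude": float(np.linalg.norm(ev.offset)),
                    "present_in": present_in,
                }
            )
    ca, cb = spec_a.pocket_cage, spec_b.pocket_cage
    if ca is not None and cb is not None and ca.cavity_radius != cb.cavity_radius:
        deltas.append(
            {
                "kind": "cavity",
                "magnitude": cb.cavity_radius - ca.cavity_radius,
                "smaller_in": "b" if cb.cavity_radius < ca.cavity_radius else "a",
            }
        )
    return deltas


def paired_experiment(
    spec_a: SyntheticSpec,
    spec_b: SyntheticSpec,
    labels: tuple[str, str] = ("a", "b"),
) -> tuple[ConditionSet, ConditionSet, list[dict]]:
    """Generate two conditions over a shared base and list their deltas.

    The returned manifest enumerates every declared difference between the
    specs (flexibility windows, displacement events, cavity size) so that
    recovery tests can check the analysis finds exactly what was injected.
    """
    if (
        spec_a.n_residues != spec_b.n_residues
        or spec_a.base_geometry != spec_b.base_geometry
    ):
        raise SpecValidationError(
            "paired conditions need equal n_residues and base geometry"
        )
    cond_a = generate_condition(spec_a, labels[0])
    cond_b = generate_condition(spec_b, labels[1])
    return cond_a, cond_b, _spec_deltas(spec_a, spec_b)
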