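import numpy as np
import pytest

from mdshift.model import Atom, Structure
from mdshift.synthetic import SyntheticSpec, base_structure


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


def make_ca_chain(n_residues: int, geometry: str = "helix") -> Structure:
    """Noise-free Calpha-only toy chain."""
    spec = SyntheticSpec(
        n_residues=n_residues, n_frames=2, seed=0, base_geometry=geometry
    )
    return base_structure(spec)


def make_cage_structure(
    shell_radius: float, atom_radius: float, n_atoms: int = 3000
) -> Structure:
    """Spherical shell of uniform pseudo-atoms around the origin.

    Free interior cavity radius = shell_radius - atom_radius (probe 0).
    """
    from .oracles import golden_sphere

    centers = shell_radius * golden_sphere(n_atoms)
    atoms = tuple(
        Atom(i + 1, "C", "CAG", "A", i + 1, "C", atom_radius)
        for i in range(n_atoms)
    )
    return Structure(atoms, centers)


@pytest.fixture
def helix20() -> Structure:
    return make_ca_chain(20)
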