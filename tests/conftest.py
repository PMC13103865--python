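import numpy as np
import pytest

import xanthsol as xs
from xanthsol.frames import MolecularFrame, Species


@pytest.fixture
def templates():
    return xs.default_templates()


def make_point_frame(points, roles, box_edge, species_prefix="P"):
    """Frame of single-atom molecules at given points (census-style tests)."""
    points = np.asarray(points, dtype=float)
    names = []
    species = {}
    for role in set(roles):
        name = f"{species_prefix}{role[:2].upper()}"
        species[name] = Species(name=name, role=role)
        names.append(name)
    mol_species = [f"{species_prefix}{r[:2].upper()}" for r in roles]
    return MolecularFrame(
        coords=points, elements=["C"] * len(points),
        atom_mol=np.arange(len(points)), mol_species=mol_species,
        species=species, box_edge=box_edge)


@pytest.fixture
def flat_ring_frame():
    """One 4-atom flat square 'ring' molecule in the xy-plane, plus box."""
    sp = Species(name="SQ", role="xanthine", plane_atoms=(0, 1, 2, 3),
                 aromatic=True)
    coords = np.array([[1.0, 0, 0], [0, 1.0, 0], [-1.0, 0, 0], [0, -1.0, 0]])
    return MolecularFrame(coords=coords, elements=["C"] * 4,
                          atom_mol=np.zeros(4, dtype=int), mol_species=["SQ"],
                          species={"SQ": sp}, box_edge=20.0)


def random_fibril_spec(seed, box_edge=40.0, tilt_sd=0.0, jitter_sd=0.0):
    """A seeded mixed xanthine/agent fibril box used by recovery checks."""
    rng = np.random.default_rng(seed)
    plans = []
    for _ in range(int(rng.integers(2, 5))):
        k = int(rng.integers(3, 7))
        plans.append(tuple(rng.choice(["XAN", "BZA", "PYA"], size=k,
                                      p=[0.6, 0.2, 0.2])))
    return xs.BoxSpec(
        box_edge=box_edge, fibril_plan=plans,
        n_free_xanthine=int(rng.integers(0, 5)),
        n_free_agent=int(rng.integers(0, 4)),
        tilt_sd=tilt_sd, lateral_jitter_sd=jitter_sd, seed=seed)
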