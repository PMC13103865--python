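"""Geometry primitives and trajectory I/O round trips."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import xanthsol as xs
from xanthsol.frames import (
    Species, minimum_image, molecule_com, plane_normal,
    read_species_map, write_species_map,
)
from conftest import make_point_frame


# ---------------------------------------------------------------------------
# minimum image
# ---------------------------------------------------------------------------

def test_minimum_image_wraps_across_boundary():
    d = minimum_image(np.array([1.0, 0, 0]), np.array([9.0, 0, 0]), 10.0)
    assert np.linalg.norm(d) == pytest.approx(2.0)
    assert np.allclose(minimum_image(np.ones(3), np.ones(3), 10.0), 0.0)


def test_minimum_image_components_in_half_open_interval():
    # the L/2 tie goes to +L/2, not -L/2
    d = minimum_image(np.zeros(3), np.array([5.0, -5.0, 2.5]), 10.0)
    assert np.allclose(d, [5.0, 5.0, 2.5])


@settings(max_examples=200, deadline=None, derandomize=True)
@given(st.integers(0, 10_000))
def test_minimum_image_matches_27_image_brute_force(seed):
    rng = np.random.default_rng(seed)
    L = float(rng.uniform(2.0, 50.0))
    a, b = rng.uniform(-2 * L, 2 * L, size=(2, 3))
    d = minimum_image(a, b, L)
    shifts = np.array([(i, j, k) for i in (-1, 0, 1) for j in (-1, 0, 1)
                       for k in (-1, 0, 1)], dtype=float) * L
    base = (b % L) - (a % L)
    brute = min(np.linalg.norm(base + s) for s in shifts)
    assert np.linalg.norm(d) == pytest.approx(brute, abs=1e-9)
    assert np.linalg.norm(d) <= L * np.sqrt(3) / 2 + 1e-9
    # antisymmetry of the magnitude
    assert np.linalg.norm(minimum_image(b, a, L)) == pytest.approx(
        np.linalg.norm(d), abs=1e-9)


# ---------------------------------------------------------------------------
# molecule centres
# ---------------------------------------------------------------------------

def _two_atom_frame(x0, x1, L=10.0):
    sp = Species(name="D2", role="agent")
    return xs.MolecularFrame(
        coords=np.array([[x0, 0, 0], [x1, 0, 0]]), elements=["C", "C"],
        atom_mol=np.zeros(2, dtype=int), mol_species=["D2"],
        species={"D2": sp}, box_edge=L)


def test_com_is_midpoint():
    assert np.allclose(molecule_com(_two_atom_frame(0.0, 2.0), 0), [1, 0, 0])


def test_com_unwraps_molecule_split_across_boundary():
    com = molecule_com(_two_atom_frame(9.5, 0.5), 0)
    # the unwrapped centre is at x = 10 = 0 (mod L), never the naive 5.0
    assert com[0] % 10.0 == pytest.approx(0.0, abs=1e-9)


@settings(max_examples=50, deadline=None, derandomize=True)
@given(st.integers(0, 10_000))
def test_com_translation_invariance_mod_box(seed):
    rng = np.random.default_rng(seed)
    f = _two_atom_frame(*rng.uniform(0, 10, 2))
    shift = rng.uniform(-30, 30, 3)
    g = xs.MolecularFrame(
        coords=(f.coords + shift) % 10.0, elements=f.elements,
        atom_mol=f.atom_mol, mol_species=f.mol_species, species=f.species,
        box_edge=10.0)
    d = (molecule_com(g, 0) - molecule_com(f, 0) - shift) % 10.0
    assert np.allclose(np.minimum(d, 10.0 - d), 0.0, atol=1e-9)


def test_mass_weighted_com_differs_for_heteroatoms():
    sp = Species(name="CO", role="agent")
    f = xs.MolecularFrame(
        coords=np.array([[0.0, 0, 0], [2.0, 0, 0]]), elements=["C", "O"],
        atom_mol=np.zeros(2, dtype=int), mol_species=["CO"],
        species={"CO": sp}, box_edge=20.0)
    assert molecule_com(f, 0, mass_weighted=True)[0] > \
        molecule_com(f, 0)[0]


# ---------------------------------------------------------------------------
# plane normals
# ---------------------------------------------------------------------------

def test_plane_normal_of_flat_xy_ring_is_z(flat_ring_frame):
    n = plane_normal(flat_ring_frame, 0)
    assert np.allclose(np.abs(n), [0, 0, 1], atol=1e-12)


def _flat_ring_frame():
    sp = Species(name="SQ", role="xanthine", plane_atoms=(0, 1, 2, 3),
                 aromatic=True)
    coords = np.array([[1.0, 0, 0], [0, 1.0, 0], [-1.0, 0, 0], [0, -1.0, 0]])
    return xs.MolecularFrame(coords=coords, elements=["C"] * 4,
                             atom_mol=np.zeros(4, dtype=int),
                             mol_species=["SQ"], species={"SQ": sp},
                             box_edge=20.0)


@settings(max_examples=50, deadline=None, derandomize=True)
@given(st.integers(0, 10_000))
def test_plane_normal_rotates_with_the_molecule(seed):
    flat_ring_frame = _flat_ring_frame()
    rng = np.random.default_rng(seed)
    q = rng.normal(size=4)
    w, x, y, z = q / np.linalg.norm(q)
    R = np.array([
        [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
        [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
        [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)]])
    f = flat_ring_frame
    g = xs.MolecularFrame(coords=f.coords @ R.T, elements=f.elements,
                          atom_mol=f.atom_mol, mol_species=f.mol_species,
                          species=f.species, box_edge=f.box_edge)
    n0, n1 = plane_normal(f, 0), plane_normal(g, 0)
    assert abs(abs(np.dot(R @ n0, n1)) - 1.0) < 1e-9


def test_plane_normal_invariant_under_plane_atom_permutation(flat_ring_frame):
    f = flat_ring_frame
    sp = Species(name="SQ", role="xanthine", plane_atoms=(2, 0, 3, 1),
                 aromatic=True)
    g = xs.MolecularFrame(coords=f.coords, elements=f.elements,
                          atom_mol=f.atom_mol, mol_species=["SQ"],
                          species={"SQ": sp}, box_edge=f.box_edge)
    assert abs(abs(np.dot(plane_normal(f, 0), plane_normal(g, 0))) - 1) < 1e-12


def test_plane_normal_rejects_collinear_atoms():
    sp = Species(name="LN", role="xanthine", plane_atoms=(0, 1, 2),
                 aromatic=True)
    f = xs.MolecularFrame(
        coords=np.array([[0.0, 0, 0], [1.0, 0, 0], [2.0, 0, 0]]),
        elements=["C"] * 3, atom_mol=np.zeros(3, dtype=int),
        mol_species=["LN"], species={"LN": sp}, box_edge=10.0)
    with pytest.raises(ValueError, match="collinear"):
        plane_normal(f, 0)


# ---------------------------------------------------------------------------
# XYZ round trip
# ---------------------------------------------------------------------------

@pytest.fixture
def small_traj():
    spec = xs.BoxSpec(box_edge=25.0, fibril_plan=[("XAN", "BZA", "XAN")],
                      n_free_xanthine=2, n_water=10, seed=3)
    frame, _ = xs.generate_box(spec)
    shifted = xs.MolecularFrame(
        coords=frame.coords + 0.25, elements=frame.elements,
        atom_mol=frame.atom_mol, mol_species=frame.mol_species,
        species=frame.species, box_edge=frame.box_edge, index=1)
    return xs.Trajectory([frame, shifted])


def test_xyz_round_trip_preserves_coords_and_frame_order(tmp_path, small_traj):
    p, sp = tmp_path / "t.xyz", tmp_path / "t.csv"
    xs.write_xyz(small_traj, p)
    write_species_map(small_traj.topology, sp)
    back = xs.read_xyz(p, read_species_map(sp))
    assert len(back) == 2
    for a, b in zip(small_traj, back):
        assert np.abs(a.coords - b.coords).max() < 1e-6
        assert a.box_edge == pytest.approx(b.box_edge)
        assert b.mol_species == a.mol_species


def test_xyz_header_body_mismatch_raises(tmp_path, small_traj):
    p, sp = tmp_path / "t.xyz", tmp_path / "t.csv"
    write_species_map(small_traj.topology, sp)
    smap = read_species_map(sp)
    n = small_traj.topology.n_atoms
    lines = [f"{n}", "box=25.0"] + ["C 0 0 0"] * (n - 1)
    p.write_text("\n".join(lines) + "\n")
    with pytest.raises(ValueError, match="fewer"):
        xs.read_xyz(p, smap)


def test_xyz_missing_box_token_raises(tmp_path, small_traj):
    p, sp = tmp_path / "t.xyz", tmp_path / "t.csv"
    write_species_map(small_traj.topology, sp)
    smap = read_species_map(sp)
    n = small_traj.topology.n_atoms
    p.write_text(f"{n}\nno box here\n" + "C 0 0 0\n" * n)
    with pytest.raises(ValueError, match="box"):
        xs.read_xyz(p, smap)


# ---------------------------------------------------------------------------
# PDB round trip
# ---------------------------------------------------------------------------

def test_pdb_round_trip_and_census_idempotence(tmp_path, small_traj):
    p, sp = tmp_path / "t.pdb", tmp_path / "t.csv"
    xs.write_pdb(small_traj, p)
    write_species_map(small_traj.topology, sp)
    back = xs.read_pdb(p, read_species_map(sp))
    assert len(back) == 2
    assert np.abs(back[0].coords - small_traj[0].coords).max() < 1.5e-3
    c0 = xs.neighbor_census(small_traj).per_observation
    c1 = xs.neighbor_census(back).per_observation
    assert c0.equals(c1)


def test_pdb_cubic_cryst1_parsed(tmp_path, small_traj):
    p, sp = tmp_path / "t.pdb", tmp_path / "t.csv"
    xs.write_pdb(small_traj.topology, p)
    write_species_map(small_traj.topology, sp)
    assert xs.read_pdb(p, read_species_map(sp))[0].box_edge == pytest.approx(
        25.0, abs=1e-3)


def _tiny_pdb(cryst: str | None) -> str:
    lines = []
    if cryst:
        lines.append(cryst)
    lines += [
        "ATOM      1  C1  MOL A   1       1.000   1.000   1.000  1.00  0.00           C",
        "END",
    ]
    return "\n".join(lines) + "\n"


def test_pdb_non_cubic_cell_rejected(tmp_path):
    p, sp = tmp_path / "t.pdb", tmp_path / "t.csv"
    p.write_text(_tiny_pdb(
        "CRYST1   80.000   80.000   80.000  90.00  90.00 120.00 P 1           1"))
    import pandas as pd
    pd.DataFrame([{"molecule_id": 0, "species": "MOL", "role": "agent",
                   "plane_atom_indices": "", "n_atoms": 1,
                   "aromatic": False}]).to_csv(sp, index=False)
    with pytest.raises(ValueError, match="cubic"):
        xs.read_pdb(p, read_species_map(sp))


def test_pdb_missing_cryst1_rejected(tmp_path):
    p, sp = tmp_path / "t.pdb", tmp_path / "t.csv"
    p.write_text(_tiny_pdb(None))
    import pandas as pd
    pd.DataFrame([{"molecule_id": 0, "species": "MOL", "role": "agent",
                   "plane_atom_indices": "", "n_atoms": 1,
                   "aromatic": False}]).to_csv(sp, index=False)
    with pytest.raises(ValueError, match="CRYST1"):
        xs.read_pdb(p, read_species_map(sp))
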