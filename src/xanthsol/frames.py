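"""Data model and I/O for periodic molecular configurations.

A configuration is a set of molecules in a cubic box with periodic
boundaries.  Atoms carry no bonds: each molecule is an index range given by
the atom->molecule assignment, and each molecule belongs to a *species*
that fixes its role in the analysis (``xanthine``, ``agent``, ``water`` or
``cation``) and, for flat aromatic species, which atoms define the aromatic
plane.

Coordinates are in Angstrom and may lie outside the primary cell: wrapping
is never applied on input, and all geometry (:func:`minimum_image`,
:func:`molecule_com`, :func:`plane_normal`) applies the minimum-image
convention explicitly.

Formats
-------
* XYZ dialect: line 1 atom count, line 2 ``box=<L>`` token (plus a free
  ``frame=`` token), then ``element x y z`` lines.  XYZ has no topology, so
  a species sidecar CSV (``molecule_id,species,role,plane_atom_indices,
  n_atoms,aromatic``) travels with it.
* PDB: CRYST1 for the cubic cell, MODEL/ENDMDL for multi-frame, one residue
  per molecule with the species name as residue name (handled through
  MDAnalysis).  Only cubic cells are accepted.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterator, Mapping, Sequence

import numpy as np
import pandas as pd

ROLES = ("xanthine", "agent", "water", "cation")
PLANAR_ROLES = ("xanthine", "agent")

#: Atomic masses for the optional mass-weighted centre (u).
ATOMIC_MASSES = {
    "H": 1.008, "C": 12.011, "N": 14.007, "O": 15.999,
    "Na": 22.990, "S": 32.06, "P": 30.974, "K": 39.098, "Cl": 35.45,
}


@dataclass(frozen=True)
class Species:
    """Identity of a molecule kind: its role and which atoms span its plane.

    ``plane_atoms`` are 0-based indices *within* the molecule; at least three
    non-collinear atoms are required for planar roles (xanthine, aromatic
    agent), while water/cation and non-aromatic agents may leave it empty.
    """

    name: str
    role: str
    plane_atoms: tuple[int, ...] = ()
    aromatic: bool = False

    def __post_init__(self) -> None:
        if self.role not in ROLES:
            raise ValueError(f"unknown role {self.role!r}; expected one of {ROLES}")

    @property
    def planar(self) -> bool:
        """True when the species carries a usable aromatic plane."""
        return len(self.plane_atoms) >= 3


class MolecularFrame:
    """One configuration: coordinates plus the molecule/species partition.

    Parameters
    ----------
    coords : (N, 3) array, Angstrom
    elements : sequence of N element symbols
    atom_mol : (N,) int array mapping each atom to its molecule index
        (0-based, contiguous)
    mol_species : sequence of species names, one per molecule
    species : mapping of species name -> :class:`Species`
    box_edge : cubic box edge, Angstrom
    index : frame index within a trajectory
    """

    def __init__(
        self,
        coords: np.ndarray,
        elements: Sequence[str],
        atom_mol: np.ndarray,
        mol_species: Sequence[str],
        species: Mapping[str, Species],
        box_edge: float,
        index: int = 0,
    ) -> None:
        coords = np.asarray(coords, dtype=float)
        atom_mol = np.asarray(atom_mol, dtype=int)
        if coords.ndim != 2 or coords.shape[1] != 3:
            raise ValueError("coords must be (N, 3)")
        if not np.all(np.isfinite(coords)):
            raise ValueError("coordinates must be finite")
        if len(elements) != len(coords) or len(atom_mol) != len(coords):
            raise ValueError("elements/atom_mol length must match coords")
        if box_edge <= 0:
            raise ValueError("box_edge must be positive")
        n_mol = len(mol_species)
        if n_mol == 0:
            raise ValueError("frame must contain at least one molecule")
        counts = np.bincount(atom_mol, minlength=n_mol)
        if atom_mol.min() < 0 or atom_mol.max() >= n_mol or np.any(counts == 0):
            raise ValueError("every molecule needs at least one atom and "
                             "atom_mol must index mol_species")
        for name in mol_species:
            if name not in species:
                raise ValueError(f"species {name!r} missing from species map")
        self.coords = coords
        self.elements = list(elements)
        self.atom_mol = atom_mol
        self.mol_species = list(mol_species)
        self.species = dict(species)
        self.box_edge = float(box_edge)
        self.index = int(index)
        # atom indices per molecule, in input order
        order = np.argsort(atom_mol, kind="stable")
        bounds = np.searchsorted(atom_mol[order], np.arange(n_mol + 1))
        self._mol_atoms = [order[bounds[i]:bounds[i + 1]] for i in range(n_mol)]

    # -- basic queries ---------------------------------------------------
    @property
    def n_atoms(self) -> int:
        return len(self.coords)

    @property
    def n_molecules(self) -> int:
        return len(self.mol_species)

    def mol_atoms(self, mol: int) -> np.ndarray:
        """Atom indices belonging to molecule ``mol``."""
        return self._mol_atoms[mol]

    def species_of(self, mol: int) -> Species:
        return self.species[self.mol_species[mol]]

    def role_of(self, mol: int) -> str:
        return self.species_of(mol).role

    def molecules_with_role(self, role: str) -> list[int]:
        return [m for m in range(self.n_molecules) if self.role_of(m) == role]

    def count_role(self, role: str) -> int:
        return len(self.molecules_with_role(role))

    def planar_molecules(self) -> list[int]:
        """Molecules whose species carries an aromatic plane."""
        return [m for m in range(self.n_molecules) if self.species_of(m).planar]


class Trajectory:
    """Ordered frames sharing one topology (atom count and species map)."""

    def __init__(self, frames: Sequence[MolecularFrame]) -> None:
        frames = list(frames)
        if not frames:
            raise ValueError("trajectory must contain at least one frame")
        f0 = frames[0]
        for f in frames[1:]:
            if f.n_atoms != f0.n_atoms or f.mol_species != f0.mol_species:
                raise ValueError("all frames must share atom count and species map")
        self.frames = frames

    def __len__(self) -> int:
        return len(self.frames)

    def __iter__(self) -> Iterator[MolecularFrame]:
        return iter(self.frames)

    def __getitem__(self, i: int) -> MolecularFrame:
        return self.frames[i]

    @property
    def topology(self) -> MolecularFrame:
        return self.frames[0]


# ---------------------------------------------------------------------------
# periodic geometry
# ---------------------------------------------------------------------------

def minimum_image(point_a: np.ndarray, point_b: np.ndarray, box_edge: float) -> np.ndarray:
    """Minimum-image displacement ``b - a`` in a cubic box.

    Every component of the result lies in ``(-L/2, L/2]``.  Works on single
    points or broadcastable arrays of points.
    """
    d = np.asarray(point_b, dtype=float) - np.asarray(point_a, dtype=float)
    return d - box_edge * np.ceil(d / box_edge - 0.5)


def unwrap_molecule(frame: MolecularFrame, mol: int) -> np.ndarray:
    """Atom positions of ``mol`` made whole about its first atom.

    Each atom is replaced by its periodic image nearest to the first atom,
    so a molecule split across the boundary is reassembled (its coordinates
    may then lie outside the primary cell).
    """
    idx = frame.mol_atoms(mol)
    ref = frame.coords[idx[0]]
    return ref + minimum_image(ref, frame.coords[idx], frame.box_edge)


def molecule_com(frame: MolecularFrame, mol: int, mass_weighted: bool = False) -> np.ndarray:
    """Centre of a molecule after minimum-image unwrapping.

    Geometric (unweighted) by default; ``mass_weighted=True`` uses standard
    atomic masses.  The centre is reported in the unwrapped frame of the
    molecule's first atom and may lie outside the primary cell; downstream
    distances always go through :func:`minimum_image`, so this is harmless.
    """
    pos = unwrap_molecule(frame, mol)
    if not mass_weighted:
        return pos.mean(axis=0)
    idx = frame.mol_atoms(mol)
    w = np.array([ATOMIC_MASSES.get(frame.elements[i], 12.0) for i in idx])
    return (pos * w[:, None]).sum(axis=0) / w.sum()


def plane_normal(
    frame: MolecularFrame,
    mol: int,
    reference: np.ndarray | None = None,
) -> np.ndarray:
    """Unit normal of the least-squares plane through a molecule's plane atoms.

    Plane atoms are unwrapped first.  The sign is arbitrary for a lone frame
    and is fixed deterministically (largest-magnitude component positive);
    pass ``reference`` (e.g. the previous frame's normal) to keep the sign
    continuous along a trajectory.  Raises for species without >=3 plane
    atoms or when the plane atoms are (numerically) collinear.
    """
    sp = frame.species_of(mol)
    if not sp.planar:
        raise ValueError(f"species {sp.name!r} has no usable plane atoms")
    pos = unwrap_molecule(frame, mol)[list(sp.plane_atoms)]
    centred = pos - pos.mean(axis=0)
    _, s, vt = np.linalg.svd(centred, full_matrices=False)
    if s[1] <= 1e-9 * max(s[0], 1.0):
        raise ValueError(f"plane atoms of molecule {mol} are collinear")
    n = vt[2]
    if reference is not None:
        if float(np.dot(n, reference)) < 0:
            n = -n
    else:
        k = int(np.argmax(np.abs(n)))
        if n[k] < 0:
            n = -n
    return n / np.linalg.norm(n)


# ---------------------------------------------------------------------------
# species sidecar
# ---------------------------------------------------------------------------

@dataclass
class SpeciesMap:
    """Topology sidecar for coordinate-only formats.

    ``atom_counts[i]`` is the atom count of molecule ``i``; atoms are assumed
    contiguous per molecule in file order (how all writers here lay them out).
    """

    mol_species: list[str]
    species: dict[str, Species]
    atom_counts: list[int]

    @property
    def n_atoms(self) -> int:
        return int(sum(self.atom_counts))

    def atom_mol(self) -> np.ndarray:
        return np.repeat(np.arange(len(self.mol_species)), self.atom_counts)


def write_species_map(frame: MolecularFrame, path: str | Path) -> None:
    rows = []
    for m, name in enumerate(frame.mol_species):
        sp = frame.species[name]
        rows.append({
            "molecule_id": m,
            "species": name,
            "role": sp.role,
            "plane_atom_indices": ";".join(str(i) for i in sp.plane_atoms),
            "n_atoms": len(frame.mol_atoms(m)),
            "aromatic": sp.aromatic,
        })
    pd.DataFrame(rows).to_csv(path, index=False)


def read_species_map(path: str | Path) -> SpeciesMap:
    df = pd.read_csv(path, keep_default_na=False)
    species: dict[str, Species] = {}
    mol_species, counts = [], []
    for _, row in df.iterrows():
        name = str(row["species"])
        if name not in species:
            raw = str(row["plane_atom_indices"]).strip()
            plane = tuple(int(t) for t in raw.split(";") if t != "") if raw else ()
            species[name] = Species(
                name=name, role=str(row["role"]), plane_atoms=plane,
                aromatic=bool(row["aromatic"]) if "aromatic" in row else False,
            )
        mol_species.append(name)
        counts.append(int(row["n_atoms"]))
    return SpeciesMap(mol_species=mol_species, species=species, atom_counts=counts)


# ---------------------------------------------------------------------------
# XYZ dialect
# ---------------------------------------------------------------------------

def write_xyz(traj: Trajectory | MolecularFrame, path: str | Path) -> None:
    if isinstance(traj, MolecularFrame):
        traj = Trajectory([traj])
    with open(path, "w") as fh:
        for fr in traj:
            fh.write(f"{fr.n_atoms}\n")
            fh.write(f"box={fr.box_edge:.6f} frame={fr.index}\n")
            for el, (x, y, z) in zip(fr.elements, fr.coords):
                fh.write(f"{el} {x:.6f} {y:.6f} {z:.6f}\n")


def read_xyz(path: str | Path, species_map: SpeciesMap) -> Trajectory:
    """Read a multi-frame XYZ file written in the ``box=<L>`` dialect.

    XYZ carries no topology; the sidecar ``species_map`` supplies the
    molecule partition and roles.
    """
    frames: list[MolecularFrame] = []
    atom_mol = species_map.atom_mol()
    with open(path) as fh:
        lines = fh.read().splitlines()
    i, fidx = 0, 0
    while i < len(lines):
        if lines[i].strip() == "":
            i += 1
            continue
        try:
            natoms = int(lines[i].strip())
        except ValueError as exc:
            raise ValueError(f"bad atom-count line {i + 1}: {lines[i]!r}") from exc
        if natoms != species_map.n_atoms:
            raise ValueError(
                f"frame {fidx}: {natoms} atoms but species map describes "
                f"{species_map.n_atoms}")
        if i + 1 >= len(lines):
            raise ValueError("truncated file: missing comment line")
        box_edge = None
        for tok in lines[i + 1].split():
            if tok.startswith("box="):
                box_edge = float(tok[4:])
        if box_edge is None:
            raise ValueError(f"frame {fidx}: comment line lacks a box=<L> token")
        body = lines[i + 2:i + 2 + natoms]
        if len(body) < natoms or any(len(ln.split()) < 4 for ln in body):
            raise ValueError(
                f"frame {fidx}: header announces {natoms} atoms but fewer "
                "well-formed atom lines follow")
        elements, coords = [], []
        for ln in body:
            parts = ln.split()
            elements.append(parts[0])
            coords.append([float(parts[1]), float(parts[2]), float(parts[3])])
        frames.append(MolecularFrame(
            coords=np.array(coords), elements=elements, atom_mol=atom_mol,
            mol_species=species_map.mol_species, species=species_map.species,
            box_edge=box_edge, index=fidx))
        i += 2 + natoms
        fidx += 1
    return Trajectory(frames)


# ---------------------------------------------------------------------------
# PDB (via MDAnalysis)
# ---------------------------------------------------------------------------

def write_pdb(traj: Trajectory | MolecularFrame, path: str | Path) -> None:
    """Write frames as a (multi-)MODEL PDB with CRYST1, one residue per molecule.

    PDB residue names are limited to 4 characters, so species names must be
    that short to survive the round trip.
    """
    import MDAnalysis as mda
    from MDAnalysis.coordinates.memory import MemoryReader

    if isinstance(traj, MolecularFrame):
        traj = Trajectory([traj])
    f0 = traj.topology
    for name in set(f0.mol_species):
        if len(name) > 4:
            raise ValueError(f"species name {name!r} exceeds the 4-character "
                             "PDB residue-name limit")
    n, m = f0.n_atoms, f0.n_molecules
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        u = mda.Universe.empty(n, n_residues=m, atom_resindex=f0.atom_mol,
                               trajectory=False)
        u.add_TopologyAttr("resids", np.arange(1, m + 1))
        u.add_TopologyAttr("resnames", list(f0.mol_species))
        names = []
        for mol in range(m):
            for j, a in enumerate(f0.mol_atoms(mol)):
                names.append(f"{f0.elements[a]}{j + 1}"[:4])
        # mol_atoms preserves input order within molecules and molecules are
        # contiguous, so this matches atom order
        u.add_TopologyAttr("names", names)
        u.add_TopologyAttr("elements", list(f0.elements))
        coords = np.stack([fr.coords for fr in traj]).astype(np.float32)
        dims = np.array(
            [[fr.box_edge, fr.box_edge, fr.box_edge, 90.0, 90.0, 90.0] for fr in traj],
            dtype=np.float32)
        u.load_new(coords, format=MemoryReader, dimensions=dims)
        with mda.Writer(str(path), n, multiframe=True) as w:
            for _ in u.trajectory:
                w.write(u.atoms)
    # the multi-model reader only picks up CRYST1 inside a MODEL block, so
    # replicate the header record into each model
    lines = Path(path).read_text().splitlines()
    cryst = next((ln for ln in lines if ln.startswith("CRYST1")), None)
    if cryst is not None and any(ln.startswith("MODEL") for ln in lines):
        out = []
        for ln in lines:
            out.append(ln)
            if ln.startswith("MODEL"):
                out.append(cryst)
        Path(path).write_text("\n".join(out) + "\n")


def read_pdb(path: str | Path, species_map: SpeciesMap) -> Trajectory:
    """Read a cubic-cell PDB trajectory; roles come from the sidecar map.

    Raises when CRYST1 is absent or describes a non-cubic cell.
    """
    import MDAnalysis as mda

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        u = mda.Universe(str(path))
        atom_mol = u.atoms.resindices.copy().astype(int)
        if len(u.residues) != len(species_map.mol_species):
            raise ValueError(
                f"PDB has {len(u.residues)} residues but species map describes "
                f"{len(species_map.mol_species)} molecules")
        try:
            elements = [str(e) for e in u.atoms.elements]
        except (AttributeError, mda.exceptions.NoDataError):
            elements = ["".join(c for c in nm if c.isalpha()) or "X"
                        for nm in u.atoms.names]
        frames = []
        for fidx, ts in enumerate(u.trajectory):
            dims = ts.dimensions
            if dims is None or not np.all(np.asarray(dims)[:3] > 0):
                raise ValueError("PDB lacks a CRYST1 record (no box)")
            a, b, c, al, be, ga = (float(x) for x in dims)
            if not (np.allclose([al, be, ga], 90.0, atol=1e-3)
                    and np.allclose([a, b], c, atol=1e-3)):
                raise ValueError(
                    f"only cubic cells are supported; got a,b,c=({a},{b},{c}) "
                    f"angles=({al},{be},{ga})")
            frames.append(MolecularFrame(
                coords=np.asarray(ts.positions, dtype=float).copy(),
                elements=elements, atom_mol=atom_mol,
                mol_species=species_map.mol_species, species=species_map.species,
                box_edge=c, index=fidx))
    return Trajectory(frames)
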