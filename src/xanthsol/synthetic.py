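"""Synthetic configurations and measurement tables with known ground truth.

The generators emulate the study conditions the analysis modules are built
for, at coarse geometric fidelity:

* :func:`generate_box` builds periodic boxes of flat molecules stacked into
  rigid fibrils (xanthine columns, optionally intercalated or end-capped by
  aromatic agents) plus free monomers, counter-ions and water, recording
  exactly which molecule sits in each axial slot of each xanthine.
* :func:`generate_solubility_curve` produces linear (complexation-like) or
  threshold-exponential (hydrotrope-like, MHC) solubility series.
* :func:`generate_nmr_table` produces proton-integral tables that are the
  exact inverse of the water-referenced qNMR molality formula.
* :func:`generate_roesy_table` produces normalized cross-peak volume tables
  under homo- or hetero-association regimes.

Everything is driven by a single integer seed; identical inputs give
byte-identical outputs.  Molecular templates are coarse flat skeletons with
roughly the right heavy-atom footprint — the analysis metrics downstream
are purely geometric, so no force-field geometry is needed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .frames import (
    MolecularFrame, Species, Trajectory, minimum_image, write_species_map,
)
from .solution import M_W, SolubilityCurve, WATER_COMPOUND


# ---------------------------------------------------------------------------
# species templates
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SpeciesTemplate(Species):
    """A species plus its rigid body-frame geometry (centred on the centroid)."""

    body_elements: tuple[str, ...] = ()
    body_coords: tuple[tuple[float, float, float], ...] = ()

    def __post_init__(self) -> None:
        super().__post_init__()
        coords = np.asarray(self.body_coords, dtype=float)
        if coords.ndim != 2 or coords.shape[1] != 3 or not np.all(np.isfinite(coords)):
            raise ValueError("template coordinates must be finite (n, 3)")
        if len(self.body_elements) != len(coords):
            raise ValueError("element/coordinate length mismatch")
        if self.planar:
            pts = coords[list(self.plane_atoms)]
            centred = pts - pts.mean(axis=0)
            s = np.linalg.svd(centred, compute_uv=False)
            if len(s) < 2 or s[1] <= 1e-9 * max(s[0], 1.0):
                raise ValueError(f"plane atoms of template {self.name!r} are collinear")

    @property
    def n_atoms(self) -> int:
        return len(self.body_elements)

    def coords_array(self) -> np.ndarray:
        return np.asarray(self.body_coords, dtype=float)


def _ring(n: int, bond: float = 1.39) -> np.ndarray:
    """Regular n-ring of the given bond length in the xy-plane, centred."""
    r = bond / (2 * math.sin(math.pi / n))
    ang = np.arange(n) * 2 * math.pi / n
    return np.column_stack([r * np.cos(ang), r * np.sin(ang), np.zeros(n)])


def _fused_purine() -> tuple[list[str], np.ndarray]:
    """Coarse purine-like skeleton: hexagon fused to a pentagon, plus the
    two carbonyl oxygens and three methyl carbons of a caffeine footprint."""
    hexa = _ring(6)
    # fuse pentagon on the hexagon edge between vertices 0 and 5
    p, q = hexa[0], hexa[5]
    s = float(np.linalg.norm(p - q))
    mid = (p + q) / 2
    outward = mid[:2] / np.linalg.norm(mid[:2])
    a5 = s / (2 * math.tan(math.pi / 5))     # pentagon apothem
    centre = np.array([*(mid[:2] + a5 * outward), 0.0])
    th_p = math.atan2(p[1] - centre[1], p[0] - centre[0])
    r5 = s / (2 * math.sin(math.pi / 5))
    penta = np.array([
        [centre[0] + r5 * math.cos(th_p + k * 2 * math.pi / 5),
         centre[1] + r5 * math.sin(th_p + k * 2 * math.pi / 5), 0.0]
        for k in range(5)])
    # the two pentagon vertices nearest p/q duplicate the shared edge
    keep = [k for k in range(5)
            if min(np.linalg.norm(penta[k] - p), np.linalg.norm(penta[k] - q)) > 0.3]
    ring = np.vstack([hexa, penta[keep]])
    elements = ["N", "C", "N", "C", "C", "C", "N", "C", "N"]
    # substituents placed radially in-plane: 2 carbonyl O, 3 methyl C
    def radial(v: np.ndarray, d: float) -> np.ndarray:
        u = v[:2] / np.linalg.norm(v[:2])
        return np.array([v[0] + d * u[0], v[1] + d * u[1], 0.0])
    subs = [radial(hexa[1], 1.23), radial(hexa[3], 1.23),
            radial(hexa[2], 1.47), radial(hexa[4], 1.47), radial(ring[8], 1.47)]
    coords = np.vstack([ring, subs])
    elements += ["O", "O", "C", "C", "C"]
    return elements, coords - coords.mean(axis=0)


def _benzene_agent() -> tuple[list[str], np.ndarray]:
    """Benzene ring with a short carboxylate tail (salicylate/ferulate-like
    footprint)."""
    hexa = _ring(6)
    v = hexa[0]
    u = v[:2] / np.linalg.norm(v[:2])
    cc = np.array([v[0] + 1.5 * u[0], v[1] + 1.5 * u[1], 0.0])
    perp = np.array([-u[1], u[0]])
    o1 = np.array([cc[0] + 1.0 * u[0] + 0.7 * perp[0],
                   cc[1] + 1.0 * u[1] + 0.7 * perp[1], 0.0])
    o2 = np.array([cc[0] + 1.0 * u[0] - 0.7 * perp[0],
                   cc[1] + 1.0 * u[1] - 0.7 * perp[1], 0.0])
    coords = np.vstack([hexa, cc, o1, o2])
    return ["C"] * 7 + ["O", "O"], coords - coords.mean(axis=0)


def _pyridine_agent() -> tuple[list[str], np.ndarray]:
    """Pyridine ring with an amide-like tail (nicotinate/niacinamide
    footprint)."""
    elements, coords = _benzene_agent()
    elements = ["N"] + elements[1:-1] + ["N"]  # ring N and amide N
    return elements, coords


def _aliphatic_agent() -> tuple[list[str], np.ndarray]:
    """Levulinate-like zig-zag chain; no aromatic plane, cannot stack."""
    xs = np.arange(5) * 1.3
    ys = np.array([0.0, 0.6, 0.0, 0.6, 0.0])
    chain = np.column_stack([xs, ys, np.zeros(5)])
    o1 = chain[4] + np.array([1.0, 0.7, 0.0])
    o2 = chain[4] + np.array([1.0, -0.7, 0.0])
    coords = np.vstack([chain, o1, o2])
    return ["C"] * 5 + ["O", "O"], coords - coords.mean(axis=0)


def default_templates(water_sites: int = 1) -> dict[str, SpeciesTemplate]:
    """Coarse default species set.

    ``XAN``: methylxanthine (planar, 14 heavy atoms); ``BZA``: benzene-based
    aromatic agent; ``PYA``: pyridine-based aromatic agent; ``ALI``:
    aliphatic (levulinate-like) agent without a plane; ``WAT``: water as a
    single oxygen bead (``water_sites=3`` adds the two hydrogens); ``NA``:
    sodium-like counter-ion.
    """
    xe, xc = _fused_purine()
    be, bc = _benzene_agent()
    pe, pc = _pyridine_agent()
    ae, ac = _aliphatic_agent()
    if water_sites == 1:
        we, wc = ["O"], np.zeros((1, 3))
    elif water_sites == 3:
        d, half = 0.9572, math.radians(104.52 / 2)
        we = ["O", "H", "H"]
        wc = np.array([[0.0, 0.0, 0.0],
                       [d * math.sin(half), d * math.cos(half), 0.0],
                       [-d * math.sin(half), d * math.cos(half), 0.0]])
        wc = wc - wc.mean(axis=0)
    else:
        raise ValueError("water_sites must be 1 or 3")
    mk = lambda name, role, el, co, plane, arom: SpeciesTemplate(
        name=name, role=role, plane_atoms=plane, aromatic=arom,
        body_elements=tuple(el), body_coords=tuple(map(tuple, co)))
    return {
        "XAN": mk("XAN", "xanthine", xe, xc, tuple(range(9)), True),
        "BZA": mk("BZA", "agent", be, bc, tuple(range(6)), True),
        "PYA": mk("PYA", "agent", pe, pc, tuple(range(6)), True),
        "ALI": mk("ALI", "agent", ae, ac, (), False),
        "WAT": mk("WAT", "water", we, wc, (), False),
        "NA": mk("NA", "cation", ["Na"], np.zeros((1, 3)), (), False),
    }


# ---------------------------------------------------------------------------
# box generation
# ---------------------------------------------------------------------------

@dataclass
class BoxSpec:
    """Recipe for one synthetic periodic box.

    ``fibril_plan`` lists fibrils as ordered species sequences, e.g.
    ``("XAN", "BZA", "XAN")`` for an intercalated trimer; only species with
    an aromatic plane may appear.  Successive molecular planes sit
    ``stack_spacing`` apart along a random axis, perturbed by in-plane
    Gaussian jitter (``lateral_jitter_sd``) and plane tilt
    (``tilt_sd``, degrees).  Remaining molecules are placed uniformly,
    clash-free under minimum image.
    """

    box_edge: float = 80.0
    fibril_plan: Sequence[Sequence[str]] = ()
    n_free_xanthine: int = 0
    n_free_agent: int = 0
    free_agent_species: str = "BZA"
    n_water: int = 0
    n_cation: int = 0
    stack_spacing: float = 3.4
    lateral_jitter_sd: float = 0.0
    tilt_sd: float = 0.0
    seed: int = 0
    clash_distance: float = 2.0
    #: minimum COM separation between planar molecules of *different* units
    #: (fibrils or free monomers); keeps the recorded axial occupancy
    #: exhaustive by construction — 6 A exceeds the reach of the default
    #: axial window (sqrt(d_max^2 + lateral_max^2) ~ 5.6 A), so no
    #: unplanted stacking contact can arise between units
    planar_isolation: float = 6.0
    max_attempts: int = 10000

    def __post_init__(self) -> None:
        if self.box_edge <= 0 or self.stack_spacing <= 0 or self.clash_distance <= 0:
            raise ValueError("box_edge, stack_spacing and clash_distance must be > 0")
        for n in (self.n_free_xanthine, self.n_free_agent, self.n_water, self.n_cation):
            if n < 0:
                raise ValueError("molecule counts must be non-negative")
        if self.lateral_jitter_sd < 0 or self.tilt_sd < 0:
            raise ValueError("noise magnitudes must be non-negative")


@dataclass
class GroundTruth:
    """What was actually built: fibril membership and axial occupancy.

    ``axial_occupants[x]`` maps ``"up"``/``"down"`` to ``(molecule id, role)``
    or ``None`` for every xanthine ``x`` (up = towards the fibril axis);
    ``planted_k[x]`` counts the agent-role occupants among them.
    """

    fibril_id: dict[int, int | None]
    axial_occupants: dict[int, dict[str, tuple[int, str] | None]]
    planted_k: dict[int, int]

    def validate(self) -> None:
        for x, occ in self.axial_occupants.items():
            k = sum(1 for slot in occ.values()
                    if slot is not None and slot[1] == "agent")
            if k != self.planted_k[x]:
                raise AssertionError(f"planted k inconsistent for xanthine {x}")


def _unit(v: np.ndarray) -> np.ndarray:
    return v / np.linalg.norm(v)


def _rotation_about(axis: np.ndarray, angle: float) -> np.ndarray:
    axis = _unit(axis)
    K = np.array([[0, -axis[2], axis[1]],
                  [axis[2], 0, -axis[0]],
                  [-axis[1], axis[0], 0]])
    return np.eye(3) + math.sin(angle) * K + (1 - math.cos(angle)) * (K @ K)


def _align_z_to(u: np.ndarray) -> np.ndarray:
    u = _unit(u)
    c = u[2]
    if c < -1 + 1e-12:
        return np.diag([1.0, -1.0, -1.0])
    v = np.array([-u[1], u[0], 0.0])  # z x u
    K = np.array([[0, 0, v[1]], [0, 0, -v[0]], [-v[1], v[0], 0]])
    return np.eye(3) + K + K @ K / (1 + c)


def _random_rotation(rng: np.random.Generator) -> np.ndarray:
    q = rng.normal(size=4)
    w, x, y, z = q / np.linalg.norm(q)
    return np.array([
        [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
        [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
        [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)],
    ])


def _clashes(new_atoms: np.ndarray, placed: np.ndarray, L: float, dmin: float) -> bool:
    if placed.size == 0:
        return False
    d = minimum_image(new_atoms[:, None, :], placed[None, :, :], L)
    return bool(np.any(np.einsum("ijk,ijk->ij", d, d) < dmin * dmin))


def generate_box(
    spec: BoxSpec,
    templates: Mapping[str, SpeciesTemplate] | None = None,
) -> tuple[MolecularFrame, GroundTruth]:
    """Build one clash-free periodic configuration and its ground truth.

    Fibrils are placed first (each as a rigid unit, re-drawn on clash),
    then free xanthines/agents, counter-ions and water by rejection
    sampling.  Raises when any placement fails ``max_attempts`` times,
    naming the molecular density of the request.
    """
    templates = dict(templates) if templates is not None else default_templates()
    rng = np.random.default_rng(spec.seed)
    L = spec.box_edge

    mol_species: list[str] = []
    all_elements: list[str] = []
    all_coords: list[np.ndarray] = []
    placed = np.empty((0, 3))
    planar_coms = np.empty((0, 3))  # COMs of committed planar molecules
    fibril_id: dict[int, int | None] = {}
    axial: dict[int, dict[str, tuple[int, str] | None]] = {}

    def commit(name: str, atoms: np.ndarray) -> int:
        nonlocal placed, planar_coms
        mid = len(mol_species)
        mol_species.append(name)
        all_elements.extend(templates[name].body_elements)
        all_coords.append(atoms)
        placed = np.vstack([placed, atoms])
        if templates[name].planar:
            planar_coms = np.vstack([planar_coms, atoms.mean(axis=0)])
        return mid

    def too_close_to_other_units(coms: np.ndarray) -> bool:
        return _clashes(np.atleast_2d(coms), planar_coms, L,
                        spec.planar_isolation)

    def density_error(what: str) -> ValueError:
        n_req = (sum(len(p) for p in spec.fibril_plan) + spec.n_free_xanthine
                 + spec.n_free_agent + spec.n_water + spec.n_cation)
        rho = n_req / L ** 3
        return ValueError(
            f"packing failed while placing {what} after {spec.max_attempts} "
            f"attempts (requested density {rho:.2e} molecules/A^3 in a "
            f"{L:.1f} A box)")

    # --- fibrils --------------------------------------------------------
    for fib, plan in enumerate(spec.fibril_plan):
        plan = list(plan)
        for name in plan:
            if name not in templates:
                raise ValueError(f"unknown species {name!r} in fibril plan")
            if not templates[name].planar:
                raise ValueError(
                    f"species {name!r} has no aromatic plane and cannot stack")
        for attempt in range(spec.max_attempts):
            u = _unit(rng.normal(size=3))
            base = rng.uniform(0, L, size=3)
            A = _align_z_to(u)
            # two in-plane directions for lateral jitter
            e1 = _unit(np.cross(u, [1.0, 0.0, 0.0])
                       if abs(u[0]) < 0.9 else np.cross(u, [0.0, 1.0, 0.0]))
            e2 = np.cross(u, e1)
            mols: list[tuple[str, np.ndarray]] = []
            ok = True
            for j, name in enumerate(plan):
                spin = _rotation_about(np.array([0.0, 0.0, 1.0]),
                                       rng.uniform(0, 2 * math.pi))
                tilt_angle = math.radians(rng.normal(0.0, spec.tilt_sd)) \
                    if spec.tilt_sd > 0 else 0.0
                tilt_axis = math.cos(a := rng.uniform(0, 2 * math.pi)) * e1 \
                    + math.sin(a) * e2
                P = _rotation_about(tilt_axis, tilt_angle)
                R = P @ A @ spin
                jit = (rng.normal(0.0, spec.lateral_jitter_sd) * e1
                       + rng.normal(0.0, spec.lateral_jitter_sd) * e2) \
                    if spec.lateral_jitter_sd > 0 else 0.0
                centre = base + j * spec.stack_spacing * u + jit
                atoms = centre + templates[name].coords_array() @ R.T
                mols.append((name, atoms))
            new_atoms = np.vstack([a for _, a in mols])
            if _clashes(new_atoms, placed, L, spec.clash_distance):
                continue
            if too_close_to_other_units(
                    np.array([a.mean(axis=0) for _, a in mols])):
                continue
            ids = [commit(name, atoms) for name, atoms in mols]
            for j, mid in enumerate(ids):
                fibril_id[mid] = fib
                if templates[plan[j]].role == "xanthine":
                    up = ((ids[j + 1], templates[plan[j + 1]].role)
                          if j + 1 < len(ids) else None)
                    down = ((ids[j - 1], templates[plan[j - 1]].role)
                            if j - 1 >= 0 else None)
                    axial[mid] = {"up": up, "down": down}
            break
        else:
            raise density_error(f"fibril {fib} ({'-'.join(plan)})")

    # --- free molecules -------------------------------------------------
    def place_free(name: str, n: int, what: str) -> list[int]:
        out = []
        for _ in range(n):
            for attempt in range(spec.max_attempts):
                R = _random_rotation(rng)
                centre = rng.uniform(0, L, size=3)
                atoms = centre + templates[name].coords_array() @ R.T
                if _clashes(atoms, placed, L, spec.clash_distance):
                    continue
                if templates[name].planar and \
                        too_close_to_other_units(atoms.mean(axis=0)):
                    continue
                out.append(commit(name, atoms))
                break
            else:
                raise density_error(what)
        return out

    for mid in place_free("XAN", spec.n_free_xanthine, "a free xanthine"):
        fibril_id[mid] = None
        axial[mid] = {"up": None, "down": None}
    for mid in place_free(spec.free_agent_species, spec.n_free_agent, "a free agent"):
        fibril_id[mid] = None
    for mid in place_free("NA", spec.n_cation, "a counter-ion"):
        fibril_id[mid] = None
    for mid in place_free("WAT", spec.n_water, "a water"):
        fibril_id[mid] = None

    if not mol_species:
        raise ValueError("empty box: the spec places no molecules")

    planted_k = {x: sum(1 for slot in occ.values()
                        if slot is not None and slot[1] == "agent")
                 for x, occ in axial.items()}
    species_used = {name: templates[name] for name in set(mol_species)}
    atom_mol = np.repeat(np.arange(len(mol_species)),
                         [templates[n].n_atoms for n in mol_species])
    frame = MolecularFrame(
        coords=np.vstack(all_coords), elements=all_elements, atom_mol=atom_mol,
        mol_species=mol_species, species=species_used, box_edge=L)
    truth = GroundTruth(fibril_id=fibril_id, axial_occupants=axial,
                        planted_k=planted_k)
    truth.validate()
    return frame, truth


# ---------------------------------------------------------------------------
# solubility curves
# ---------------------------------------------------------------------------

def generate_solubility_curve(
    model: str,
    params: Sequence[float],
    noise_sd: float = 0.0,
    n_points: int = 10,
    c_max: float = 3.0,
    seed: int = 0,
    xanthine: str = "caffeine",
    agent: str = "agent",
) -> SolubilityCurve:
    """Synthetic solubility series on a uniform agent-molality grid.

    ``model="linear"`` takes ``params=(s0, slope)`` and returns
    ``s = s0 + slope*c``; ``model="mhc"`` takes ``params=(s0, mhc, rate)``
    and returns ``s0`` below the minimum hydrotropic concentration and
    ``s0*exp(rate*(c - mhc))`` above it.  I.i.d. Gaussian noise of standard
    deviation ``noise_sd`` is added and values are floored at zero.
    """
    if n_points < 4:
        raise ValueError("need at least 4 points")
    if any(p < 0 for p in params):
        raise ValueError("model parameters must be non-negative")
    c = np.linspace(0.0, c_max, n_points)
    if model == "linear":
        s0, slope = params
        s = s0 + slope * c
    elif model == "mhc":
        s0, mhc, rate = params
        s = np.where(c < mhc, s0, s0 * np.exp(rate * (c - mhc)))
    else:
        raise ValueError("model must be 'linear' or 'mhc'")
    if noise_sd > 0:
        s = s + np.random.default_rng(seed).normal(0.0, noise_sd, size=n_points)
    return SolubilityCurve(c=c, s=np.maximum(s, 0.0),
                           xanthine=xanthine, agent=agent)


# ---------------------------------------------------------------------------
# qNMR tables
# ---------------------------------------------------------------------------

def generate_nmr_table(
    molalities: Mapping[str, float],
    proton_counts: Mapping[str, Mapping[str, int]],
    noise_sd: float = 0.0,
    seed: int = 0,
    reference: tuple[str, str] | None = None,
) -> pd.DataFrame:
    """Proton-integral table consistent with water-referenced quantitation.

    Per-proton integrals are proportional to molar amounts; the water row
    carries two protons per molecule at the 55.508 mol/kg of water in one
    kilogram of itself.  The table is normalized so the designated
    one-proton ``reference`` peak (default: the first one-proton peak of the
    first compound) integrates to exactly 1.  ``noise_sd`` is the relative
    standard deviation of per-peak Gaussian noise (applied before
    normalization, floored at zero).  At ``noise_sd=0`` the table is the
    exact inverse of :func:`xanthsol.solution.molality_from_integrals`.
    """
    for comp, m in molalities.items():
        if m <= 0:
            raise ValueError(f"molality of {comp!r} must be positive")
        if comp not in proton_counts:
            raise ValueError(f"no proton counts given for {comp!r}")
        for peak, n in proton_counts[comp].items():
            if n < 1:
                raise ValueError(f"peak {comp}/{peak}: proton count must be >= 1")
    if reference is None and molalities:
        for comp in molalities:
            ones = [p for p, n in proton_counts[comp].items() if n == 1]
            if ones:
                reference = (comp, ones[0])
                break
        else:
            raise ValueError("no one-proton peak available as reference")
    rng = np.random.default_rng(seed)
    rows = []
    for comp, m in molalities.items():
        for peak, n in proton_counts[comp].items():
            rows.append({"compound": comp, "peak": peak,
                         "integral": n * m, "n_protons": n})
    rows.append({"compound": WATER_COMPOUND, "peak": "H2O",
                 "integral": 2.0 / M_W, "n_protons": 2})
    df = pd.DataFrame(rows)
    if noise_sd > 0:
        # relative Gaussian noise: integrals span orders of magnitude
        # (water vs dilute solute), so the error scales with the peak
        df["integral"] = np.maximum(
            df["integral"] * (1.0 + rng.normal(0.0, noise_sd, size=len(df))),
            0.0)
    if reference is not None:
        mask = (df["compound"] == reference[0]) & (df["peak"] == reference[1])
        if not mask.any():
            raise ValueError(f"reference peak {reference} not in table")
        scale = float(df.loc[mask, "integral"].iloc[0])
        if scale <= 0:
            raise ValueError("reference integral vanished")
        df["integral"] = df["integral"] / scale
    return df


# ---------------------------------------------------------------------------
# ROESY tables
# ---------------------------------------------------------------------------

XANTHINE_SITES = ("A", "B", "C", "D")


def generate_roesy_table(
    regime: str,
    n_hetero_peaks: int = 8,
    seed: int = 0,
    aromatic_fraction: float = 0.5,
    aromatic_bias: float = 0.0,
    scale: float = 1.0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Cross-peak volume table under a homo- or hetero-association regime.

    Returns ``(peaks, sites)``.  ``[A-B]`` is always the strongest peak
    (raw volume ``scale``); ``[B-C]``/``[B-D]`` carry the xanthine
    homo-association signal.  In the ``homo`` regime every xanthine-agent
    volume falls below them; in the ``hetero`` regime every one exceeds
    them, with ``aromatic_bias`` added to agent sites flagged aromatic.
    Agent sites are numbered from 2; the first ``aromatic_fraction`` of them
    are ring members.
    """
    if regime not in ("homo", "hetero"):
        raise ValueError("regime must be 'homo' or 'hetero'")
    if n_hetero_peaks < 1:
        raise ValueError("need at least one xanthine-agent cross-peak")
    rng = np.random.default_rng(seed)
    agent_sites = [str(i + 2) for i in range(n_hetero_peaks)]
    n_arom = round(aromatic_fraction * n_hetero_peaks)
    aromatic = {s: (i < n_arom) for i, s in enumerate(agent_sites)}
    if regime == "homo":
        bc, bd = rng.uniform(0.18, 0.26, size=2)
        floor_ = min(bc, bd)
        het = rng.uniform(0.02, 0.9 * floor_, size=n_hetero_peaks)
    else:
        bc, bd = rng.uniform(0.05, 0.10, size=2)
        het = max(bc, bd) + rng.uniform(0.05, 0.25, size=n_hetero_peaks)
        het = het + aromatic_bias * np.array(
            [1.0 if aromatic[s] else 0.0 for s in agent_sites])
    rows = [("A", "B", 1.0), ("B", "C", float(bc)), ("B", "D", float(bd))]
    xan_cycle = [XANTHINE_SITES[i % 4] for i in range(n_hetero_peaks)]
    for xs, ags, v in zip(xan_cycle, agent_sites, het):
        rows.append((xs, ags, float(min(v, 0.95))))
    peaks = pd.DataFrame(rows, columns=["site_a", "site_b", "volume"])
    peaks["volume"] *= scale
    sites = pd.DataFrame(
        [{"id": s, "molecule": "xanthine", "aromatic": True}
         for s in XANTHINE_SITES]
        + [{"id": s, "molecule": "agent", "aromatic": aromatic[s]}
           for s in agent_sites])
    return peaks, sites


# ---------------------------------------------------------------------------
# writers
# ---------------------------------------------------------------------------

def write_ground_truth_csv(frame: MolecularFrame, truth: GroundTruth,
                           path: str | Path) -> None:
    rows = []
    for m, name in enumerate(frame.mol_species):
        occ = truth.axial_occupants.get(m, {})
        fmt = lambda slot: "" if occ.get(slot) is None else str(occ[slot][0])
        rows.append({
            "molecule_id": m, "species": name, "role": frame.role_of(m),
            "fibril_id": "" if truth.fibril_id.get(m) is None else truth.fibril_id[m],
            "planted_k": truth.planted_k.get(m, ""),
            "up_occupant": fmt("up"), "down_occupant": fmt("down"),
        })
    pd.DataFrame(rows).to_csv(path, index=False)


def write_curve_csv(curve: SolubilityCurve, path: str | Path) -> None:
    df = pd.DataFrame({"agent_molality": curve.c, "solubility": curve.s})
    if curve.sd is not None:
        df["sd"] = curve.sd
    df.to_csv(path, index=False)


def read_curve_csv(path: str | Path, xanthine: str = "", agent: str = "") -> SolubilityCurve:
    df = pd.read_csv(path)
    return SolubilityCurve(
        c=df["agent_molality"].to_numpy(), s=df["solubility"].to_numpy(),
        sd=df["sd"].to_numpy() if "sd" in df else None,
        xanthine=xanthine, agent=agent)


def write_box_config(spec: BoxSpec, path: str | Path) -> None:
    d = asdict(spec)
    d["fibril_plan"] = [list(p) for p in spec.fibril_plan]
    with open(path, "w") as fh:
        yaml.safe_dump(d, fh, sort_keys=False)


def read_box_config(path: str | Path) -> BoxSpec:
    with open(path) as fh:
        d = yaml.safe_load(fh)
    d["fibril_plan"] = [tuple(p) for p in d.get("fibril_plan", [])]
    return BoxSpec(**d)
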