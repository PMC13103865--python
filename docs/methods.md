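# Methods

`xanthsol` analyses how aromatic anions and amides ("complexing agents",
CA) solubilize methylxanthines (caffeine, theophylline, theobromine) in
water.  The scientific question is mechanistic: does an agent act as a
classical *hydrotrope* (cooperative self-assembly above a threshold
concentration, giving an exponential solubility onset) or as a
*complexing agent* (stoichiometric-like pi-stacked pairing, giving a
linear solubility law that survives dilution)?  The package implements
the four quantitative strands of that argument — solution quantitation,
curve-shape discrimination, ROESY association classification, and
geometric stacking metrics on molecular configurations — plus a
synthetic-data layer that makes each strand testable against known
ground truth.

## Quantitative NMR (water-referenced molality)

A solute's molality follows from proton integrals with the water signal
as internal standard:

    m = (A_c / N_c) / (A_w / 2) / M_W

with `A_c` the solute peak integral, `N_c` its protons per molecule,
`A_w` the water integral (two protons per molecule, hence the /2) and
`M_W = 0.0180153 kg/mol`.  The quotient `(A_c/N_c)/(A_w/2)` is the
solute-to-water mole ratio; dividing by `M_W` converts to moles per
kilogram of water.  Two consequences are useful as checks and are
asserted in the tests: equal per-proton solute and water integrals read
exactly `1/M_W = 55.508 mol/kg` (an equimolal solution in water), and
the formula is linear in `A_c`.  When a compound shows several
well-resolved peaks, per-proton integrals are averaged before the
quotient.  Tables are normalized so a designated one-proton xanthine
peak integrates to 1; the formula is scale-free, so the normalization
choice cannot affect the result.

The synthetic table generator is the exact algebraic inverse of this
formula at zero noise (round-trip error is at machine precision, the
suite requires <= 1e-10 relative).  Its noise model is per-peak relative
Gaussian noise, because real integral uncertainties scale with the peak:
an absolute noise term would be dominated by the ~110-unit water
integral while dilute solute peaks sit near 0.1.

## Solubility-increase factor

`F_SI = s_SA / s0`, the saturation molality with the agent over the
pure-water value.  Both inputs are explicit; the package deliberately
does not hard-wire a pure-water value into the quotient because the
record itself rounds theobromine's solubility inconsistently (0.0018 vs
0.002 mol/kg, a 10% difference that moves `F_SI` between ~306 and ~275).
The reference table in `xanthsol.datasets` carries the three-digit
values.

## Linear vs MHC curve discrimination

Two rival forms are least-squares fitted to each solubility series
`s(c)`:

* linear (complexation-like): `s = s0 + a c`;
* hydrotrope-like: `s = s0` for `c < MHC`, `s0 exp(b (c - MHC))` above,
  where MHC is the minimum hydrotropic concentration.  The
  threshold-exponential form is the standard hydrotropy signature; the
  exact functional form above threshold is a modelling choice, and
  exponential is the simplest one consistent with "exponential onset
  above a threshold".

The MHC fit is profiled: the breakpoint runs over a grid containing the
interior data abscissae plus a 25-point uniform refinement, and `s0, b`
are optimized per candidate (bounded Levenberg–Marquardt via
`scipy.optimize.least_squares`).  Including the data abscissae means a
noiseless breakpoint sitting on a grid point is recovered exactly.
Model choice uses small-sample-corrected AIC (AICc) with k = 3 (linear)
vs k = 4 (MHC) parameters counting the noise variance; the verdict is
decisive only when the AICc difference exceeds 2 (the conventional
evidence threshold), otherwise `indeterminate`.  Degenerate (constant)
curves warn and return `indeterminate`.  Under the package's study
conditions (n = 10 points on c in [0, 3], noise 5% of the response
range, linear s0 = 0.106 / slope = 1.0 mirroring the caffeine–salicylate
series; MHC curve s0 = 0.1, MHC = 1.0, b = 1.0) the verdict accuracy is
measured at 100% per class over 200 seeded curves, comfortably above the
95% the acceptance suite requires.  The two families are well separated
here because an exponential through the observed dynamic range (~30x)
cannot mimic a line of this slope; discrimination degrades for nearly
flat curves, where the exponential linearizes.

Breakpoint/plateau detection is separate from model choice: a continuous
two-segment linear fit (`s = b0 + b1 c + b2 (c - c*)+`, candidates at
interior data abscissae with two points per side) is reported only when
it improves AICc over the single line by >= 2; a plateau is flagged when
the outgoing slope drops to <= 0.1 of the incoming slope.  Absence of a
breakpoint is a valid (and for a straight line, the correct) result.

## Phase-domain classification

The ternary behaviour (water + xanthine + agent salt) is summarised by
two binodal polylines over agent molality: the upper traces
xanthine-saturated solutions, the lower agent-saturated ones; between
them lies the homogeneous domain.  Query points are classified by linear
interpolation of each polyline, with a `boundary` band of
eps = 0.01 mol/kg, and no extrapolation outside the measured span —
digitized binodals are guides to the eye, not models.  The bundled
diagram is a synthetic reconstruction pinned to the described anchors
(ferulate alone saturates at 0.41 mol/kg; 1.65 mol/kg ferulate stays
dissolved at 2.0 mol/kg caffeine), used for fixtures and the worked
example.

## ROESY association classification

Cross-peak volumes are normalized to the intramolecular `[A-B]`
reference (methyl to adjacent CH; strongest peak, set to 1.0 in every
sample).  The intermolecular xanthine–xanthine peaks `[B-C]`/`[B-D]`
gauge homo-association; their maximum is the homo baseline.  Default
rule: `hetero_preferred` when at least half of the xanthine–agent peaks
exceed the baseline and the strongest one does; `homo_preferred` when
the baseline dominates every hetero peak; `mixed` otherwise.  Pair
keys are unordered and duplicate symmetric entries are averaged.

Because pair propensities scale with concentration ([X]^2 for homo,
[X][A] for hetero), a volume-only rule can under-call homo-association
in xanthine-poor samples.  The optional concentration-aware rule divides
the homo baseline by the xanthine:agent molality ratio before the
comparison.  The nicotinate system is the worked case: volume-only it is
`mixed` (only 4 of 14 hetero peaks above a 0.12 baseline), while the
concentration-aware rule (caffeine three-fold dilute relative to the
agent) lifts the baseline to 0.40 and calls `homo_preferred` — the
verdict is rule-sensitive by construction and both readings are
reported.  `ring_involvement` additionally ranks agent proton sites by
their mean normalized contact volume with xanthine sites, split
aromatic vs non-aromatic: stronger ring-face contact is the stacking
signature that separates benzene-based from pyridine-based agents.

No volume-to-distance conversion is attempted: long-mixing-time ROESY
volumes rank proximities but do not measure distances.

## Periodic configurations and stacking metrics

Configurations live in cubic periodic boxes (the only cell shape
supported); coordinates are in Angstrom and may lie outside the primary
cell, with all geometry routed through the minimum-image convention
(components of a displacement lie in (-L/2, L/2]).  Molecule centres are
geometric (unweighted) means after unwrapping the molecule about its
first atom — contact counting does not need masses, though a
mass-weighted option exists.  Aromatic plane normals come from the SVD
of the centred plane atoms; analyses only ever use |n.d|, so the sign
convention (largest component positive, or continuity against a supplied
reference) never matters downstream.

**Neighbor census.**  For every xanthine and frame, the number of
xanthine, agent and water molecules whose centre (water: its oxygen
site) lies within a cutoff of the xanthine COM, excluding itself;
averages pool uniformly over frames and xanthines.  Search uses a
periodic cell list, falling back to the exact O(N^2) evaluation when the
box holds fewer than 3 cells per edge; the brute-force mode is retained
as a first-class independent oracle and the suite asserts bit-identical
counts on random frames.

**Axial classification.**  Molecule j occupies an axial stacking site of
xanthine i when (1) the projection of the COM displacement on i's plane
normal has magnitude in [d_min, d_max], (2) the in-plane (lateral)
offset is <= lateral_max, and (3) the interplane angle is <= max_tilt.
Each side (up/down) keeps the nearest qualifying occupant, ties to the
lower molecule id.  The distribution P(k) counts *all* qualifying
agent-role contacts per xanthine (not just the two slot winners), capped
at 3 with a logged fold — this is what lets a k = 3 class exist at all
around a single planar molecule: a third agent can qualify off-axis
within the lateral tolerance while the slots hold two.

**Cutoff defaults are calibration choices, not measured values.**  The
experimental record never states the geometric definition of
"surrounding".  Defaults: COM cutoff 7.0 A (two 3.4-A stacking
separations plus slack — note this deliberately includes
second-stack neighbours at 6.8 A), water cutoff 5.0 A (first shell),
axial window [2.5, 5.0] A, lateral_max 2.5 A, max_tilt 40 degrees.  All
are parameters; every consumer logs or writes the values used.

**Efficiency.**  `E = (sum_k k P(k)) * n_xanthine / n_agent`: the mean
agent count per xanthine, rescaled into "xanthines engaged per agent".
The rescaling removes the bias whereby xanthine-rich boxes mechanically
dilute P(k>0); E is comparable across systems with different xanthine
loadings.  E = 0 iff P(0) = 1, and pooling two copies of the same box
leaves both P and E unchanged (asserted as a property).

**Aggregates.**  Planar molecules are nodes; an edge joins two molecules
when either holds the other in an axial slot.  Connected components
(via networkx) are aggregates; a component is a *fibril* when its
contact graph is a simple path of >= 3 molecules.  Agent degree inside a
component separates intercalation (degree 2, benzene-like agents inside
a stack) from end-capping (degree <= 1, pyridine-like agents at stack
ends).

## Synthetic configuration generator

Boxes are built from coarse rigid templates — flat ring skeletons with
approximately the right heavy-atom footprint (purine-like 14-atom
xanthine, benzene- and pyridine-based agents with short tails, a
non-planar aliphatic agent that cannot stack, single-bead or 3-site
water, point counter-ions).  Geometric fidelity at the ring level is all
the metrics need; no energies or force fields are involved.

Fibrils are placed as rigid stacks along a uniformly random axis with
3.4 A plane spacing (the canonical aromatic stacking distance), each
molecule given a random in-plane spin, optional Gaussian lateral jitter
and plane tilt.  Free monomers, ions and waters follow by rejection
sampling.  Three placement guarantees make the ground truth usable:

* clash-freedom: no two heavy atoms of distinct molecules closer than
  2.0 A under minimum image (asserted by a brute-force test);
* exhaustive occupancy records: planar molecules of *different* units
  keep >= 6.0 A COM separation (`planar_isolation`), which exceeds the
  reach of the default axial window (sqrt(5.0^2 + 2.5^2) ~ 5.6 A), so
  no unplanted stacking contact can arise and the recorded per-xanthine
  agent count is exact by construction;
* determinism: one integer seed drives every draw; identical specs give
  byte-identical frames and truth.

Placement failure after 10,000 attempts raises an error naming the
requested molecular density.

What the generator does *not* emulate: thermal disorder beyond the two
noise knobs, exchange dynamics, curved or branched aggregates,
hydrogen-bonded networks, and realistic water structure.  Passing the
recovery tests therefore certifies the *analysis geometry* (the
classifiers return exactly what was built, and degrade gracefully at
5-degree tilt / 0.3 A jitter, where recovery stays >= 99%), not the
physics of real trajectories.  Likewise the census density-ordering
check (concentrated fibril boxes show more xanthine neighbours and fewer
first-shell waters than dilute monomeric ones) reproduces the *ordering*
of the crowding effect, not any published magnitudes — those would
require hundreds of nanoseconds of all-atom sampling, which is out of
scope here.

## Problem sizes and numerical choices

The bundled analyses and the acceptance script use desk-scale systems:
32–40 A boxes with up to ~1000 single-bead waters and 2–4 fibrils of
3–6 molecules (<= 300 molecules in recovery ensembles of 50 boxes), 200
curves per class for the discrimination study, and 1e5 point pairs for
the minimum-image cross-check.  These sizes were chosen as the smallest
that exercise every code path with non-trivial statistics; all are
parameters, and the 80 A default `BoxSpec` matches the simulated systems
the metrics are designed for.

Other numerics: tie-breaks on axial slots go to the lower molecule id;
k > 3 axial agent counts fold into the k = 3 class with a logged
warning; XYZ coordinates round-trip at 1e-6 A and PDB at its 1e-3 A
format precision (the census is integer-valued and survives both, which
is asserted); collinear plane atoms raise rather than return a garbage
normal; RSS values are floored at n*1e-30 inside AICc so exact fits do
not produce -inf.

## Known limitations

* Only cubic boxes; no binary trajectory formats (DCD/NetCDF) — text
  XYZ/PDB with a species sidecar CSV is the interchange surface.
* The slot rule admits at most one occupant per side; heavily disordered
  stacks where two molecules share a side at similar axial distance are
  reported through the full contact list, not the slots.
* The MHC fit assumes a sharp threshold; smooth crossovers are absorbed
  into the breakpoint grid and can land between data points.
* ROESY verdicts depend on the decision rule in xanthine-poor samples;
  both rules are reported rather than resolved.
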