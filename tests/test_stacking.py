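"""Neighbor census, axial classification, P(k), efficiency, aggregates."""

import numpy as np
import pytest

import xanthsol as xs
from xanthsol.frames import minimum_image
from xanthsol.stacking import count_within
from conftest import make_point_frame, random_fibril_spec


def brute_force_counts(centers, points, cutoff, L, center_ids=None,
                       point_ids=None):
    """Independent O(N^2) oracle: plain double loop over minimum images."""
    counts = np.zeros(len(centers), dtype=int)
    for i, c in enumerate(centers):
        for j, p in enumerate(points):
            if center_ids is not None and point_ids is not None \
                    and center_ids[i] == point_ids[j]:
                continue
            if np.linalg.norm(minimum_image(c, p, L)) <= cutoff:
                counts[i] += 1
    return counts


# ---------------------------------------------------------------------------
# census
# ---------------------------------------------------------------------------

def test_single_xanthine_has_zero_neighbors():
    f = make_point_frame([[5.0, 5, 5]], ["xanthine"], 20.0)
    c = xs.neighbor_census(f)
    assert c.mean_xanthine == 0 and c.mean_water == 0 and c.mean_agent == 0


def test_census_requires_a_xanthine():
    f = make_point_frame([[1.0, 1, 1]], ["water"], 20.0)
    with pytest.raises(ValueError, match="xanthine"):
        xs.neighbor_census(f)


def test_planted_five_stack_census_mean():
    # 5 xanthines 3.4 A apart on a line.  A 5 A cutoff sees only adjacent
    # stack partners: counts (1,2,2,2,1), mean 8/5 = 1.6.  A 7 A cutoff
    # also captures the 6.8 A second neighbors: counts (2,3,4,3,2),
    # mean 14/5 = 2.8.  Both frozen from the O(N^2) distance oracle.
    pts = [[10.0, 10, 10 + 3.4 * i] for i in range(5)]
    f = make_point_frame(pts, ["xanthine"] * 5, 40.0)
    for cutoff, expected_counts in ((5.0, [1, 2, 2, 2, 1]),
                                    (7.0, [2, 3, 4, 3, 2])):
        c = xs.neighbor_census(f, xs.CensusParams(molecule_com_cutoff=cutoff))
        oracle = brute_force_counts(np.array(pts), np.array(pts), cutoff,
                                    40.0, np.arange(5), np.arange(5))
        assert oracle.tolist() == expected_counts
        assert c.per_observation["n_xanthine"].tolist() == expected_counts
    assert xs.neighbor_census(
        f, xs.CensusParams(molecule_com_cutoff=5.0)).mean_xanthine == \
        pytest.approx(1.6)


@pytest.mark.parametrize("seed", range(6))
def test_cell_list_census_equals_brute_force(seed):
    rng = np.random.default_rng(seed)
    L = float(rng.uniform(15, 40))
    n = int(rng.integers(30, 120))
    pts = rng.uniform(-L, 2 * L, size=(n, 3))  # also exercises wrapping
    cutoff = float(rng.uniform(2.0, 9.0))
    ids = np.arange(n)
    cell = count_within(pts, pts, cutoff, L, ids, ids, method="cell")
    brute = count_within(pts, pts, cutoff, L, ids, ids, method="brute")
    oracle = brute_force_counts(pts, pts, cutoff, L, ids, ids)
    assert np.array_equal(cell, brute)
    assert np.array_equal(cell, oracle)


def test_census_monotone_in_cutoff():
    frame, _ = xs.generate_box(random_fibril_spec(40))
    prev = None
    for cutoff in (3.0, 5.0, 7.0, 10.0):
        c = xs.neighbor_census(
            frame, xs.CensusParams(molecule_com_cutoff=cutoff)).per_observation
        if prev is not None:
            assert (c["n_xanthine"] >= prev["n_xanthine"]).all()
            assert (c["n_agent"] >= prev["n_agent"]).all()
        prev = c


def test_intercalation_lowers_xanthine_xanthine_crowding():
    pure = xs.BoxSpec(box_edge=40, fibril_plan=[("XAN",) * 8] * 2, seed=9)
    mixed = xs.BoxSpec(
        box_edge=40,
        fibril_plan=[tuple("XAN" if i % 2 == 0 else "BZA" for i in range(8))] * 2,
        seed=9)
    c_pure = xs.neighbor_census(xs.generate_box(pure)[0])
    c_mixed = xs.neighbor_census(xs.generate_box(mixed)[0])
    assert c_mixed.mean_xanthine < c_pure.mean_xanthine


# ---------------------------------------------------------------------------
# axial classification
# ---------------------------------------------------------------------------

def test_coplanar_side_by_side_pair_is_not_axial(templates):
    # two xanthines side by side in the same plane: axial projection ~ 0
    spec = xs.BoxSpec(box_edge=30, fibril_plan=[("XAN",)], seed=1)
    frame, _ = xs.generate_box(spec)
    xan = templates["XAN"]
    shifted = frame.coords + np.array([8.0, 0.0, 0.0]) * 0  # placeholder
    coords = np.vstack([frame.coords, frame.coords + [7.0, 0.0, 0.0]])
    f2 = xs.MolecularFrame(
        coords=coords, elements=frame.elements * 2,
        atom_mol=np.concatenate([frame.atom_mol, frame.atom_mol + 1]),
        mol_species=["XAN", "XAN"], species=frame.species, box_edge=30.0)
    assert all(not o.contacts for o in xs.classify_axial(f2))


def test_zero_noise_planted_recovery_is_exact():
    spec = random_fibril_spec(55)
    frame, truth = xs.generate_box(spec)
    rec = xs.recovered_k(xs.classify_axial(frame))
    for x, k in truth.planted_k.items():
        assert rec[(0, x)] == k
    # slot partners match the recorded occupants
    occ = {o.xanthine: o for o in xs.classify_axial(frame)}
    for x, slots in truth.axial_occupants.items():
        got = set(p for p in occ[x].slot_partners if p is not None)
        want = set(s[0] for s in slots.values() if s is not None)
        assert got == want


def test_classification_matches_raw_coordinate_rederivation():
    # independent oracle: recompute the geometric rule from scratch
    frame, _ = xs.generate_box(random_fibril_spec(66, tilt_sd=4.0,
                                                  jitter_sd=0.25))
    params = xs.AxialParams()
    planar = frame.planar_molecules()
    coms = {m: xs.molecule_com(frame, m) for m in planar}
    nrm = {m: xs.plane_normal(frame, m) for m in planar}
    expected = {}
    for x in frame.molecules_with_role("xanthine"):
        ks = 0
        for j in planar:
            if j == x or frame.role_of(j) != "agent":
                continue
            d = minimum_image(coms[x], coms[j], frame.box_edge)
            a = float(nrm[x] @ d)
            lat = np.linalg.norm(d - a * nrm[x])
            tilt = np.degrees(np.arccos(min(abs(float(nrm[x] @ nrm[j])), 1.0)))
            if params.d_min <= abs(a) <= params.d_max \
                    and lat <= params.lateral_max and tilt <= params.max_tilt:
                ks += 1
        expected[x] = min(ks, 3)
    assert xs.recovered_k(xs.classify_axial(frame, params)) == {
        (0, x): k for x, k in expected.items()}


# ---------------------------------------------------------------------------
# P(k) and efficiency
# ---------------------------------------------------------------------------

def test_all_free_box_gives_p0_one():
    frame, _ = xs.generate_box(xs.BoxSpec(box_edge=40, n_free_xanthine=8,
                                          n_free_agent=4, seed=12))
    dist = xs.config_distribution(xs.classify_axial(frame))
    assert dist.p[0] == pytest.approx(1.0)


def test_fully_intercalated_interior_gives_p2_one():
    # A-X-A-X-A: every xanthine sits between two agents
    plan = tuple("BZA" if i % 2 == 0 else "XAN" for i in range(7))
    frame, truth = xs.generate_box(xs.BoxSpec(box_edge=40,
                                              fibril_plan=[plan], seed=13))
    assert set(truth.planted_k.values()) == {2}
    dist = xs.config_distribution(xs.classify_axial(frame))
    assert dist.p[2] == pytest.approx(1.0)


def test_pk_matches_planted_histogram():
    frame, truth = xs.generate_box(random_fibril_spec(77))
    dist = xs.config_distribution(xs.classify_axial(frame))
    ks = np.array(list(truth.planted_k.values()))
    expected = np.bincount(np.minimum(ks, 3), minlength=4) / len(ks)
    assert np.allclose(dist.p, expected)
    assert dist.p.sum() == pytest.approx(1.0)


def test_pooling_two_identical_boxes_leaves_p_and_e_unchanged():
    frame, _ = xs.generate_box(random_fibril_spec(88))
    occ1 = xs.classify_axial(frame)
    occ2 = xs.classify_axial(xs.Trajectory([frame, frame]))
    d1, d2 = xs.config_distribution(occ1), xs.config_distribution(occ2)
    assert np.allclose(d1.p, d2.p)
    n_x, n_a = frame.count_role("xanthine"), frame.count_role("agent")
    if n_a:
        e1 = xs.agent_efficiency(d1, n_x, n_a).efficiency
        e2 = xs.agent_efficiency(d2, 2 * n_x, 2 * n_a).efficiency
        assert e1 == pytest.approx(e2)


@pytest.mark.parametrize("p,nx,na,expected", [
    ([1, 0, 0, 0], 10, 5, 0.0),
    ([0, 1, 0, 0], 7, 7, 1.0),
    ([0.5, 0.5, 0, 0], 10, 5, 1.0),
    ([0.2, 0.3, 0.4, 0.1], 12, 6, (0.3 + 0.8 + 0.3) * 2),
])
def test_efficiency_formula(p, nx, na, expected):
    dist = xs.ConfigDistribution(p=np.array(p, dtype=float), n_observations=1)
    assert xs.agent_efficiency(dist, nx, na).efficiency == pytest.approx(expected)


def test_efficiency_requires_agents():
    dist = xs.ConfigDistribution(p=np.array([1.0, 0, 0, 0]), n_observations=1)
    with pytest.raises(ValueError):
        xs.agent_efficiency(dist, 10, 0)


def test_efficiency_zero_iff_p0_one():
    d0 = xs.ConfigDistribution(p=np.array([1.0, 0, 0, 0]), n_observations=1)
    assert xs.agent_efficiency(d0, 5, 5).efficiency == 0
    d1 = xs.ConfigDistribution(p=np.array([0.9, 0.1, 0, 0]), n_observations=1)
    assert xs.agent_efficiency(d1, 5, 5).efficiency > 0


# ---------------------------------------------------------------------------
# aggregates
# ---------------------------------------------------------------------------

def test_planted_six_stack_is_one_fibril():
    frame, _ = xs.generate_box(xs.BoxSpec(box_edge=40,
                                          fibril_plan=[("XAN",) * 6], seed=5))
    agg = xs.detect_aggregates(frame)
    assert len(agg.aggregates) == 1
    a = agg.aggregates[0]
    assert a.size == 6 and a.is_fibril


def test_two_stacked_pairs_are_not_fibrils():
    frame, _ = xs.generate_box(xs.BoxSpec(
        box_edge=40, fibril_plan=[("XAN", "XAN"), ("XAN", "XAN")], seed=6))
    agg = xs.detect_aggregates(frame)
    assert sorted(agg.sizes) == [2, 2]
    assert not any(a.is_fibril for a in agg.aggregates)


def test_intercalated_vs_end_capped_distinguished_by_agent_degree():
    inter, _ = xs.generate_box(xs.BoxSpec(
        box_edge=40, fibril_plan=[("XAN", "BZA", "XAN", "BZA", "XAN")], seed=7))
    caps, _ = xs.generate_box(xs.BoxSpec(
        box_edge=40, fibril_plan=[("PYA", "XAN", "XAN", "XAN", "PYA")], seed=7))
    a_inter = xs.detect_aggregates(inter).aggregates[0]
    a_caps = xs.detect_aggregates(caps).aggregates[0]
    assert a_inter.n_interior_agents == 2 and a_inter.n_end_agents == 0
    assert a_caps.n_interior_agents == 0 and a_caps.n_end_agents == 2
    assert a_inter.is_fibril and a_caps.is_fibril
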