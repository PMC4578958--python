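import itertools
import math

import numpy as np
import pytest

from scaffoldscan import (
    KSRNetwork,
    PPINetwork,
    PhosphositeTable,
    PredictionSet,
    degree_matched_sample,
    extrinsic_cases,
    generate,
    heterotypic_analysis,
    homotypic_analysis,
    hypergeom_sf,
    intrinsic_cases,
    phosphosite_profile,
    recovery_stats,
    regulation_null,
    shared_pathway_ppi,
    term_enrichment,
)
from scaffoldscan.randomize import CandidateAssociation
from scaffoldscan.simulate import SyntheticConfig
from conftest import random_ppi, random_ksr


def _pred(pairs) -> PredictionSet:
    assoc = [
        CandidateAssociation(s, tuple(p), 0, len(p)) for s, p in pairs
    ]
    return PredictionSet(
        associations=assoc,
        per_scaffold_cutoff={s: 2 for s, _ in pairs},
        q_star=0.01,
        integral_fdr=0.0,
    )


# ---------------------------------------------------------------------------
# hypergeometric
# ---------------------------------------------------------------------------


def _pmf_sum_oracle(k, K, n, N):
    total = 0.0
    for x in range(k, min(n, K) + 1):
        total += (
            math.comb(K, x) * math.comb(N - K, n - x) / math.comb(N, n)
        )
    return total


def test_hypergeom_whole_support_is_one():
    assert hypergeom_sf(0, 5, 3, 10) == pytest.approx(1.0)


def test_hypergeom_matches_exhaustive_pmf_small_N():
    for N in range(1, 13):
        for K in range(N + 1):
            for n in range(N + 1):
                for k in range(min(n, K) + 1):
                    assert hypergeom_sf(k, K, n, N) == pytest.approx(
                        _pmf_sum_oracle(k, K, n, N), abs=1e-12
                    )


def test_hypergeom_rejects_inconsistent_parameters():
    with pytest.raises(ValueError):
        hypergeom_sf(5, 3, 4, 10)  # k > K
    with pytest.raises(ValueError):
        hypergeom_sf(1, 3, 11, 10)  # n > N


# ---------------------------------------------------------------------------
# recovery
# ---------------------------------------------------------------------------


def test_recovery_worked_example_arithmetic():
    predicted = {f"P{i}" for i in range(212)}
    known = {f"P{i}" for i in range(18)} | {f"K{i}" for i in range(60)}
    r = recovery_stats(predicted, known, 24_000)
    assert r.k == 18
    assert r.expected == pytest.approx(0.689, abs=1e-3)
    assert r.fold == pytest.approx(18 / 0.689, rel=1e-3)
    assert r.sensitivity == pytest.approx(18 / 78)
    assert r.p_value < 6.9e-21


def test_recovery_identical_sets_full_sensitivity():
    s = {"A", "B", "C"}
    r = recovery_stats(s, s, 100)
    assert r.sensitivity == 1.0 and r.k == 3


def test_recovery_disjoint_sets_zero_fold():
    r = recovery_stats({"A"}, {"B"}, 100)
    assert r.k == 0 and r.fold == 0.0


def test_recovery_requires_known_set():
    with pytest.raises(ValueError):
        recovery_stats({"A"}, set(), 100)


# ---------------------------------------------------------------------------
# homotypic / heterotypic
# ---------------------------------------------------------------------------


def test_homotypic_extreme_case_finite():
    net = PPINetwork([("S1", "S1"), ("S2", "S2"), ("S1", "B1"), ("S2", "B2")])
    r = homotypic_analysis(net, {"S1", "S2"})
    assert r.k == 2 and r.K == 2
    assert 0 < r.p_value <= 1
    assert math.isfinite(r.fold)


def test_homotypic_planted_excess_detected():
    rng = np.random.default_rng(0)
    net = random_ppi(200, 0.05, rng)
    scaffolds = {f"N{i}" for i in range(30)}
    for p in scaffolds:  # planted self-loop excess
        net.add_edge(p, p)
    for i in range(30, 45):  # background self-loop rate much lower
        net.add_edge(f"N{i}", f"N{i}")
    r = homotypic_analysis(net, scaffolds)
    assert r.p_value < 0.05


def test_homotypic_rejects_empty():
    with pytest.raises(ValueError):
        homotypic_analysis(PPINetwork([("A", "B")]), set())


def test_degree_matched_sample_properties():
    rng = np.random.default_rng(1)
    net = random_ppi(150, 0.06, rng)
    reference = set(sorted(net.proteins)[:25])
    sample = degree_matched_sample(net, reference, seed=0)
    assert len(sample) == len(reference)
    assert sample <= net.proteins


def test_degree_matched_whole_network_returns_itself():
    net = PPINetwork([("A", "B"), ("B", "C"), ("C", "D")])
    sample = degree_matched_sample(net, net.proteins, seed=0)
    assert sample == net.proteins


def test_degree_matched_bins_track_reference_degrees():
    # power-law-ish graph; matched sample should stay within one geometric bin
    cfg = SyntheticConfig(n_proteins=1000, n_kinases=30, cascades=(2, 3),
                          n_background_ksr=5, n_planted_scaffolds=3, seed=2)
    comp, _, _ = generate(cfg)
    net = comp.ppi
    degrees = net.degree_sequence()
    reference = set(sorted(net.proteins, key=lambda p: -degrees[p])[:50])
    diffs = []
    rng = np.random.default_rng(9)
    for _ in range(20):
        sample = degree_matched_sample(net, reference, seed=rng)
        ref_sorted = sorted(degrees[p] for p in reference)
        smp_sorted = sorted(degrees[p] for p in sample)
        diffs.append(np.mean([
            abs((r.bit_length() if r else 0) - (s.bit_length() if s else 0))
            for r, s in zip(ref_sorted, smp_sorted)
        ]))
    assert np.mean(diffs) <= 1.0


def test_heterotypic_clique_observed_count():
    members = [f"S{i}" for i in range(5)]
    net = PPINetwork(list(itertools.combinations(members, 2)))
    obs, exp = heterotypic_analysis(net, set(members), n_reps=5, seed=0)
    assert obs == 10


def test_heterotypic_nonadjacent_scaffolds_zero():
    net = PPINetwork([("S1", "x"), ("S2", "y"), ("x", "y")])
    obs, _ = heterotypic_analysis(net, {"S1", "S2"}, n_reps=3, seed=0)
    assert obs == 0


def test_heterotypic_planted_complex_exceeds_expected():
    cfg = SyntheticConfig(
        n_proteins=400, n_kinases=40, cascades=(3, 3, 4, 4),
        n_background_ksr=10, n_planted_scaffolds=12,
        complex_planting=True, pair_wiring_prob=1.0, seed=3,
    )
    comp, truth, _ = generate(cfg)
    obs, exp = heterotypic_analysis(comp.ppi, truth.scaffolds, n_reps=30, seed=4)
    assert obs > exp


# ---------------------------------------------------------------------------
# shared-pathway pairs
# ---------------------------------------------------------------------------


def test_shared_pathway_adjacent_pair():
    net = PPINetwork([("S1", "S2"), ("S1", "A"), ("S2", "A")])
    pred = _pred([("S1", ("A", "B")), ("S2", ("A", "B"))])
    sharing, with_ppi, exp = shared_pathway_ppi(pred, net, n_reps=20, seed=0)
    assert (sharing, with_ppi) == (1, 1)


def test_shared_pathway_nonadjacent_pair():
    net = PPINetwork([("S1", "A"), ("S2", "A")])
    pred = _pred([("S1", ("A", "B")), ("S2", ("A", "B"))])
    sharing, with_ppi, _ = shared_pathway_ppi(pred, net, n_reps=20, seed=0)
    assert (sharing, with_ppi) == (1, 0)


def test_shared_pathway_no_sharing_warns():
    net = PPINetwork([("S1", "A")])
    pred = _pred([("S1", ("A", "B")), ("S2", ("C", "D"))])
    assert shared_pathway_ppi(pred, net, n_reps=5, seed=0) == (0, 0, 0.0)


def test_shared_pathway_planted_complexes_exceed_null():
    cfg = SyntheticConfig(
        n_proteins=400, n_kinases=40, cascades=(3, 3, 4, 4),
        n_background_ksr=10, n_planted_scaffolds=12,
        complex_planting=True, pair_wiring_prob=1.0, seed=5,
    )
    comp, truth, _ = generate(cfg)
    pred = _pred(sorted(truth.planted))
    sharing, with_ppi, exp = shared_pathway_ppi(pred, comp.ppi, n_reps=50, seed=6)
    assert sharing > 0
    assert with_ppi > exp


# ---------------------------------------------------------------------------
# regulation cases
# ---------------------------------------------------------------------------


def test_intrinsic_case_kinase_in_pathway():
    ksr = KSRNetwork([("LCK", "PLCG2"), ("LCK", "DAPP")])
    pred = _pred([("DAPP", ("LCK", "PLCG2"))])
    cases = intrinsic_cases(pred, ksr)
    assert len(cases) == 1
    c = cases[0]
    assert (c.scaffold, c.kinase, c.mode) == ("DAPP", "LCK", "intrinsic")


def test_extrinsic_case_outside_kinase_with_co_target():
    ksr = KSRNetwork(
        [("CSK", "SRC"), ("SRC", "CTNNB1"), ("FYN", "CAV1"), ("FYN", "CTNNB1")]
    )
    pred = _pred([("CAV1", ("CSK", "SRC", "CTNNB1"))])
    cases = extrinsic_cases(pred, ksr)
    assert len(cases) == 1
    c = cases[0]
    assert (c.scaffold, c.kinase, c.co_target) == ("CAV1", "FYN", "CTNNB1")
    # the in-pathway kinases produce no extrinsic case
    assert all(x.kinase not in x.pathway for x in cases)


def test_no_edge_into_scaffold_no_cases():
    ksr = KSRNetwork([("A", "B")])
    pred = _pred([("S", ("A", "B"))])
    assert intrinsic_cases(pred, ksr) == []
    assert extrinsic_cases(pred, ksr) == []


def _brute_regulation(pred, ksr):
    intr, extr = [], []
    for s, pw in {(a.scaffold, a.pathway) for a in pred.associations}:
        for k in pw:
            if ksr.has_edge(k, s):
                intr.append((s, pw, k))
        for k in sorted(ksr.kinases()):
            if k in pw or not ksr.has_edge(k, s):
                continue
            for co in pw:
                if ksr.has_edge(k, co):
                    extr.append((s, pw, k, co))
    return sorted(intr), sorted(extr)


@pytest.mark.parametrize("seed", [0, 1, 2])
def test_regulation_cases_match_brute_force(seed):
    rng = np.random.default_rng(seed)
    ksr = random_ksr(10, 0.2, rng)
    ids = sorted(ksr.proteins)
    pairs = []
    for _ in range(5):
        pw = tuple(rng.choice(ids, size=3, replace=False))
        pairs.append((str(rng.choice(ids)), pw))
    pred = _pred(pairs)
    intr, extr = _brute_regulation(pred, ksr)
    got_i = [(c.scaffold, c.pathway, c.kinase) for c in intrinsic_cases(pred, ksr)]
    got_e = [
        (c.scaffold, c.pathway, c.kinase, c.co_target)
        for c in extrinsic_cases(pred, ksr)
    ]
    assert sorted(got_i) == intr
    assert sorted(got_e) == extr
    assert set(got_i).isdisjoint({(s, p, k) for s, p, k, _ in got_e})


def test_regulation_null_zero_when_no_edges_into_proteome():
    ksr = KSRNetwork([("A", "B")])
    pred = _pred([("S", ("A", "B"))])
    proteome = {f"Z{i}" for i in range(10)}
    ei, ee = regulation_null(pred, ksr, proteome, n_reps=10, seed=0)
    assert ei == 0.0 and ee == 0.0


def test_regulation_planted_wiring_exceeds_null():
    cfg = SyntheticConfig(
        n_proteins=400, n_kinases=40, cascades=(3, 4, 5),
        n_background_ksr=10, n_planted_scaffolds=9,
        intrinsic_wiring_rate=1.0, extrinsic_wiring_rate=1.0, seed=7,
    )
    comp, truth, _ = generate(cfg)
    pred = _pred(sorted(truth.planted))
    obs_i = len(intrinsic_cases(pred, comp.ksr))
    obs_e = len(extrinsic_cases(pred, comp.ksr))
    ei, ee = regulation_null(
        pred, comp.ksr, comp.ppi.proteins, n_reps=30, seed=8
    )
    assert obs_i > 3 * max(ei, 0.1)
    assert obs_e > 3 * max(ee, 0.1)


# ---------------------------------------------------------------------------
# phosphosites and terms
# ---------------------------------------------------------------------------


def test_phosphosite_profile_trivial_group():
    sites = PhosphositeTable([(f"G{i}", 1, "S") for i in range(4)])
    prof = phosphosite_profile(
        sites, {f"G{i}" for i in range(4)}, {f"G{i}" for i in range(8)}
    )
    assert prof["group"].mean_sites == 1.0
    assert prof["group"].frac_at_least_1 == 1.0
    assert prof["group"].frac_at_least_5 == 0.0


def test_phosphosite_empty_table_all_zero():
    sites = PhosphositeTable()
    prof = phosphosite_profile(sites, {"A"}, {"A", "B"})
    assert prof["group"].mean_sites == 0.0


def test_phosphosite_duplicates_collapse_and_validation():
    t = PhosphositeTable([("A", 3, "S"), ("A", 3, "S")])
    assert len(t) == 1
    with pytest.raises(ValueError):
        t.add("A", 0, "S")
    with pytest.raises(ValueError):
        t.add("A", 1, "Q")


def test_phosphosite_rate_recovery_on_generated_data():
    cfg = SyntheticConfig(
        n_proteins=800, n_kinases=40, cascades=(3, 4, 5),
        n_background_ksr=10, n_planted_scaffolds=200 - 188,  # 12 planted
        seed=11,
    )
    # accumulate over seeds to reach ~200 scaffold draws
    means_s, means_b = [], []
    for seed in range(17):
        cfg.seed = seed
        comp, truth, sites = generate(cfg)
        prof = phosphosite_profile(sites, truth.scaffolds, comp.ppi.proteins)
        means_s.append(prof["group"].mean_sites)
        means_b.append(prof["background"].mean_sites)
    assert np.mean(means_s) == pytest.approx(12.0, rel=0.10)
    assert np.mean(means_b) == pytest.approx(2.0, rel=0.10)


def test_phosphosite_length_matched_control_runs():
    rng = np.random.default_rng(3)
    proteins = [f"P{i}" for i in range(60)]
    lengths = {p: int(rng.integers(100, 2000)) for p in proteins}
    sites = PhosphositeTable(
        [(p, int(j) + 1, "S") for p in proteins for j in range(rng.poisson(2))]
    )
    group = set(proteins[:10])
    prof = phosphosite_profile(
        sites, group, set(proteins), length_table=lengths, n_reps=10, seed=4
    )
    assert "background_length_matched" in prof
    assert prof["background_length_matched"].n_proteins == len(group)


def test_term_enrichment_whole_background_term():
    background = {f"P{i}" for i in range(20)}
    group = {f"P{i}" for i in range(5)}
    res = term_enrichment({"all": set(background)}, group, background)
    assert res[0].p_value == pytest.approx(1.0)
    assert res[0].fold == pytest.approx(1.0)


def test_term_enrichment_exact_group_term_is_minimal_p():
    background = {f"P{i}" for i in range(30)}
    group = {f"P{i}" for i in range(6)}
    membership = {"exact": set(group), "half": {f"P{i}" for i in range(3, 18)}}
    res = term_enrichment(membership, group, background)
    assert res[0].term == "exact"
    assert res[0].k == 6
    assert res[0].p_value == pytest.approx(
        1 / math.comb(30, 6), rel=1e-9
    )


def test_term_enrichment_group_outside_background_rejected():
    with pytest.raises(ValueError):
        term_enrichment({}, {"X"}, {"Y"})


def test_term_enrichment_null_calibration():
    rng = np.random.default_rng(5)
    background = [f"P{i}" for i in range(200)]
    membership = {
        f"T{t}": set(rng.choice(background, size=30, replace=False))
        for t in range(40)
    }
    frac_sig = []
    for seed in range(100):
        g = set(np.random.default_rng(seed).choice(background, size=40, replace=False))
        res = term_enrichment(membership, g, set(background))
        frac_sig.append(np.mean([r.p_adjusted < 0.05 for r in res]))
    assert np.mean(frac_sig) <= 0.05
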