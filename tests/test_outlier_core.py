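"""Ranking, outlier calling, permutation enrichment, DMRs, contrasts."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from tfbsmeth import outlier_core as oc
from tfbsmeth.models import MotifSite, SnvTfbsPair, Variant
from tfbsmeth.stats import fisher_exact_2x2, paired_t_test
from tfbsmeth.synthgen import SimConfig, generate_cohort


def make_pair(carriers, pos=500, tf="TF1", chrom="chr1", start=490, end=510):
    v = Variant(chrom, pos, "A", "T", frozenset(carriers))
    return SnvTfbsPair(v, tf, chrom, start, end, True, "+")


def one_probe_ranked(values, samples=None):
    samples = samples or [f"S{i+1}" for i in range(len(values))]
    beta = pd.DataFrame([values], index=["cg1"], columns=samples)
    return oc.rank_betas(beta)


# --- ranking ----------------------------------------------------------------

@pytest.mark.parametrize("values,expected", [
    ([0.3, 0.1, 0.2], [3, 1, 2]),
    ([0.2, 0.2, 0.1], [2, 3, 1]),  # tie between S1/S2 broken by sample id
])
def test_rank_examples(values, expected):
    ranked = one_probe_ranked(values)
    assert ranked.ranks.loc["cg1"].tolist() == expected


def test_ranks_are_a_permutation():
    rng = np.random.default_rng(0)
    beta = pd.DataFrame(rng.uniform(size=(30, 247)),
                        columns=[f"S{i:03d}" for i in range(247)])
    ranked = oc.rank_betas(beta)
    expect = set(range(1, 248))
    for _, row in ranked.ranks.iterrows():
        assert set(row) == expect
    assert ranked.ranks.to_numpy().min() == 1
    assert ranked.ranks.to_numpy().max() == 247


def test_tail_width_for_cohort_of_247():
    assert oc.tail_k(247, 0.05) == 12


# --- outlier calls ----------------------------------------------------------

def test_rank_13_is_not_an_outlier_at_n_247():
    values = list(np.linspace(0.0, 1.0, 247))
    samples = [f"S{i:03d}" for i in range(247)]
    ranked = oc.rank_betas(pd.DataFrame([values], index=["cg1"], columns=samples))
    carrier = samples[12]  # rank 13
    pair = make_pair([carrier])
    calls = oc.call_outliers(ranked, [pair], {pair.pair_id: ["cg1"]})
    assert calls == []


def test_top_rank_with_positive_delta_is_a_gain():
    rng = np.random.default_rng(1)
    values = list(rng.normal(0.5, 0.01, 246)) + [0.58]
    samples = [f"S{i:03d}" for i in range(247)]
    ranked = oc.rank_betas(pd.DataFrame([values], index=["cg1"], columns=samples))
    pair = make_pair([samples[246]])
    (call,) = oc.call_outliers(ranked, [pair], {pair.pair_id: ["cg1"]})
    assert call.rank == 247
    assert call.direction == "gain"
    assert call.delta_beta == pytest.approx(0.08, abs=0.01)


def test_identical_betas_yield_no_outlier():
    values = [0.5] * 247
    samples = [f"S{i:03d}" for i in range(247)]
    ranked = oc.rank_betas(pd.DataFrame([values], index=["cg1"], columns=samples))
    pair = make_pair([samples[0]])
    assert oc.call_outliers(ranked, [pair], {pair.pair_id: ["cg1"]}) == []


def test_small_tail_refused():
    ranked = one_probe_ranked([0.1, 0.2, 0.3, 0.4])
    pair = make_pair(["S1"])
    with pytest.raises(ValueError, match="tail"):
        oc.call_outliers(ranked, [pair], {pair.pair_id: ["cg1"]})


def test_null_extreme_cell_rate_bounded_by_tails():
    """Under a null cohort the per-cell extreme probability cannot exceed
    2k/n; the delta-beta requirement only lowers it."""
    cfg = SimConfig(n_samples=247, n_tfs=5, n_variants=50, n_motif_instances=50,
                    n_probes=2000, seed=13, frac_effect_tfs=0.0,
                    frac_nuisance_probes=0.0, frac_flagged_probes=0.0,
                    n_chroms=4, genome_length_per_chrom=2_000_000)
    cohort = generate_cohort(cfg)
    ranked = oc.rank_betas(cohort.beta)
    extreme = oc.extreme_cells(ranked)
    rate = extreme.to_numpy().mean()
    bound = 2 * oc.tail_k(247) / 247
    assert extreme.size > 100_000
    assert rate <= bound + 3 * np.sqrt(bound * (1 - bound) / extreme.size)


# --- enrichment ratio and permutation test ---------------------------------

@pytest.mark.parametrize("counts,expected", [
    ((2, 4, 10, 1000), 50.0),
    ((0, 4, 10, 1000), 0.0),
    ((1, 4, 0, 1000), np.inf),
])
def test_enrichment_ratio(counts, expected):
    assert oc.enrichment_ratio(*counts) == expected


def test_enrichment_ratio_empty_group_is_an_error():
    with pytest.raises(ValueError):
        oc.enrichment_ratio(1, 0, 1, 10)


def _tf_obs_from_beta(beta, pairs, pair_probes, k=1):
    ranked = oc.rank_betas(beta)
    extreme = oc.extreme_cells(ranked, k=k)
    return oc.build_tf_observations(extreme, pairs, pair_probes)


def test_permutation_matches_enumeration_on_random_small_cohorts():
    """Monte-Carlo p equals exhaustive enumeration within the add-one
    estimator's binomial error, for 6-sample cohorts with 1-2 carriers."""
    rng = np.random.default_rng(5)
    samples = [f"S{i}" for i in range(6)]
    for trial in range(5):
        beta = pd.DataFrame(rng.uniform(size=(4, 6)),
                            index=[f"cg{i}" for i in range(4)], columns=samples)
        pairs, pair_probes = [], {}
        for j, carriers in enumerate([("S0",), ("S2", "S4")]):
            p = make_pair(carriers, tf="TFX", pos=500 + j)
            pairs.append(p)
            pair_probes[p.pair_id] = [f"cg{2*j}", f"cg{2*j+1}"]
        obs = _tf_obs_from_beta(beta, pairs, pair_probes)["TFX"]
        exact = oc.permutation_test_tf("TFX", obs, method="exact", n_tfs_tested=1)
        B = 20_000
        mc = oc.permutation_test_tf("TFX", obs, n_perm=B, seed=trial,
                                    n_tfs_tested=1)
        se = np.sqrt(max(exact.p_raw * (1 - exact.p_raw), 1e-6) / B)
        assert abs(mc.p_raw - exact.p_raw) <= 4 * se + 2 / B


def test_no_outliers_gives_p_one():
    beta = pd.DataFrame([[0.5] * 6], index=["cg1"],
                        columns=[f"S{i}" for i in range(6)])
    pair = make_pair(["S0"])
    obs = _tf_obs_from_beta(beta, [pair], {pair.pair_id: ["cg1"]})["TF1"]
    r = oc.permutation_test_tf("TF1", obs, n_perm=500, seed=0, n_tfs_tested=1)
    assert r.observed_ratio == 0.0
    assert r.p_raw == 1.0


def test_infinite_ratio_permutation_p():
    """When only the carrier is ever extreme the observed ratio is infinite
    and a permutation beats it exactly when it re-draws the carrier, so
    p converges to 1/n."""
    rng = np.random.default_rng(2)
    vals = list(rng.normal(0.3, 0.005, 19)) + [0.8]
    samples = [f"S{i:02d}" for i in range(20)]
    beta = pd.DataFrame([vals], index=["cg1"], columns=samples)
    pair = make_pair(["S19"])
    obs = _tf_obs_from_beta(beta, [pair], {pair.pair_id: ["cg1"]})["TF1"]
    assert obs[0].e_counts.sum() == 1  # only the carrier cell is extreme
    r = oc.permutation_test_tf("TF1", obs, n_perm=6000, seed=1, n_tfs_tested=1)
    assert r.observed_ratio == np.inf
    assert r.p_raw == pytest.approx(1 / 20, abs=0.01)


def test_bonferroni_never_below_raw():
    beta = pd.DataFrame([[0.5] * 6], index=["cg1"],
                        columns=[f"S{i}" for i in range(6)])
    pair = make_pair(["S0"])
    obs = _tf_obs_from_beta(beta, [pair], {pair.pair_id: ["cg1"]})["TF1"]
    r = oc.permutation_test_tf("TF1", obs, n_perm=100, seed=0, n_tfs_tested=133)
    assert r.p_bonferroni >= r.p_raw
    assert r.p_bonferroni <= 1.0


# --- direction and association ----------------------------------------------

def _call(direction, probe="cg1", pair="p"):
    from tfbsmeth.models import OutlierCall
    return OutlierCall(probe, pair, "S1", 1, 0.1 if direction == "gain" else -0.1,
                       direction)


@pytest.mark.parametrize("gains,losses,expected", [
    (29, 20, 1.45), (5, 5, 1.0), (0, 5, 0.0),
])
def test_direction_enrichment(gains, losses, expected):
    calls = [_call("gain", probe=f"g{i}") for i in range(gains)] + \
            [_call("loss", probe=f"l{i}") for i in range(losses)]
    assert oc.direction_enrichment(calls) == pytest.approx(expected)


def test_direction_enrichment_zero_losses_is_infinite():
    assert oc.direction_enrichment([_call("gain")]) == np.inf


@pytest.mark.parametrize("n_probes,n_outliers,expected", [
    (3, 1, True), (4, 1, False), (1, 1, True),
])
def test_pair_association_one_third_rule(n_probes, n_outliers, expected):
    pair_probes = {"p": [f"cg{i}" for i in range(n_probes)]}
    calls = [_call("gain", probe=f"cg{i}") for i in range(n_outliers)]
    assert oc.pair_association(calls, pair_probes)["p"] is expected


def test_pair_with_no_probes_is_dropped():
    assert "p" not in oc.pair_association([], {"p": []})


# --- DMR caller -------------------------------------------------------------

def dmr_beta(positions, hot_probes, hot_sample="S00", n_samples=40, value=0.95,
             base=0.2, seed=0, directions=None):
    rng = np.random.default_rng(seed)
    probes = [f"cg{i}" for i in range(len(positions))]
    samples = [f"S{i:02d}" for i in range(n_samples)]
    beta = pd.DataFrame(rng.normal(base, 0.01, (len(probes), n_samples)).clip(0, 1),
                        index=probes, columns=samples)
    for k, p in enumerate(hot_probes):
        v = value if directions is None else (value if directions[k] == "hyper" else 0.01)
        beta.loc[p, hot_sample] = v
    manifest = pd.DataFrame({"chrom": "chr1", "cpg_pos": positions},
                            index=probes)
    return beta, manifest


def test_dmr_rule_oracle():
    """Three qualifying probes at 100/400/900 form one hyper DMR [100, 900]."""
    beta, manifest = dmr_beta([100, 400, 900, 5000], ["cg0", "cg1", "cg2"])
    dmrs = oc.detect_dmrs(beta, manifest)
    assert len(dmrs) == 1
    d = dmrs[0]
    assert (d.start, d.end, d.n_probes, d.direction, d.sample) == \
        (100, 900, 3, "hyper", "S00")


def test_two_qualifying_probes_are_not_enough():
    beta, manifest = dmr_beta([100, 400, 900], ["cg0", "cg1"])
    assert oc.detect_dmrs(beta, manifest) == []


def test_mixed_directions_do_not_form_a_dmr():
    beta, manifest = dmr_beta([100, 400, 900], ["cg0", "cg1", "cg2"],
                              directions=["hyper", "hypo", "hyper"])
    assert oc.detect_dmrs(beta, manifest) == []


def test_probes_outside_window_split_calls():
    """Qualifying probes further than 1 kb apart cannot share a DMR."""
    beta, manifest = dmr_beta([100, 400, 900, 2500, 2600, 2700],
                              [f"cg{i}" for i in range(6)])
    dmrs = oc.detect_dmrs(beta, manifest)
    assert len(dmrs) == 2
    for d in dmrs:
        assert d.end - d.start <= 1000


def test_dmr_output_is_order_invariant():
    beta, manifest = dmr_beta([100, 400, 900, 5000, 5100, 5300],
                              ["cg0", "cg1", "cg2", "cg3", "cg4", "cg5"])
    base = oc.detect_dmrs(beta, manifest)
    perm = np.random.default_rng(3).permutation(len(beta))
    shuffled = oc.detect_dmrs(beta.iloc[perm], manifest.iloc[perm])
    assert base == shuffled and len(base) == 2


def test_dmr_links_require_same_sample_and_eligibility(small_cohort):
    from tfbsmeth.models import DMR
    pair = make_pair(["S01"], pos=500, start=490, end=510)
    pair_probes = {pair.pair_id: ["cg0", "cg1", "cg2"]}
    calls = [_call("gain", probe="cg0", pair=pair.pair_id)]
    near_same = DMR("S01", "chr1", 700, 900, 3, "hyper")
    near_other = DMR("S02", "chr1", 700, 900, 3, "hyper")
    links, eligible = oc.dmr_tfbs_intersection([near_same, near_other], [pair],
                                               pair_probes, calls)
    assert eligible == [pair.pair_id]
    assert links[pair.pair_id] == [near_same]
    # two window CpGs -> excluded from the denominator
    links2, eligible2 = oc.dmr_tfbs_intersection(
        [near_same], [pair], {pair.pair_id: ["cg0", "cg1"]}, calls)
    assert eligible2 == [] and links2 == {}


# --- distance binning -------------------------------------------------------

def test_probe_distances_and_bins():
    pair = make_pair(["S1"], pos=100_500, start=100_490, end=100_510)
    manifest = pd.DataFrame(
        {"chrom": "chr1", "cpg_pos": [100_500, 101_000, 106_010, 90_000, 260_000]},
        index=[f"cg{i}" for i in range(5)])
    probes, d = oc.probe_distances([pair], manifest)[pair.pair_id]
    dist = dict(zip(probes, d))
    assert dist["cg0"] == 0                       # inside the motif
    assert dist["cg1"] == 101_000 - 1 - 100_510 + 1  # just past the end
    assert 5000 < dist["cg2"] <= 6000             # ~5.5 kb -> bin 1-10kb
    assert "cg4" not in dist                      # 160 kb away: out of range
    edges = list(oc.DEFAULT_BIN_EDGES_BP)
    bin_of = np.searchsorted(edges, dist["cg2"], side="left") - 1
    assert oc.bin_label(edges[bin_of], edges[bin_of + 1]) == "1-10kb"


def test_distance_analysis_excludes_local_cpgs():
    rng = np.random.default_rng(0)
    samples = [f"S{i:02d}" for i in range(40)]
    pair = make_pair([samples[0]], pos=50_000, start=49_990, end=50_010)
    manifest = pd.DataFrame({"chrom": "chr1", "cpg_pos": [50_100, 55_000]},
                            index=["local", "far"])
    beta = pd.DataFrame(rng.uniform(size=(2, 40)), index=manifest.index,
                        columns=samples)
    extreme = oc.extreme_cells(oc.rank_betas(beta), k=2)
    results = oc.distance_bin_analysis(extreme, [pair], manifest,
                                       n_perm=200, seed=0)
    assert {r.bin_label for r in results} == {"1-10kb"}
    assert all(r.n_cpg_obs == 1 for r in results)


# --- flank comparison and region overlap ------------------------------------

def test_flank_comparison_identical_vectors():
    enr = {f"chr{i}": 1.0 + 0.1 * i for i in range(1, 23)}
    fold, t, p, n = oc.flank_comparison(enr, dict(enr))
    assert fold == 1.0 and t == 0.0 and p == 1.0 and n == 22


def test_flank_comparison_zero_variance_shift():
    x = {f"chr{i}": 1.0 + 0.1 * i for i in range(1, 23)}
    y = {c: v - 0.5 for c, v in x.items()}
    fold, t, p, n = oc.flank_comparison(x, y)
    assert p == 0.0 and np.isinf(t)


def test_flank_comparison_matches_textbook_t():
    rng = np.random.default_rng(8)
    diffs = rng.normal(0.2, 0.1, 22)
    y = {f"chr{i+1}": 1.0 + rng.uniform(0, 0.3) for i in range(22)}
    x = {c: y[c] + diffs[i] for i, c in enumerate(sorted(y))}
    fold, t, p, n = oc.flank_comparison(x, y)
    xs = np.array([x[c] for c in sorted(x)])
    ys = np.array([y[c] for c in sorted(y)])
    d = xs - ys
    t_ref = d.mean() / (d.std(ddof=1) / np.sqrt(len(d)))
    assert t == pytest.approx(t_ref)
    assert p == pytest.approx(2 * sps.t.sf(abs(t_ref), len(d) - 1))


def test_flank_comparison_needs_three_chromosomes():
    fold, t, p, n = oc.flank_comparison({"chr1": 2.0, "chr2": 2.0},
                                        {"chr1": 1.0, "chr2": 1.0})
    assert p is None and fold == 2.0


def test_region_overlap_example():
    manifest = pd.DataFrame({"chrom": "chr1",
                             "cpg_pos": np.arange(1, 1001) * 10},
                            index=[f"cg{i}" for i in range(1000)])
    # two regions: one covers cg0..cg9 (pos 10..100), the other cg100..cg109
    regions = [("chr1", 0, 100), ("chr1", 1000, 1100)]
    outliers = [f"cg{i}" for i in range(100)]          # 10 in-region, 90 out
    rest = [f"cg{i}" for i in range(100, 1000)]        # 10 in-region, 890 out
    odds, p, table = oc.region_overlap_enrichment(outliers, rest, regions, manifest)
    assert table == [[10, 90], [10, 890]]
    assert odds == pytest.approx((10 * 890) / (90 * 10))
    assert p == pytest.approx(float(sps.fisher_exact(table).pvalue))


def test_region_overlap_degenerate_cases():
    manifest = pd.DataFrame({"chrom": "chr1", "cpg_pos": [10, 20, 30, 40]},
                            index=["a", "b", "c", "d"])
    odds, p, _ = oc.region_overlap_enrichment([], ["a", "b", "c", "d"],
                                              [("chr1", 0, 25)], manifest)
    assert odds is None and p == 1.0


# --- Fisher exact internals -------------------------------------------------

def test_fisher_matches_scipy_exhaustively():
    """The internal hypergeometric enumeration reproduces scipy's two-sided
    p on every table with entries up to 6 (margins up to 12)."""
    for a, b, c, d in itertools.product(range(7), repeat=4):
        table = [[a, b], [c, d]]
        _or, p = fisher_exact_2x2(table)
        assert p == pytest.approx(float(sps.fisher_exact(table).pvalue), abs=1e-9)


def test_paired_t_matches_scipy():
    rng = np.random.default_rng(1)
    x, y = rng.normal(size=10), rng.normal(size=10)
    t, p = paired_t_test(x, y)
    ref = sps.ttest_rel(x, y)
    assert t == pytest.approx(ref.statistic) and p == pytest.approx(ref.pvalue)
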