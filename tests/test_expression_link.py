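"""Expression z-scoring, small-cohort outliers, promoter assignment, Fisher."""

import numpy as np
import pandas as pd
import pytest

from tfbsmeth import outlier_core as oc
from tfbsmeth.expression_link import (
    expression_outlier_enrichment,
    promoter_pairs,
    residualize,
    small_cohort_outliers,
    zscore_expression,
)
from tfbsmeth.models import GeneModel, SnvTfbsPair, Variant


def make_pair(carriers, pos, tf="TF1", chrom="chr1"):
    v = Variant(chrom, pos, "A", "T", frozenset(carriers))
    return SnvTfbsPair(v, tf, chrom, pos - 10, pos + 5, True, "+")


# --- z-scores ---------------------------------------------------------------

def test_low_rpkm_and_flat_genes_are_dropped():
    rng = np.random.default_rng(0)
    expr = pd.DataFrame({
        "weak": rng.uniform(0, 1, 8),
        "flat": np.full(8, 5.0),
        "good": rng.normal(10, 2, 8),
    }).T
    expr.columns = [f"S{i}" for i in range(8)]
    rpkm = pd.Series({"weak": 0.5, "flat": 5.0, "good": 10.0})
    z = zscore_expression(expr, rpkm)
    assert list(z.index) == ["good"]
    assert z.loc["good"].mean() == pytest.approx(0.0, abs=1e-9)
    assert z.loc["good"].std(ddof=1) == pytest.approx(1.0, abs=1e-9)


def test_z_boundary_is_strict():
    """A value exactly 2 sample-sd above the mean is not an outlier."""
    vals = np.array([0.0, 0.0, 0.0, 0.0])
    vals = np.append(vals, 0.0)
    expr = pd.DataFrame([np.array([1.0, 2.0, 3.0, 4.0, 5.0])],
                        index=["g"], columns=[f"S{i}" for i in range(5)])
    z = zscore_expression(expr, pd.Series({"g": 2.0}))
    assert (z.abs() <= 2).all().all()
    assert not (z.abs() > 2).any().any()


# --- small-cohort outliers --------------------------------------------------

def _small_ranked(carrier_value, others_spread=0.004, n=20):
    rng = np.random.default_rng(1)
    vals = list(0.5 + rng.uniform(-others_spread, others_spread, n - 1))
    samples = [f"S{i:02d}" for i in range(n)]
    beta = pd.DataFrame([vals + [carrier_value]], index=["cg1"], columns=samples)
    return oc.rank_betas(beta), samples[-1]


@pytest.mark.parametrize("value,expected_calls", [
    (0.57, 1),    # rank 20, delta +0.07 -> outlier
    (0.5035, 0),  # inside the pack (rank != 1, 20)
    (0.46, 0),    # rank 1 but |delta| = 0.04 < 0.05
])
def test_small_cohort_extreme_rank_rules(value, expected_calls):
    ranked, carrier = _small_ranked(value)
    pair = make_pair([carrier], pos=500)
    calls = small_cohort_outliers(ranked, [pair], {pair.pair_id: ["cg1"]})
    assert len(calls) == expected_calls
    if calls:
        assert calls[0].rank in (1, 20)


def test_small_cohort_needs_four_samples():
    beta = pd.DataFrame([[0.1, 0.2, 0.9]], index=["cg1"],
                        columns=["S1", "S2", "S3"])
    with pytest.raises(ValueError):
        small_cohort_outliers(oc.rank_betas(beta), [], {})


# --- promoter assignment ----------------------------------------------------

def test_promoter_window_boundaries():
    genes = [GeneModel("G1", "chr1", "+", 10_000)]
    inside = make_pair(["S1"], pos=11_500)
    boundary = make_pair(["S1"], pos=12_000)
    outside = make_pair(["S1"], pos=12_001)
    assert promoter_pairs([inside], genes) == {inside.pair_id: "G1"}
    assert promoter_pairs([boundary], genes) == {boundary.pair_id: "G1"}
    assert promoter_pairs([outside], genes) == {}


def test_closest_gene_wins():
    genes = [GeneModel("NEAR", "chr1", "+", 10_000),
             GeneModel("FAR", "chr1", "+", 50_000)]
    pair = make_pair(["S1"], pos=11_000)
    assert promoter_pairs([pair], genes)[pair.pair_id] == "NEAR"


def test_interval_distance_mode():
    """With interval distance a TSS inside the merged interval is closest."""
    genes = [GeneModel("IN", "chr1", "+", 1000),
             GeneModel("NEARMID", "chr1", "+", 1080)]
    v = Variant("chr1", 1000, "A", "T", frozenset({"S1"}))
    pair = SnvTfbsPair(v, "TF1", "chr1", 990, 1010, True, "+")
    # midpoint 1000: NEARMID at |1080-1000|=80 vs IN at |1000-1000|=0 -> IN both
    assert promoter_pairs([pair], genes, distance="interval")[pair.pair_id] == "IN"


# --- enrichment -------------------------------------------------------------

def test_expression_enrichment_hand_table():
    """Pairs engineered to the 2x2 table [[4,16],[10,190]] give fold 4."""
    n_samples = 8
    samples = [f"S{i}" for i in range(n_samples)]
    rng = np.random.default_rng(0)
    pair_assoc, pair_gene, pair_carriers = {}, {}, {}
    z_rows = {}
    spec = [(True, True, 4), (True, False, 16), (False, True, 10),
            (False, False, 190)]
    k = 0
    for assoc, expr_out, count in spec:
        for _ in range(count):
            pid, gid = f"p{k}", f"g{k}"
            pair_assoc[pid] = assoc
            pair_gene[pid] = gid
            pair_carriers[pid] = ["S0"]
            row = rng.normal(0, 0.5, n_samples)
            row[0] = 3.0 if expr_out else 0.0
            z_rows[gid] = row
            k += 1
    z = pd.DataFrame(z_rows, index=samples).T
    fold, p, table = expression_outlier_enrichment(pair_assoc, pair_gene, z,
                                                   pair_carriers)
    assert table == [[4, 16], [10, 190]]
    assert fold == pytest.approx(4.0)
    assert 0 < p <= 1


def test_proportional_table_is_null():
    samples = ["S0", "S1", "S2", "S3"]
    pair_assoc, pair_gene, pair_carriers, z_rows = {}, {}, {}, {}
    k = 0
    for assoc, expr_out, count in [(True, True, 2), (True, False, 2),
                                   (False, True, 2), (False, False, 2)]:
        for _ in range(count):
            pid, gid = f"p{k}", f"g{k}"
            pair_assoc[pid], pair_gene[pid] = assoc, gid
            pair_carriers[pid] = ["S0"]
            z_rows[gid] = np.array([3.0 if expr_out else 0.0, 0.1, -0.1, 0.0])
            k += 1
    z = pd.DataFrame(z_rows, index=samples).T
    fold, p, table = expression_outlier_enrichment(pair_assoc, pair_gene, z,
                                                   pair_carriers)
    assert fold == pytest.approx(1.0)
    assert p == pytest.approx(1.0)


def test_per_gene_collapse_merges_pairs():
    samples = ["S0", "S1", "S2", "S3"]
    z = pd.DataFrame({"g1": [3.0, 0.0, 0.1, -0.1]}, index=samples).T
    pair_assoc = {"p1": True, "p2": False}
    pair_gene = {"p1": "g1", "p2": "g1"}
    carriers = {"p1": ["S0"], "p2": ["S0"]}
    _f, _p, per_pair = expression_outlier_enrichment(pair_assoc, pair_gene, z,
                                                     carriers)
    _f, _p, per_gene = expression_outlier_enrichment(pair_assoc, pair_gene, z,
                                                     carriers, per_gene=True)
    assert sum(map(sum, per_pair)) == 2
    assert sum(map(sum, per_gene)) == 1


def test_residualize_removes_covariate_signal():
    rng = np.random.default_rng(3)
    cov = pd.DataFrame({"age": rng.uniform(0, 50, 30)},
                       index=[f"S{i}" for i in range(30)])
    noise = rng.normal(0, 0.1, 30)
    expr = pd.DataFrame([2.0 * cov["age"].to_numpy() + noise],
                        index=["g"], columns=cov.index)
    resid = residualize(expr, cov)
    corr = np.corrcoef(resid.loc["g"], cov["age"])[0, 1]
    assert abs(corr) < 1e-8
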