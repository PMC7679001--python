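"""End-to-end validation experiments on synthetic cohorts.

Each function here generates a cohort under a named study condition, runs
the real pipeline on it and reduces the outcome to a small metrics dict.
They serve two purposes: the test suite asserts their statistical
properties (type-I error calibration, power on planted effects, DMR
sensitivity, distance decay, expression coupling), and the reproduction
script reports their numbers.

Problem sizes are chosen so each experiment runs in minutes on one core
while keeping the per-TF observation counts large enough for the
permutation p-values to be informative (see the methods note).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from scipy import stats as sps

from . import outlier_core as oc
from .models import SnvTfbsPair, Variant
from .pipeline import (
    AnalysisInput,
    AnalysisParams,
    AnalysisResult,
    analyze_cohort,
    dpwm_association_test,
    dpwm_bin_correlation,
)
from .stats import fisher_exact_2x2
from .synthgen import Cohort, SimConfig, generate_cohort


def cohort_to_input(cohort: Cohort) -> AnalysisInput:
    return AnalysisInput(beta=cohort.beta, manifest=cohort.manifest,
                         variants=cohort.variants, motifs=cohort.motifs,
                         pwms=cohort.pwms, fractions=cohort.fractions,
                         expression=cohort.expression,
                         rpkm_means=cohort.rpkm_means, genes=cohort.genes)


def _child_seed(seed: int, salt: int) -> int:
    return int(np.random.SeedSequence([seed, salt]).generate_state(1)[0] % (2**31))


# ---------------------------------------------------------------------------
# permutation exactness on a hand-built miniature cohort
# ---------------------------------------------------------------------------

def permutation_exactness(seed: int = 0, n_perm: int = 10_000) -> dict:
    """Four samples, one pair, one probe where only the carrier is extreme.

    The carrier's beta sits 0.09 above the tightly clustered controls, so
    with single-rank tails only the carrier cell is extreme; exact
    enumeration over the four possible carrier assignments gives p = 1/4
    and the Monte Carlo estimator must agree within its binomial error.
    """
    samples = ["S1", "S2", "S3", "S4"]
    beta = pd.DataFrame({"S1": [0.290], "S2": [0.200], "S3": [0.201],
                         "S4": [0.202]}, index=["cg1"])[samples]
    variant = Variant("chr1", 150, "A", "T", frozenset({"S1"}),
                      cohort_af=1 / 8, external_afs={})
    pair = SnvTfbsPair(variant, "TF1", "chr1", 140, 155, isolated=True, strand="+")
    ranked = oc.rank_betas(beta)
    extreme = oc.extreme_cells(ranked, delta_min=0.05, k=1)
    obs = oc.build_tf_observations(extreme, [pair], {pair.pair_id: ["cg1"]})
    exact = oc.permutation_test_tf("TF1", obs["TF1"], method="exact",
                                   n_tfs_tested=1)
    mc = oc.permutation_test_tf("TF1", obs["TF1"], n_perm=n_perm, seed=seed,
                                n_tfs_tested=1)
    return {"p_exact": exact.p_raw, "p_montecarlo": mc.p_raw,
            "observed_ratio": exact.observed_ratio, "n_samples": 4,
            "n_assignments": 4}


# ---------------------------------------------------------------------------
# type-I error calibration on a null cohort
# ---------------------------------------------------------------------------

NULL_CONFIG = dict(n_samples=247, n_tfs=133, n_variants=1330,
                   n_motif_instances=1330, n_probes=8500,
                   probes_per_window=6, carriers_min=2, carriers_max=2,
                   frac_effect_tfs=0.0, frac_flagged_probes=0.005,
                   frac_nuisance_probes=0.02, n_chroms=4,
                   genome_length_per_chrom=5_000_000)


def null_calibration(seed: int = 0, n_perm: int = 1000) -> dict:
    """Null cohort: per-TF permutation p-values should be uniform.

    133 TFs with ten two-carrier pairs each and six CpGs per window give
    every TF enough observation cells that the discrete atoms of the
    permutation p-value stay small; the raw p-values are compared with
    U(0,1) by a Kolmogorov-Smirnov test and the Bonferroni-significant TF
    count is reported.
    """
    cohort = generate_cohort(SimConfig(seed=_child_seed(seed, 1), **NULL_CONFIG))
    params = AnalysisParams(n_perm=n_perm, seed=_child_seed(seed, 2),
                            stages=("local",))
    res = analyze_cohort(cohort_to_input(cohort), params)
    p_raw = np.array([r.p_raw for r in res.tf_results])
    ks = sps.kstest(p_raw, "uniform")
    n_sig = int(sum(r.p_bonferroni < 0.05 for r in res.tf_results))
    return {"n_tfs": len(p_raw), "ks_stat": float(ks.statistic),
            "ks_p": float(ks.pvalue), "n_bonferroni_significant": n_sig,
            "p_values": p_raw}


# ---------------------------------------------------------------------------
# planted-effect recovery
# ---------------------------------------------------------------------------

def planted_recovery(seed: int = 0, n_perm: int = 10_000) -> dict:
    """Plant carrier beta shifts of 0.3 for 20 of 133 TFs and recover them.

    Ten two-carrier pairs per TF, five CpGs per +/-1 kb window.  Reports
    the fraction of planted TFs that are Bonferroni-significant, the
    fraction of planted pairs passing the 1/3 association rule, the number
    of false-positive TFs, and the gain/loss fold among outlier calls.
    """
    config = SimConfig(seed=_child_seed(seed, 1), n_samples=247, n_tfs=133,
                       n_variants=1330, n_motif_instances=1330, n_probes=7650,
                       probes_per_window=5, carriers_min=2, carriers_max=2,
                       frac_effect_tfs=20 / 133, effect_beta_shift=0.3,
                       frac_flagged_probes=0.005, frac_nuisance_probes=0.02,
                       n_chroms=4, genome_length_per_chrom=5_000_000)
    cohort = generate_cohort(config)
    params = AnalysisParams(n_perm=n_perm, seed=_child_seed(seed, 2),
                            stages=("local",))
    res = analyze_cohort(cohort_to_input(cohort), params)

    truth = cohort.truth
    planted_tfs = set(truth.loc[truth["planted"], "tf_name"])
    sig = {r.tf_name for r in res.tf_results if r.p_bonferroni < 0.05}
    planted_pairs = [f"{row.variant_key}|{row.tf_name}"
                     for row in truth.loc[truth["planted"]].itertuples()]
    assessed = [pid for pid in planted_pairs if pid in res.association]
    assoc_rate = (np.mean([res.association[pid] for pid in assessed])
                  if assessed else float("nan"))
    fold = res.direction_fold
    return {
        "n_planted_tfs": len(planted_tfs),
        "tf_sensitivity": len(planted_tfs & sig) / len(planted_tfs),
        "n_false_positive_tfs": len(sig - planted_tfs),
        "pair_association_rate": float(assoc_rate),
        "n_planted_pairs": len(planted_pairs),
        "gain_loss_fold": fold,
        "n_outlier_calls": len(res.calls),
    }


# ---------------------------------------------------------------------------
# delta-PWM coupling
# ---------------------------------------------------------------------------

def _pair_cpg_dbeta(res: AnalysisResult) -> tuple[list[float], list[float]]:
    """Per-CpG |delta-beta| (carrier mean vs controls) and the pair's delta-PWM."""
    beta = res.ranked.beta
    n = res.ranked.n
    col_index = {s: i for i, s in enumerate(beta.columns)}
    vals = beta.to_numpy()
    row_of = {p: i for i, p in enumerate(beta.index)}
    row_sums = vals.sum(axis=1)
    mags, deltas = [], []
    for pair in res.pairs:
        delta = res.deltas.get(pair.pair_id)
        if delta is None:
            continue
        probes = [p for p in res.pair_probes.get(pair.pair_id, []) if p in row_of]
        if not probes:
            continue
        c_idx = [col_index[s] for s in sorted(pair.variant.carriers)]
        rows = np.array([row_of[p] for p in probes])
        car = vals[np.ix_(rows, c_idx)]
        ctrl_mean = (row_sums[rows] - car.sum(axis=1)) / (n - len(c_idx))
        dbeta = car.mean(axis=1) - ctrl_mean
        mags.extend(np.abs(dbeta))
        deltas.extend([delta] * len(probes))
    return mags, deltas


def pwm_coupling(seed: int = 0, coupled: bool = True, n_tfs: int = 45,
                 pairs_per_tf: int = 30, n_perm: int = 200) -> dict:
    """Shift-vs-disruption coupling and its Wilcoxon / correlation readouts.

    Coupled condition: every pair of every TF carries a shift proportional
    to its delta-PWM (scale 0.5), so association with outlier methylation
    tracks motif constraint.  Decoupled condition: a random half of each
    TF's pairs receive a constant 0.3 shift, independent of delta-PWM, so
    the matched Wilcoxon test should reject only at its nominal level.
    """
    config = SimConfig(seed=_child_seed(seed, 1), n_samples=247, n_tfs=n_tfs,
                       n_variants=n_tfs * pairs_per_tf,
                       n_motif_instances=n_tfs * pairs_per_tf,
                       n_probes=n_tfs * pairs_per_tf * 5 + 500,
                       probes_per_window=5, carriers_min=2, carriers_max=2,
                       frac_effect_tfs=1.0,
                       effect_pwm_coupling=coupled,
                       effect_beta_shift=0.5 if coupled else 0.3,
                       frac_effect_pairs=1.0 if coupled else 0.5,
                       frac_flagged_probes=0.0, frac_nuisance_probes=0.0,
                       n_chroms=4, genome_length_per_chrom=5_000_000)
    cohort = generate_cohort(config)
    params = AnalysisParams(n_perm=n_perm, seed=_child_seed(seed, 2),
                            stages=("local",))
    res = analyze_cohort(cohort_to_input(cohort), params)
    wilcoxon_p, tf_table = dpwm_association_test(res.deltas, res.association,
                                                 res.pairs)
    mags, deltas = _pair_cpg_dbeta(res)
    bin_r, _bins = dpwm_bin_correlation(mags, deltas)
    spearman = None
    truth = cohort.truth
    planted = truth.loc[truth["planted"] & (truth["planted_shift"] != 0)]
    if coupled and len(planted) > 2:
        spearman = float(sps.spearmanr(np.abs(planted["planted_shift"]),
                                       planted["delta_pwm"]).statistic)
    return {"wilcoxon_p": wilcoxon_p, "n_tfs_tested": len(tf_table),
            "bin_correlation": bin_r, "truth_shift_spearman": spearman}


# ---------------------------------------------------------------------------
# DMR caller
# ---------------------------------------------------------------------------

def dmr_validation(seed: int = 0) -> dict:
    """Sensitivity on planted <=1 kb clusters plus a null-rate bound.

    Planted condition: 200 variants, each with four probes within +/-400 bp
    (cluster span < 1 kb) shifted by 0.25 in one carrier.  Null condition:
    same geometry, no effects, no nuisance probes; the mean per-sample DMR
    count is compared with the analytic union bound obtained from the
    nearest-rank tail probability q = floor(0.05 n)/n per direction,
    ignoring the additional |beta - mean| >= 0.1 requirement.
    """
    base = dict(n_samples=247, n_tfs=20, n_variants=200, n_motif_instances=200,
                n_probes=2000, probes_per_window=4, probe_window_bp=400,
                carriers_min=1, carriers_max=1, frac_flagged_probes=0.0,
                frac_nuisance_probes=0.0, n_chroms=4,
                genome_length_per_chrom=2_000_000)
    planted_cfg = SimConfig(seed=_child_seed(seed, 1), frac_effect_tfs=1.0,
                            effect_beta_shift=0.25, **base)
    cohort = generate_cohort(planted_cfg)
    dmrs = oc.detect_dmrs(cohort.beta, cohort.manifest)
    by_sample_chrom: dict[tuple[str, str], list] = {}
    for d in dmrs:
        by_sample_chrom.setdefault((d.sample, d.chrom), []).append(d)
    recovered = 0
    planted_rows = cohort.truth.loc[cohort.truth["planted"]]
    variant_of = {v.key: v for v in cohort.variants}
    for row in planted_rows.itertuples():
        v = variant_of[row.variant_key]
        carrier = sorted(v.carriers)[0]
        probes = row.affected_probes.split(",")
        pos = cohort.manifest.loc[probes, "cpg_pos"]
        lo, hi = int(pos.min()), int(pos.max())
        hit = any(d.start <= hi and d.end >= lo
                  for d in by_sample_chrom.get((carrier, v.chrom), []))
        recovered += hit
    sensitivity = recovered / len(planted_rows)

    null_cfg = SimConfig(seed=_child_seed(seed, 2), frac_effect_tfs=0.0, **base)
    null = generate_cohort(null_cfg)
    null_dmrs = oc.detect_dmrs(null.beta, null.manifest)
    n = null.beta.shape[1]
    q = np.floor(0.05 * n) / n
    manifest = null.manifest.sort_values(["chrom", "cpg_pos"])
    bound = 0.0
    for _c, g in manifest.groupby("chrom"):
        pos = g["cpg_pos"].to_numpy()
        m_i = np.searchsorted(pos, pos + 1000, side="right") - np.arange(len(pos))
        bound += float(sps.binom.sf(2, m_i, q).sum())
    bound *= 2  # both directions
    mean_null = len(null_dmrs) / n
    return {"sensitivity": sensitivity, "n_planted": len(planted_rows),
            "null_mean_dmrs_per_sample": mean_null,
            "null_analytic_bound": bound,
            "n_null_dmrs": len(null_dmrs)}


# ---------------------------------------------------------------------------
# distance decay
# ---------------------------------------------------------------------------

def distance_decay_validation(seed: int = 0, n_perm: int = 10_000) -> dict:
    """Planted effects decaying as exp(-d / 15 kb) over +/-100 kb windows.

    Twenty TFs with ten two-carrier pairs each; thirty probes per window
    spread uniformly over +/-100 kb, so every 10-kb distance bin holds
    about three CpGs per pair.  Significant (Bonferroni) bins should be
    confined below ~30-50 kb where the decayed shift still clears the 0.05
    delta-beta criterion.
    """
    config = SimConfig(seed=_child_seed(seed, 1), n_samples=247, n_tfs=20,
                       n_variants=200, n_motif_instances=200, n_probes=6500,
                       probes_per_window=30, probe_window_bp=100_000,
                       carriers_min=2, carriers_max=2, frac_effect_tfs=1.0,
                       effect_beta_shift=0.3, distance_decay=True,
                       decay_tau_bp=15_000, frac_flagged_probes=0.0,
                       frac_nuisance_probes=0.0, n_chroms=4,
                       genome_length_per_chrom=15_000_000)
    cohort = generate_cohort(config)
    params = AnalysisParams(n_perm=n_perm, seed=_child_seed(seed, 2),
                            stages=("local", "distance"))
    res = analyze_cohort(cohort_to_input(cohort), params)
    sig_per_bin: dict[str, int] = {}
    for r in res.distance_results:
        sig_per_bin.setdefault(r.bin_label, 0)
        sig_per_bin[r.bin_label] += r.p_bonferroni < 0.05
    edges = list(oc.DEFAULT_BIN_EDGES_BP)
    max_sig_kb = 0
    max_multi_kb = 0
    for bi in range(len(edges) - 1):
        label = oc.bin_label(edges[bi], edges[bi + 1])
        if sig_per_bin.get(label, 0) > 0:
            max_sig_kb = edges[bi + 1] // 1000
        if sig_per_bin.get(label, 0) > 1:  # beyond a single chance-level hit
            max_multi_kb = edges[bi + 1] // 1000
    return {"significant_tfs_per_bin": sig_per_bin,
            "max_significant_bin_kb": max_sig_kb,
            "max_bin_multiple_significant_kb": max_multi_kb,
            "n_sig_90_100kb": sig_per_bin.get("90-100kb", 0)}


# ---------------------------------------------------------------------------
# expression integration
# ---------------------------------------------------------------------------

def expression_enrichment_run(seed: int = 0, planted: bool = True) -> dict:
    """One small-cohort expression integration run (20 samples, 550 pairs).

    Planted condition: 5 of 55 TFs (50 pairs) couple a 0.3 promoter
    methylation shift in the single carrier to a 3-standard-deviation
    expression shift of the assigned gene.  Returns the Fisher fold, exact
    p, and a randomized (fuzzy) p that is exactly U(0,1) under the null.
    """
    config = SimConfig(seed=_child_seed(seed, 1), n_samples=20, n_tfs=55,
                       n_variants=550, n_motif_instances=550, n_probes=1850,
                       probes_per_window=3, probe_window_bp=1000,
                       carriers_min=1, carriers_max=1, af_reference_n=247,
                       frac_effect_tfs=(5 / 55 if planted else 0.0),
                       effect_beta_shift=0.3, expression_effect_z=3.0,
                       with_expression=True, frac_flagged_probes=0.0,
                       frac_nuisance_probes=0.0, n_chroms=4,
                       genome_length_per_chrom=5_000_000)
    cohort = generate_cohort(config)
    params = AnalysisParams(n_perm=100, seed=_child_seed(seed, 2),
                            stages=("local", "expression"))
    res = analyze_cohort(cohort_to_input(cohort), params)
    table = res.expression_table
    # randomized p-value for calibration checks: subtract a uniform share
    # of the observed table's own probability mass
    (a, b), (c, d) = table
    p_exact = res.expression_p
    pmf_obs = float(sps.hypergeom.pmf(a, a + b + c + d, a + b, a + c)) \
        if min(a + b, c + d, a + c, b + d) > 0 else 1.0
    u = np.random.default_rng(_child_seed(seed, 3)).random()
    p_fuzzy = max(0.0, p_exact - u * pmf_obs)
    n_planted = int(cohort.truth["planted"].sum())
    return {"fold": res.expression_fold, "p": p_exact, "p_fuzzy": p_fuzzy,
            "table": table, "n_planted_pairs": n_planted}


def expression_power(seed: int = 0, n_seeds: int = 100) -> dict:
    """Detection rate of the planted expression coupling over replicates."""
    hits = 0
    folds = []
    for i in range(n_seeds):
        out = expression_enrichment_run(_child_seed(seed, 100 + i), planted=True)
        ok = (out["fold"] is not None and out["fold"] > 1
              and out["p"] < 0.05)
        hits += ok
        if out["fold"] is not None and np.isfinite(out["fold"]):
            folds.append(out["fold"])
    return {"detection_rate": hits / n_seeds, "n_seeds": n_seeds,
            "median_fold": float(np.median(folds)) if folds else None}


def expression_null_calibration(seed: int = 0, n_seeds: int = 200) -> dict:
    """Uniformity of the expression-enrichment p-value under the null.

    The exact Fisher p is discrete and conservative, so uniformity is
    checked on the randomized (fuzzy) transform, which is exactly U(0,1)
    when the test is calibrated; anticonservatism of the exact p is
    additionally bounded directly at the 5% level.
    """
    p_exact, p_fuzzy = [], []
    for i in range(n_seeds):
        out = expression_enrichment_run(_child_seed(seed, 500 + i), planted=False)
        p_exact.append(out["p"])
        p_fuzzy.append(out["p_fuzzy"])
    ks = sps.kstest(p_fuzzy, "uniform")
    frac_sig = float(np.mean(np.array(p_exact) < 0.05))
    return {"ks_stat": float(ks.statistic), "ks_p": float(ks.pvalue),
            "frac_exact_p_below_0.05": frac_sig, "n_seeds": n_seeds}


# ---------------------------------------------------------------------------
# small-oracle equivalence checks
# ---------------------------------------------------------------------------

def oracle_checks(seed: int = 0) -> dict:
    """Brute-force agreement checks on small instances.

    Covers the enrichment ratio, interval intersection/merging, delta-PWM
    strand handling, and the Fisher exact p, each against an independent
    computation.
    """
    from .variant_motif import delta_pwm, intersect_and_merge
    from .models import MotifSite, PWM as PWMModel, variant_overlaps

    rng = np.random.default_rng(seed)
    # enrichment ratio vs plain arithmetic
    ratio = oc.enrichment_ratio(2, 4, 10, 1000)
    ratio_err = abs(ratio - (2 / 4) / (10 / 1000))

    # intersection vs O(V x M) scan on a random instance
    motifs = []
    for _ in range(200):
        s = int(rng.integers(0, 5000))
        motifs.append(MotifSite("chr1", s, s + int(rng.integers(8, 21)),
                                f"TF{int(rng.integers(1, 6))}", "+"))
    variants = [Variant("chr1", int(rng.integers(1, 5001)), "A", "C",
                        frozenset({"S1"})) for _ in range(100)]
    pairs = intersect_and_merge(variants, motifs)
    expected = set()
    for v in variants:
        for m in motifs:
            if variant_overlaps(v.pos, m.start, m.end):
                expected.add((v.key, m.tf_name))
    merge_mismatch = int(len({(p.variant.key, p.tf_name) for p in pairs}
                             ^ expected))

    # delta-PWM strand involution
    probs = rng.dirichlet(np.ones(4), size=12).T
    pwm_f = PWMModel("TFX", probs)
    pwm_r = pwm_f.reverse_complement()
    v = Variant("chr1", 105, "A", "G", frozenset({"S1"}))
    pair_f = SnvTfbsPair(v, "TFX", "chr1", 100, 112, True, "+")
    pair_r = SnvTfbsPair(v, "TFX", "chr1", 100, 112, True, "-")
    d_f = delta_pwm(pair_f, {"TFX": pwm_f}).delta
    d_r = delta_pwm(pair_r, {"TFX": pwm_r}).delta
    strand_err = abs(d_f - d_r)

    # Fisher exact vs the scipy implementation over small tables
    max_fisher_err = 0.0
    for _ in range(50):
        t = rng.integers(0, 12, size=4)
        table = [[int(t[0]), int(t[1])], [int(t[2]), int(t[3])]]
        _or, p = fisher_exact_2x2(table)
        p_ref = float(sps.fisher_exact(table).pvalue)
        max_fisher_err = max(max_fisher_err, abs(p - p_ref))
    return {"enrichment_ratio_error": float(ratio_err),
            "merge_mismatches": merge_mismatch,
            "strand_involution_error": float(strand_err),
            "max_fisher_abs_error": float(max_fisher_err)}
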