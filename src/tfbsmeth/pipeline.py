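"""End-to-end orchestration: probe QC -> SNV x TFBS pairing -> outlier
statistics -> optional DMR / distance / flank / expression stages.

:func:`analyze_cohort` runs the whole analysis on in-memory objects and is
what the validation experiments and tests drive; :func:`run_pipeline` wraps
it with file I/O, result tables and a JSON run manifest so the same
analysis is reproducible from the command line.
"""

from __future__ import annotations

import hashlib
import json
import logging
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from . import io as fio
from . import outlier_core as oc
from .expression_link import (
    expression_outlier_enrichment,
    promoter_pairs,
    zscore_expression,
)
from .models import DMR, GeneModel, OutlierCall, PermutationResult, PWM, SnvTfbsPair, Variant
from .preprocess import ProbeFilterReport, apply_filters
from .variant_motif import delta_pwm, filter_rare_variants, find_flank_snvs, intersect_and_merge

log = logging.getLogger(__name__)

ALL_STAGES = ("local", "dmr", "distance", "flank", "expression")


@dataclass
class AnalysisParams:
    """Thresholds of the analysis; defaults are the reference settings.

    5% rank tails with |delta-beta| >= 0.05, +/-1 kb windows, 10,000
    permutations, the 1/3 pair-association rule, TSS +/- 2 kb promoters and
    a 5% cell-fraction exclusion quota.
    """

    tail_frac: float = 0.05
    delta_min: float = 0.05
    flank_bp: int = 1000
    n_perm: int = 10_000
    seed: int = 0
    min_frac: float = 1 / 3
    dmr_window_bp: int = 1000
    dmr_min_probes: int = 3
    dmr_pct: float = 0.95
    dmr_delta: float = 0.1
    bin_edges_bp: Sequence[int] = oc.DEFAULT_BIN_EDGES_BP
    promoter_bp: int = 2000
    z_max: float = 2.0
    min_rpkm: float = 1.0
    cellfrac_quota: float = 0.05
    cohort_maf_max: float = 0.01
    external_maf_max: float = 0.01
    max_carriers: int = 2
    pwm_score_method: str = "prob"
    stages: tuple[str, ...] = ALL_STAGES

    def tail_width(self, n: int) -> int:
        """Ranks per tail: floor(tail_frac * n), at least the single extreme."""
        return max(1, int(math.floor(self.tail_frac * n)))


@dataclass
class AnalysisInput:
    beta: pd.DataFrame
    manifest: pd.DataFrame
    variants: list[Variant]
    motifs: list
    pwms: dict[str, PWM]
    fractions: Optional[pd.DataFrame] = None
    expression: Optional[pd.DataFrame] = None
    rpkm_means: Optional[pd.Series] = None
    genes: Optional[list[GeneModel]] = None
    blacklist: Optional[list] = None
    regions: Optional[list] = None


@dataclass
class AnalysisResult:
    params: AnalysisParams
    filter_report: ProbeFilterReport
    rare_variants: list[Variant]
    pairs: list[SnvTfbsPair]
    pair_probes: dict[str, list[str]]
    ranked: oc.RankedCpGs
    extreme: pd.DataFrame
    calls: list[OutlierCall]
    association: dict[str, bool]
    tf_results: list[PermutationResult]
    direction_fold: Optional[float] = None
    deltas: dict[str, float] = field(default_factory=dict)
    dmrs: list[DMR] = field(default_factory=list)
    dmr_links: dict[str, list[DMR]] = field(default_factory=dict)
    dmr_eligible: list[str] = field(default_factory=list)
    distance_results: list[PermutationResult] = field(default_factory=list)
    flank_fold: Optional[float] = None
    flank_p: Optional[float] = None
    expression_fold: Optional[float] = None
    expression_p: Optional[float] = None
    expression_table: Optional[list[list[int]]] = None
    region_odds: Optional[float] = None
    region_p: Optional[float] = None


def analyze_cohort(inp: AnalysisInput, params: AnalysisParams) -> AnalysisResult:
    """Run the full outlier analysis on loaded data."""
    rare = filter_rare_variants(inp.variants, params.cohort_maf_max,
                                params.external_maf_max, params.max_carriers)
    pairs = intersect_and_merge(rare, inp.motifs)
    pair_variants = list({id(p.variant): p.variant for p in pairs}.values())

    report = apply_filters(inp.manifest, inp.beta, inp.fractions,
                           snv_tfbs_variants=pair_variants,
                           blacklist=inp.blacklist,
                           max_excluded_frac=params.cellfrac_quota)
    manifest = inp.manifest.loc[report.surviving]
    beta = inp.beta.loc[report.surviving]

    ranked = oc.rank_betas(beta)
    k = params.tail_width(ranked.n)
    extreme = oc.extreme_cells(ranked, params.tail_frac, params.delta_min, k=k)
    pair_probes = oc.assign_probes_to_pairs(pairs, manifest, params.flank_bp)
    calls = oc.call_outliers(ranked, pairs, pair_probes, params.tail_frac,
                             params.delta_min, k=k)
    association = oc.pair_association(calls, pair_probes, params.min_frac)

    tf_obs = oc.build_tf_observations(extreme, pairs, pair_probes)
    tf_results = oc.run_tf_permutations(tf_obs, n_perm=params.n_perm,
                                        seed=params.seed)
    direction_fold = None
    if any(c.direction == "loss" for c in calls):
        direction_fold = oc.direction_enrichment(calls)

    deltas: dict[str, float] = {}
    for p in pairs:
        pwm = inp.pwms.get(p.tf_name)
        if p.isolated and pwm is not None and p.end - p.start == pwm.width:
            deltas[p.pair_id] = delta_pwm(p, inp.pwms,
                                          method=params.pwm_score_method).delta

    result = AnalysisResult(params=params, filter_report=report,
                            rare_variants=rare, pairs=pairs,
                            pair_probes=pair_probes, ranked=ranked,
                            extreme=extreme, calls=calls,
                            association=association, tf_results=tf_results,
                            direction_fold=direction_fold, deltas=deltas)

    if "dmr" in params.stages:
        result.dmrs = oc.detect_dmrs(beta, manifest, params.dmr_window_bp,
                                     params.dmr_min_probes, params.dmr_pct,
                                     params.dmr_delta)
        result.dmr_links, result.dmr_eligible = oc.dmr_tfbs_intersection(
            result.dmrs, pairs, pair_probes, calls, params.flank_bp,
            params.dmr_min_probes)

    if "distance" in params.stages:
        result.distance_results = oc.distance_bin_analysis(
            extreme, pairs, manifest, params.bin_edges_bp,
            n_perm=params.n_perm, seed=params.seed)

    if "flank" in params.stages:
        flank_vars = find_flank_snvs(rare, inp.motifs, params.flank_bp)
        if flank_vars:
            flank_pairs = [SnvTfbsPair(v, "__flank__", v.chrom, v.pos - 1, v.pos,
                                       isolated=True, strand="+")
                           for v in flank_vars]
            fp_probes = oc.assign_probes_to_pairs(flank_pairs, manifest,
                                                  params.flank_bp)
            tf_all = [o for group in tf_obs.values() for o in group]
            fl_obs = [o for group in oc.build_tf_observations(
                extreme, flank_pairs, fp_probes).values() for o in group]
            try:
                fold, _t, p, _n = oc.flank_comparison(
                    oc.chrom_enrichments(tf_all), oc.chrom_enrichments(fl_obs))
                result.flank_fold, result.flank_p = fold, p
            except ValueError as err:
                log.info("flank stage skipped: %s", err)

    if ("expression" in params.stages and inp.expression is not None
            and inp.genes is not None):
        rpkm = (inp.rpkm_means if inp.rpkm_means is not None
                else inp.expression.mean(axis=1))
        z = zscore_expression(inp.expression, rpkm, params.min_rpkm)
        pair_gene = promoter_pairs(pairs, inp.genes, params.promoter_bp)
        carriers = {p.pair_id: sorted(p.variant.carriers) for p in pairs}
        fold, p, table = expression_outlier_enrichment(
            association, pair_gene, z, carriers, params.z_max)
        result.expression_fold, result.expression_p = fold, p
        result.expression_table = table

    if inp.regions:
        outlier_probes = sorted({c.probe_id for c in calls})
        window_probes = sorted({p for probes in pair_probes.values() for p in probes})
        non_outlier = [p for p in window_probes if p not in set(outlier_probes)]
        odds, p, _table = oc.region_overlap_enrichment(
            outlier_probes, non_outlier, inp.regions, manifest)
        result.region_odds, result.region_p = odds, p

    return result


# ---------------------------------------------------------------------------
# constraint (delta-PWM) analyses
# ---------------------------------------------------------------------------

def dpwm_association_test(deltas: dict[str, float], association: dict[str, bool],
                          pairs: Sequence[SnvTfbsPair], min_per_group: int = 1
                          ) -> tuple[Optional[float], pd.DataFrame]:
    """Matched-pairs Wilcoxon test of delta-PWM by outlier association.

    For each TF with scored isolated pairs in both groups, the medians of
    delta-PWM among associated and non-associated pairs form one matched
    observation; the two-sided Wilcoxon signed-rank test compares them
    across TFs.  Returns ``(p, per_tf_table)``; p is None when fewer than
    three TFs are informative.
    """
    tf_of = {p.pair_id: p.tf_name for p in pairs}
    rows = []
    for tf in sorted({tf_of[pid] for pid in deltas if pid in association}):
        assoc_d = [deltas[pid] for pid in deltas
                   if tf_of[pid] == tf and association.get(pid) is True]
        other_d = [deltas[pid] for pid in deltas
                   if tf_of[pid] == tf and association.get(pid) is False]
        if len(assoc_d) >= min_per_group and len(other_d) >= min_per_group:
            rows.append((tf, float(np.median(assoc_d)), float(np.median(other_d)),
                         len(assoc_d), len(other_d)))
    table = pd.DataFrame(rows, columns=["tf_name", "median_dpwm_assoc",
                                        "median_dpwm_other", "n_assoc", "n_other"])
    if len(table) < 3:
        return None, table
    x = table["median_dpwm_assoc"].to_numpy()
    y = table["median_dpwm_other"].to_numpy()
    if np.allclose(x, y):
        return 1.0, table
    _stat, p = sps.wilcoxon(x, y)
    return float(p), table


def dpwm_bin_correlation(calls_dbeta: Sequence[float], calls_delta: Sequence[float],
                         n_bins: int = 8) -> tuple[Optional[float], pd.DataFrame]:
    """Per-bin medians of delta-PWM against methylation-change magnitude.

    CpG observations are grouped into ``n_bins`` equal-count bins of
    |delta-beta| and the Pearson correlation between the per-bin median
    delta-PWM and median |delta-beta| is returned.
    """
    mags = np.abs(np.asarray(calls_dbeta, dtype=float))
    deltas = np.asarray(calls_delta, dtype=float)
    if len(mags) < n_bins:
        return None, pd.DataFrame()
    order = np.argsort(mags, kind="mergesort")
    splits = np.array_split(order, n_bins)
    rows = [(i, float(np.median(mags[idx])), float(np.median(deltas[idx])), len(idx))
            for i, idx in enumerate(splits) if len(idx)]
    table = pd.DataFrame(rows, columns=["bin", "median_abs_dbeta",
                                        "median_dpwm", "n_cpgs"])
    if len(table) < 3 or table["median_dpwm"].nunique() == 1:
        return None, table
    r, _p = sps.pearsonr(table["median_abs_dbeta"], table["median_dpwm"])
    return float(r), table


# ---------------------------------------------------------------------------
# file-driven run
# ---------------------------------------------------------------------------

@dataclass
class RunConfig:
    """Paths and thresholds for a command-line run."""

    vcf: str
    motifs: str
    pwms: str
    beta: str
    manifest: str
    out_dir: str
    fractions: Optional[str] = None
    expression: Optional[str] = None
    genes: Optional[str] = None
    blacklist: Optional[str] = None
    regions: Optional[str] = None
    params: AnalysisParams = field(default_factory=AnalysisParams)


def _load_inputs(cfg: RunConfig) -> AnalysisInput:
    variants, _skipped = fio.load_variants(cfg.vcf)
    motifs = fio.load_motifs(cfg.motifs)
    pwms = fio.load_pwms(cfg.pwms)
    beta, manifest = fio.load_beta(cfg.beta, cfg.manifest)
    fractions = fio.load_cell_fractions(cfg.fractions) if cfg.fractions else None
    expression = rpkm = genes = None
    if cfg.expression:
        expression, rpkm = fio.load_expression(cfg.expression)
    if cfg.genes:
        genes = fio.load_gene_models(cfg.genes)
    blacklist = None
    if cfg.blacklist:
        blacklist = [line.strip() for line in open(cfg.blacklist)
                     if line.strip() and not line.startswith("#")]
    regions = fio.load_regions(cfg.regions) if cfg.regions else None
    return AnalysisInput(beta=beta, manifest=manifest, variants=variants,
                         motifs=motifs, pwms=pwms, fractions=fractions,
                         expression=expression, rpkm_means=rpkm, genes=genes,
                         blacklist=blacklist, regions=regions)


def run_pipeline(cfg: RunConfig) -> dict:
    """Execute the configured stages and write result tables + manifest.

    Returns the run manifest (also written to ``out_dir/manifest.json``);
    re-running with the same config and seed reproduces every output file
    byte for byte.
    """
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    inp = _load_inputs(cfg)
    res = analyze_cohort(inp, cfg.params)

    fio.write_outlier_calls(res.calls, out / "outlier_calls.tsv")
    fio.write_tf_results(res.tf_results, out / "tf_results.tsv")
    pair_rows = []
    for p in res.pairs:
        pair_rows.append({
            "pair_id": p.pair_id, "tf_name": p.tf_name, "chrom": p.chrom,
            "start": p.start, "end": p.end, "isolated": p.isolated,
            "n_window_cpgs": len(res.pair_probes.get(p.pair_id, [])),
            "associated": res.association.get(p.pair_id, ""),
            "delta_pwm": res.deltas.get(p.pair_id, ""),
        })
    fio.write_pair_table(pair_rows, out / "pairs.tsv")
    res.filter_report.to_frame().to_csv(out / "probe_filters.tsv",
                                        sep="\t", index=False)
    stage_counts = {"pairs": len(res.pairs), "outlier_calls": len(res.calls),
                    "tf_results": len(res.tf_results)}
    if "dmr" in cfg.params.stages:
        fio.write_dmrs(res.dmrs, out / "dmrs.bed")
        stage_counts["dmrs"] = len(res.dmrs)
        stage_counts["dmr_linked_pairs"] = len(res.dmr_links)
    if "distance" in cfg.params.stages:
        fio.write_tf_results(res.distance_results, out / "distance_results.tsv")
        stage_counts["distance_results"] = len(res.distance_results)

    cfg_dict = asdict(cfg)
    cfg_dict["params"]["bin_edges_bp"] = list(cfg.params.bin_edges_bp)
    cfg_dict["params"]["stages"] = list(cfg.params.stages)
    cfg_json = json.dumps(cfg_dict, sort_keys=True)
    manifest = {
        "config": cfg_dict,
        "config_sha256": hashlib.sha256(cfg_json.encode()).hexdigest(),
        "seed": cfg.params.seed,
        "stages_run": list(cfg.params.stages),
        "n_samples": res.ranked.n,
        "n_probes_surviving": len(res.filter_report.surviving),
        "probe_filter_counts": res.filter_report.counts,
        "stage_row_counts": stage_counts,
        "direction_fold": res.direction_fold,
        "flank_fold": res.flank_fold, "flank_p": res.flank_p,
        "expression_fold": res.expression_fold, "expression_p": res.expression_p,
        "region_odds": res.region_odds, "region_p": res.region_p,
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest
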