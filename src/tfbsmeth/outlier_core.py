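"""Rank-based methylation outlier statistics and permutation enrichment.

The central quantities, per CpG probe across the cohort:

* ascending ordinal **ranks** of beta values over the n samples (ties broken
  by sample id, so ranking is deterministic);
* a per-sample **delta-beta**, the sample's beta minus the mean beta of the
  remaining samples;
* an **extreme cell** indicator per (probe, sample): rank in the 5% tails
  (``k = floor(tail_frac * n)`` ranks per tail) and |delta-beta| >= 0.05.

A carrier-level *outlier call* additionally measures delta-beta against the
non-carriers of the specific variant.  Per-TF enrichment pools (probe,
sample) cells over all of a TF's SNV-TFBS windows: the enrichment ratio is
the fraction of extreme cells among carrier cells over the fraction among
non-carrier cells, and its significance comes from permutations that
reassign each pair's carrier labels to random same-size sample subsets.
The permutation p-value uses the add-one estimator (1 + hits)/(1 + B) so
that reported p-values are never zero; an exact mode enumerates every
carrier assignment instead, which is feasible for small cohorts.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .models import DMR, OutlierCall, PermutationResult, SnvTfbsPair
from .stats import fisher_exact_2x2, paired_t_test

log = logging.getLogger(__name__)

DEFAULT_BIN_EDGES_BP = tuple([1000] + [10_000 * i for i in range(1, 11)])


# ---------------------------------------------------------------------------
# ranking
# ---------------------------------------------------------------------------

@dataclass
class RankedCpGs:
    """Per-probe sample ranks plus leave-one-out delta-beta."""

    beta: pd.DataFrame        # probes x samples
    ranks: pd.DataFrame       # int, 1..n per probe
    loo_delta: pd.DataFrame   # beta - mean(beta of all other samples)

    @property
    def n(self) -> int:
        return self.beta.shape[1]

    @property
    def samples(self) -> list[str]:
        return list(self.beta.columns)


def rank_betas(beta: pd.DataFrame, probes: Optional[Sequence[str]] = None) -> RankedCpGs:
    """Ascending ordinal ranks of beta per probe; ties broken by sample id."""
    if probes is not None:
        beta = beta.loc[list(probes)]
    # order columns lexicographically so a stable argsort breaks ties by id
    cols_sorted = sorted(beta.columns)
    vals = beta[cols_sorted].to_numpy(dtype=float)
    order = np.argsort(vals, axis=1, kind="stable")
    ranks = np.empty_like(order)
    np.put_along_axis(ranks, order, np.arange(1, vals.shape[1] + 1)[None, :], axis=1)
    ranks_df = pd.DataFrame(ranks, index=beta.index, columns=cols_sorted)[beta.columns]
    n = beta.shape[1]
    row_sum = beta.to_numpy().sum(axis=1, keepdims=True)
    loo = beta.to_numpy() - (row_sum - beta.to_numpy()) / (n - 1)
    loo_df = pd.DataFrame(loo, index=beta.index, columns=beta.columns)
    return RankedCpGs(beta=beta, ranks=ranks_df, loo_delta=loo_df)


def tail_k(n: int, tail_frac: float = 0.05) -> int:
    """Number of ranks per 5% tail: floor(tail_frac * n)."""
    return int(math.floor(tail_frac * n))


def extreme_cells(ranked: RankedCpGs, tail_frac: float = 0.05,
                  delta_min: float = 0.05, k: Optional[int] = None) -> pd.DataFrame:
    """Boolean (probe, sample) matrix of extreme methylation cells.

    ``k`` overrides the tail width; small cohorts use ``k=1`` (only the
    single lowest and highest rank count as extreme).
    """
    if k is None:
        k = tail_k(ranked.n, tail_frac)
    if k < 1:
        raise ValueError(f"cohort of {ranked.n} samples gives an empty {tail_frac:.0%} tail")
    r = ranked.ranks.to_numpy()
    in_tail = (r <= k) | (r >= ranked.n - k + 1)
    big_delta = np.abs(ranked.loo_delta.to_numpy()) >= delta_min
    return pd.DataFrame(in_tail & big_delta, index=ranked.beta.index,
                        columns=ranked.beta.columns)


# ---------------------------------------------------------------------------
# pair windows
# ---------------------------------------------------------------------------

def probe_distances(pairs: Sequence[SnvTfbsPair], manifest: pd.DataFrame
                    ) -> dict[str, tuple[list[str], np.ndarray]]:
    """Distance (bp) from each probe CpG to each pair's merged interval.

    Returns ``pair_id -> (probe_ids, distances)`` for all probes on the
    pair's chromosome within the largest supported window (100 kb); a CpG
    inside the interval has distance 0.
    """
    out: dict[str, tuple[list[str], np.ndarray]] = {}
    by_chrom = {c: g.sort_values("cpg_pos") for c, g in manifest.groupby("chrom")}
    max_span = DEFAULT_BIN_EDGES_BP[-1]
    for pair in pairs:
        g = by_chrom.get(pair.chrom)
        if g is None:
            out[pair.pair_id] = ([], np.empty(0, dtype=int))
            continue
        pos = g["cpg_pos"].to_numpy()
        pos0 = pos - 1
        lo = np.searchsorted(pos0, pair.start - max_span)
        hi = np.searchsorted(pos0, pair.end + max_span, side="right")
        sel = slice(lo, hi)
        p0 = pos0[sel]
        d = np.where(p0 < pair.start, pair.start - p0,
                     np.where(p0 >= pair.end, p0 - pair.end + 1, 0))
        out[pair.pair_id] = (list(g.index[sel]), d.astype(int))
    return out


def assign_probes_to_pairs(pairs: Sequence[SnvTfbsPair], manifest: pd.DataFrame,
                           flank_bp: int = 1000) -> dict[str, list[str]]:
    """Probes whose CpG lies within each pair's merged interval +/- flank."""
    dists = probe_distances(pairs, manifest)
    return {pid: [p for p, d in zip(probes, dd) if d <= flank_bp]
            for pid, (probes, dd) in dists.items()}


# ---------------------------------------------------------------------------
# outlier calls
# ---------------------------------------------------------------------------

def call_outliers(ranked: RankedCpGs, pairs: Sequence[SnvTfbsPair],
                  pair_probes: dict[str, list[str]], tail_frac: float = 0.05,
                  delta_min: float = 0.05, k: Optional[int] = None
                  ) -> list[OutlierCall]:
    """Carrier-level outlier calls within each pair's probe window.

    A call requires the carrier's rank in a tail (``k`` ranks per side) and
    an absolute beta difference >= ``delta_min`` against the mean of the
    variant's non-carriers (with two carriers, both are excluded from the
    control mean).
    """
    n = ranked.n
    if k is None:
        k = tail_k(n, tail_frac)
    if k < 1:
        raise ValueError(f"cohort of {n} samples gives an empty {tail_frac:.0%} tail")
    calls: list[OutlierCall] = []
    col_index = {s: i for i, s in enumerate(ranked.samples)}
    beta_vals = ranked.beta.to_numpy()
    rank_vals = ranked.ranks.to_numpy()
    row_of = {p: i for i, p in enumerate(ranked.beta.index)}
    row_sums = beta_vals.sum(axis=1)
    for pair in pairs:
        probes = pair_probes.get(pair.pair_id, [])
        if not probes:
            continue
        carriers = sorted(pair.variant.carriers)
        c_idx = [col_index[s] for s in carriers]
        rows = np.array([row_of[p] for p in probes])
        carrier_beta = beta_vals[np.ix_(rows, c_idx)]
        ctrl_mean = (row_sums[rows] - carrier_beta.sum(axis=1)) / (n - len(c_idx))
        for ci, carrier in enumerate(carriers):
            dbeta = carrier_beta[:, ci] - ctrl_mean
            rk = rank_vals[rows, c_idx[ci]]
            hit = ((rk <= k) | (rk >= n - k + 1)) & (np.abs(dbeta) >= delta_min)
            for j in np.flatnonzero(hit):
                calls.append(OutlierCall(probes[j], pair.pair_id, carrier,
                                         int(rk[j]), float(dbeta[j]),
                                         "gain" if dbeta[j] > 0 else "loss"))
    return calls


def direction_enrichment(calls: Sequence[OutlierCall]) -> float:
    """Fold enrichment of methylation gains over losses among outlier calls."""
    gains = sum(1 for c in calls if c.direction == "gain")
    losses = len(calls) - gains
    if losses == 0:
        if gains == 0:
            raise ValueError("no outlier calls")
        log.warning("direction_enrichment: no loss calls; fold is infinite")
        return float("inf")
    return gains / losses


def pair_association(calls: Sequence[OutlierCall],
                     pair_probes: dict[str, list[str]],
                     min_frac: float = 1 / 3) -> dict[str, bool]:
    """Flag pairs where >= ``min_frac`` of the window CpGs are outliers.

    Pairs with an empty window are dropped from the result rather than
    marked False.
    """
    outlier_probes: dict[str, set[str]] = {}
    for c in calls:
        outlier_probes.setdefault(c.pair_id, set()).add(c.probe_id)
    assoc = {}
    for pid, probes in pair_probes.items():
        if not probes:
            continue
        frac = len(outlier_probes.get(pid, ())) / len(probes)
        assoc[pid] = bool(frac >= min_frac - 1e-12)
    return assoc


# ---------------------------------------------------------------------------
# per-TF permutation enrichment
# ---------------------------------------------------------------------------

@dataclass
class PairObs:
    """Precomputed per-pair observation unit for the permutation test.

    ``e_counts[s]`` is the number of extreme cells sample ``s`` contributes
    over the pair's ``m`` window probes; carrier cells and non-carrier
    cells partition the ``m * n`` observation cells.
    """

    pair: SnvTfbsPair
    m: int
    e_counts: np.ndarray      # (n,) int
    carrier_idx: np.ndarray   # (c,) int

    @property
    def n(self) -> int:
        return len(self.e_counts)

    @property
    def c(self) -> int:
        return len(self.carrier_idx)


def build_tf_observations(extreme: pd.DataFrame, pairs: Sequence[SnvTfbsPair],
                          pair_probes: dict[str, list[str]]
                          ) -> dict[str, list[PairObs]]:
    """Group pairs by TF and reduce each to per-sample extreme-cell counts."""
    col_index = {s: i for i, s in enumerate(extreme.columns)}
    row_of = {p: i for i, p in enumerate(extreme.index)}
    evals = extreme.to_numpy()
    by_tf: dict[str, list[PairObs]] = {}
    for pair in pairs:
        probes = [p for p in pair_probes.get(pair.pair_id, []) if p in row_of]
        if not probes:
            continue
        rows = np.array([row_of[p] for p in probes])
        e = evals[rows].sum(axis=0).astype(np.int64)
        carrier_idx = np.array(sorted(col_index[s] for s in pair.variant.carriers))
        by_tf.setdefault(pair.tf_name, []).append(
            PairObs(pair=pair, m=len(probes), e_counts=e, carrier_idx=carrier_idx))
    return by_tf


def enrichment_ratio(co: float, ct: float, no: float, nt: float) -> float:
    """(carrier extreme fraction) / (non-carrier extreme fraction).

    Zero carrier outliers give 0; zero control outliers with a positive
    carrier count give +inf (ranking above every finite ratio).  A zero
    denominator (``ct`` or ``nt``) is the caller's error.
    """
    if ct == 0 or nt == 0:
        raise ValueError("enrichment ratio undefined: empty observation group")
    if co == 0:
        return 0.0
    if no == 0:
        return float("inf")
    return (co / ct) / (no / nt)


def observed_counts(obs: Sequence[PairObs]) -> tuple[int, int, int, int]:
    co = ct = no = nt = 0
    for o in obs:
        e_car = int(o.e_counts[o.carrier_idx].sum())
        tot = int(o.e_counts.sum())
        co += e_car
        no += tot - e_car
        ct += o.m * o.c
        nt += o.m * (o.n - o.c)
    return co, ct, no, nt


def _ratio_vector(co: np.ndarray, ct: float, no: np.ndarray, nt: float) -> np.ndarray:
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = (co / ct) / (no / nt)
    ratio = np.where(co == 0, 0.0, ratio)
    return np.where((no == 0) & (co > 0), np.inf, ratio)


def _permuted_carrier_counts(o: PairObs, n_perm: int,
                             rng: np.random.Generator) -> np.ndarray:
    """Extreme-cell counts of ``n_perm`` random carrier subsets of size c."""
    n, c = o.n, o.c
    e = o.e_counts
    if c == 1:
        return e[rng.integers(0, n, n_perm)]
    if c == 2:
        i = rng.integers(0, n, n_perm)
        j = rng.integers(0, n - 1, n_perm)
        j = j + (j >= i)
        return e[i] + e[j]
    # general case: partial shuffles in manageable chunks
    out = np.empty(n_perm, dtype=np.int64)
    chunk = max(1, 2_000_000 // n)
    for s in range(0, n_perm, chunk):
        b = min(chunk, n_perm - s)
        keys = rng.random((b, n))
        idx = np.argpartition(keys, c - 1, axis=1)[:, :c]
        out[s:s + b] = e[idx].sum(axis=1)
    return out


def permutation_test_tf(tf_name: str, obs: Sequence[PairObs], n_perm: int = 10_000,
                        seed: int | np.random.SeedSequence | None = None,
                        n_tfs_tested: int = 133, method: str = "montecarlo",
                        bin_label: str = "local",
                        scheme: str = "per_pair") -> PermutationResult:
    """Permutation enrichment test for one TF.

    Each permutation reassigns carrier labels and recomputes the pooled
    enrichment ratio; the p-value is the fraction of permutations with a
    ratio at least the observed one.  ``scheme="per_pair"`` (default)
    resamples every pair's carrier set independently, preserving per-pair
    carrier counts; ``scheme="whole_sample"`` applies one random
    relabelling of the samples to all pairs jointly, preserving the
    carrier-sharing structure across pairs.  ``method="exact"`` enumerates
    all per-pair carrier assignments (the product of per-pair subsets must
    stay below a million) and reports the exact fraction; the Monte Carlo
    path uses the add-one estimator ``(1 + hits) / (1 + n_perm)``.
    """
    co, ct, no, nt = observed_counts(obs)
    obs_ratio = enrichment_ratio(co, ct, no, nt)
    n_cpg = sum(o.m for o in obs)

    if method == "exact":
        choices = []
        total = 1
        for o in obs:
            combos = list(itertools.combinations(range(o.n), o.c))
            total *= len(combos)
            if total > 1_000_000:
                raise ValueError("exact enumeration infeasible for this cohort")
            choices.append([int(o.e_counts[list(cmb)].sum()) for cmb in combos])
        hits = 0
        for assignment in itertools.product(*choices):
            co_p = sum(assignment)
            no_p = sum(int(o.e_counts.sum()) for o in obs) - co_p
            if _ratio_vector(np.array([co_p]), ct, np.array([no_p]), nt)[0] >= obs_ratio:
                hits += 1
        p_raw = hits / total
    else:
        if seed is None:
            raise ValueError("a seed is required for the Monte Carlo permutation test")
        rng = np.random.default_rng(seed)
        tot_extreme = sum(int(o.e_counts.sum()) for o in obs)
        co_perm = np.zeros(n_perm, dtype=np.int64)
        if scheme == "per_pair":
            for o in obs:
                co_perm += _permuted_carrier_counts(o, n_perm, rng)
        elif scheme == "whole_sample":
            n = obs[0].n
            chunk = max(1, 2_000_000 // n)
            for s in range(0, n_perm, chunk):
                b = min(chunk, n_perm - s)
                perm = np.argsort(rng.random((b, n)), axis=1)
                for o in obs:
                    co_perm[s:s + b] += o.e_counts[
                        perm[:, o.carrier_idx]].sum(axis=1)
        else:
            raise ValueError(f"unknown permutation scheme {scheme!r}")
        no_perm = tot_extreme - co_perm
        ratios = _ratio_vector(co_perm.astype(float), ct, no_perm.astype(float), nt)
        hits = int((ratios >= obs_ratio).sum())
        p_raw = (1 + hits) / (1 + n_perm)

    return PermutationResult(tf_name=tf_name, bin_label=bin_label,
                             observed_ratio=obs_ratio, p_raw=p_raw,
                             p_bonferroni=min(1.0, n_tfs_tested * p_raw),
                             n_pairs=len(obs), n_cpg_obs=n_cpg)


def run_tf_permutations(tf_obs: dict[str, list[PairObs]], n_perm: int = 10_000,
                        seed: int = 0, bin_label: str = "local",
                        n_tfs_tested: Optional[int] = None
                        ) -> list[PermutationResult]:
    """Permutation tests for every TF, with per-TF child seeds.

    Child seeds are spawned in sorted TF order, so results do not depend on
    dict ordering.  TFs whose observation groups are empty on either side
    are skipped with a log entry.
    """
    tfs = sorted(tf_obs)
    if n_tfs_tested is None:
        n_tfs_tested = len(tfs)
    seeds = np.random.SeedSequence(seed).spawn(len(tfs))
    results = []
    for tf, child in zip(tfs, seeds):
        obs = tf_obs[tf]
        co, ct, no, nt = observed_counts(obs)
        if ct == 0 or nt == 0:
            log.info("run_tf_permutations: skipping %s (empty observation group)", tf)
            continue
        results.append(permutation_test_tf(tf, obs, n_perm=n_perm, seed=child,
                                           n_tfs_tested=n_tfs_tested,
                                           bin_label=bin_label))
    return results


# ---------------------------------------------------------------------------
# distance-binned analysis
# ---------------------------------------------------------------------------

def bin_label(lo: int, hi: int) -> str:
    return f"{lo // 1000}-{hi // 1000}kb"


def distance_bin_analysis(extreme: pd.DataFrame, pairs: Sequence[SnvTfbsPair],
                          manifest: pd.DataFrame,
                          bin_edges_bp: Sequence[int] = DEFAULT_BIN_EDGES_BP,
                          n_perm: int = 10_000, seed: int = 0,
                          n_tfs_tested: Optional[int] = None
                          ) -> list[PermutationResult]:
    """Per-(TF, distance-bin) permutation tests for CpGs 1-100 kb away.

    CpGs within the local window (<= the first bin edge, default 1 kb) are
    excluded; the remaining CpGs are binned by their distance to the merged
    motif interval and the local permutation machinery is applied per bin.
    """
    edges = list(bin_edges_bp)
    dists = probe_distances(pairs, manifest)
    col_index = {s: i for i, s in enumerate(extreme.columns)}
    row_of = {p: i for i, p in enumerate(extreme.index)}
    evals = extreme.to_numpy()
    results: list[PermutationResult] = []
    tfs_in_run = sorted({p.tf_name for p in pairs})
    if n_tfs_tested is None:
        n_tfs_tested = len(tfs_in_run)
    for bi in range(len(edges) - 1):
        lo, hi = edges[bi], edges[bi + 1]
        by_tf: dict[str, list[PairObs]] = {}
        for pair in pairs:
            probes, dd = dists[pair.pair_id]
            keep = [p for p, d in zip(probes, dd)
                    if lo < d <= hi and p in row_of]
            if not keep:
                continue
            rows = np.array([row_of[p] for p in keep])
            e = evals[rows].sum(axis=0).astype(np.int64)
            carrier_idx = np.array(sorted(col_index[s]
                                          for s in pair.variant.carriers))
            by_tf.setdefault(pair.tf_name, []).append(
                PairObs(pair=pair, m=len(keep), e_counts=e, carrier_idx=carrier_idx))
        if not by_tf:
            continue
        results.extend(run_tf_permutations(
            by_tf, n_perm=n_perm, seed=seed + bi + 1,
            bin_label=bin_label(lo, hi), n_tfs_tested=n_tfs_tested))
    return results


# ---------------------------------------------------------------------------
# DMR detection
# ---------------------------------------------------------------------------

def detect_dmrs(beta: pd.DataFrame, manifest: pd.DataFrame, window_bp: int = 1000,
                min_probes: int = 3, pct: float = 0.95, delta: float = 0.1
                ) -> list[DMR]:
    """Sliding-window scan for per-sample differentially methylated regions.

    A probe qualifies as hypermethylated for a sample when its beta exceeds
    the cohort's ``pct`` percentile for that probe (nearest-rank over all n
    samples, the tested sample included) and is at least ``delta`` above
    the cohort mean; the hypomethylated rule mirrors it.  A DMR is a
    maximal run of >= ``min_probes`` same-direction qualifying probes whose
    first and last CpG are within ``window_bp``.  Output is invariant to
    probe input order.
    """
    n = beta.shape[1]
    order = manifest.sort_values(["chrom", "cpg_pos"]).index
    vals = beta.loc[order].to_numpy(dtype=float)
    pos = manifest.loc[order, "cpg_pos"].to_numpy()
    chrom = manifest.loc[order, "chrom"].to_numpy()
    sorted_vals = np.sort(vals, axis=1)
    hi_idx = int(np.ceil(pct * n)) - 1
    lo_idx = int(np.ceil((1 - pct) * n)) - 1
    thr_hi = sorted_vals[:, hi_idx][:, None]
    thr_lo = sorted_vals[:, lo_idx][:, None]
    mean = vals.mean(axis=1, keepdims=True)
    hyper = (vals > thr_hi) & (vals >= mean + delta)
    hypo = (vals < thr_lo) & (vals <= mean - delta)

    dmrs: list[DMR] = []
    samples = list(beta.columns)
    for chrom_name in np.unique(chrom):
        in_chrom = chrom == chrom_name
        cpos = pos[in_chrom]
        for mask, direction in ((hyper[in_chrom], "hyper"), (hypo[in_chrom], "hypo")):
            for si, sample in enumerate(samples):
                q = cpos[mask[:, si]]
                if len(q) < min_probes:
                    continue
                hi_ptr = np.searchsorted(q, q + window_bp, side="right") - 1
                prev = -1
                for j in range(len(q)):
                    if hi_ptr[j] - j + 1 >= min_probes and hi_ptr[j] > prev:
                        dmrs.append(DMR(sample, str(chrom_name), int(q[j]),
                                        int(q[hi_ptr[j]]),
                                        int(hi_ptr[j] - j + 1), direction))
                    prev = max(prev, hi_ptr[j])
    dmrs.sort(key=lambda d: (d.chrom, d.start, d.end, d.sample, d.direction))
    return dmrs


def dmr_tfbs_intersection(dmrs: Sequence[DMR], pairs: Sequence[SnvTfbsPair],
                          pair_probes: dict[str, list[str]],
                          calls: Sequence[OutlierCall], flank_bp: int = 1000,
                          min_window_probes: int = 3
                          ) -> tuple[dict[str, list[DMR]], list[str]]:
    """Link DMRs to eligible SNV-TFBS pairs.

    Eligible pairs have >= ``min_window_probes`` CpGs in their window and
    at least one outlier call; a link requires a DMR in a carrier sample
    overlapping the pair's motif +/- ``flank_bp``.  Returns the links and
    the eligible pair ids (the denominator of the linked fraction).
    """
    pairs_with_calls = {c.pair_id for c in calls}
    eligible = [p for p in pairs
                if len(pair_probes.get(p.pair_id, [])) >= min_window_probes
                and p.pair_id in pairs_with_calls]
    by_sample_chrom: dict[tuple[str, str], list[DMR]] = {}
    for d in dmrs:
        by_sample_chrom.setdefault((d.sample, d.chrom), []).append(d)
    links: dict[str, list[DMR]] = {}
    for p in eligible:
        lo, hi = p.start - flank_bp, p.end + flank_bp
        for carrier in sorted(p.variant.carriers):
            for d in by_sample_chrom.get((carrier, p.chrom), []):
                if d.start - 1 < hi and d.end > lo:  # 1-based DMR vs half-open window
                    links.setdefault(p.pair_id, []).append(d)
    return links, [p.pair_id for p in eligible]


# ---------------------------------------------------------------------------
# flank contrast and region overlap
# ---------------------------------------------------------------------------

def chrom_enrichments(obs: Sequence[PairObs]) -> dict[str, float]:
    """Pooled enrichment ratio per chromosome over a set of pair windows."""
    by_chrom: dict[str, list[PairObs]] = {}
    for o in obs:
        by_chrom.setdefault(o.pair.chrom, []).append(o)
    out = {}
    for c, group in sorted(by_chrom.items()):
        co, ct, no, nt = observed_counts(group)
        if ct == 0 or nt == 0:
            continue
        out[c] = enrichment_ratio(co, ct, no, nt)
    return out


def flank_comparison(tfbs_by_chrom: dict[str, float],
                     flank_by_chrom: dict[str, float]
                     ) -> tuple[float, float | None, float | None, int]:
    """Chromosome-matched contrast of TFBS vs flanking-SNV enrichment.

    Returns ``(fold, t, p, n_chroms)`` where ``fold`` is the ratio of mean
    enrichments and ``p`` comes from a two-sided paired t-test over
    chromosomes with both quantities defined and finite.  Fewer than three
    matched chromosomes leave the test undefined.
    """
    common = [c for c in sorted(tfbs_by_chrom)
              if c in flank_by_chrom
              and np.isfinite(tfbs_by_chrom[c]) and np.isfinite(flank_by_chrom[c])]
    if not common:
        raise ValueError("no chromosomes with both enrichments defined")
    x = np.array([tfbs_by_chrom[c] for c in common])
    y = np.array([flank_by_chrom[c] for c in common])
    fold = float(x.mean() / y.mean()) if y.mean() != 0 else float("inf")
    if len(common) < 3:
        return fold, None, None, len(common)
    t, p = paired_t_test(x, y)
    return fold, t, p, len(common)


def region_overlap_enrichment(outlier_probes: Sequence[str],
                              nonoutlier_probes: Sequence[str],
                              regions: Sequence[tuple[str, int, int]],
                              manifest: pd.DataFrame
                              ) -> tuple[float | None, float, list[list[int]]]:
    """Fisher-exact enrichment of outlier probes inside a region list.

    Builds the 2x2 (outlier x in-region) table over the given probes; a CpG
    is in-region when it falls inside any interval (BED half-open).
    Returns ``(odds_ratio, p, table)``.
    """
    by_chrom: dict[str, list[tuple[int, int]]] = {}
    for c, s, e in regions:
        by_chrom.setdefault(c, []).append((s, e))

    def in_region(pid: str) -> bool:
        row = manifest.loc[pid]
        pos = row["cpg_pos"]
        return any(s < pos <= e for s, e in by_chrom.get(row["chrom"], ()))

    a = sum(in_region(p) for p in outlier_probes)
    b = len(outlier_probes) - a
    c_ = sum(in_region(p) for p in nonoutlier_probes)
    d = len(nonoutlier_probes) - c_
    table = [[a, b], [c_, d]]
    odds, p = fisher_exact_2x2(table)
    return odds, p, table
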