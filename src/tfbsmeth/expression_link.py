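"""Integration of promoter methylation outliers with expression outliers.

Designed for small tissue cohorts (~20 samples): extreme methylation is
restricted to the single top or bottom rank of the cohort distribution
(plus the usual |delta-beta| >= 0.05 requirement), SNV-TFBS pairs are
mapped to the closest gene and kept only when the variant lies within the
promoter (TSS +/- 2 kb), and the enrichment of expression outliers (|z| > 2)
among pairs with outlier promoter methylation is tested with a two-tailed
Fisher exact test.
"""

from __future__ import annotations

import logging
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .models import GeneModel, OutlierCall, SnvTfbsPair
from .outlier_core import RankedCpGs, call_outliers
from .stats import fisher_exact_2x2

log = logging.getLogger(__name__)


def zscore_expression(expr: pd.DataFrame, rpkm_means: pd.Series,
                      min_rpkm: float = 1.0) -> pd.DataFrame:
    """Per-gene expression Z-scores across samples.

    Genes with mean RPKM below ``min_rpkm`` are not considered expressed
    and are dropped, as are zero-variance genes (logged).  Z-scores use the
    sample standard deviation (ddof=1), so each retained gene has mean 0
    and standard deviation 1 across samples.
    """
    if expr.shape[1] < 4:
        raise ValueError("expression z-scores need >= 4 samples")
    expressed = rpkm_means.reindex(expr.index).fillna(0.0) >= min_rpkm
    kept = expr.loc[expressed[expressed].index]
    sd = kept.std(axis=1, ddof=1)
    flat = sd == 0
    if flat.any():
        log.info("zscore_expression: dropped %d zero-variance genes", int(flat.sum()))
        kept = kept.loc[~flat]
        sd = sd[~flat]
    return kept.sub(kept.mean(axis=1), axis=0).div(sd, axis=0)


def expression_outliers(z: pd.DataFrame, z_max: float = 2.0) -> pd.DataFrame:
    """Boolean outlier matrix: |z| strictly greater than ``z_max``."""
    return z.abs() > z_max


def small_cohort_outliers(ranked: RankedCpGs, pairs: Sequence[SnvTfbsPair],
                          pair_probes: dict[str, list[str]],
                          delta_min: float = 0.05) -> list[OutlierCall]:
    """Outlier calls for a small cohort: carrier rank must be 1 or n."""
    if ranked.n < 4:
        raise ValueError("small-cohort outlier calling needs >= 4 samples")
    return call_outliers(ranked, pairs, pair_probes, delta_min=delta_min, k=1)


def promoter_pairs(pairs: Sequence[SnvTfbsPair], genes: Sequence[GeneModel],
                   promoter_bp: int = 2000, distance: str = "midpoint"
                   ) -> dict[str, str]:
    """Assign each pair its closest gene; keep promoter-resident variants.

    The closest gene minimises |merged-interval midpoint - TSS| (default)
    or, with ``distance="interval"``, the gap between the merged interval
    and the TSS (zero when the TSS falls inside it), ties broken by gene
    id.  The pair is retained only when the variant position lies in
    ``[tss - promoter_bp, tss + promoter_bp]`` inclusive.
    """
    if distance not in ("midpoint", "interval"):
        raise ValueError(f"unknown distance mode {distance!r}")
    by_chrom: dict[str, list[GeneModel]] = {}
    for g in genes:
        by_chrom.setdefault(g.chrom, []).append(g)
    assigned: dict[str, str] = {}
    for pair in pairs:
        candidates = by_chrom.get(pair.chrom)
        if not candidates:
            continue
        if distance == "midpoint":
            mid = (pair.start + pair.end) // 2
            key = lambda g: (abs(g.tss - mid), g.gene_id)  # noqa: E731
        else:
            key = lambda g: (max(pair.start - (g.tss - 1), (g.tss - 1) - (pair.end - 1), 0),  # noqa: E731
                             g.gene_id)
        best = min(candidates, key=key)
        if abs(pair.variant.pos - best.tss) <= promoter_bp:
            assigned[pair.pair_id] = best.gene_id
    return assigned


def expression_outlier_enrichment(pair_assoc: dict[str, bool],
                                  pair_gene: dict[str, str],
                                  z: pd.DataFrame,
                                  pair_carriers: dict[str, Sequence[str]],
                                  z_max: float = 2.0,
                                  per_gene: bool = False
                                  ) -> tuple[Optional[float], float, list[list[int]]]:
    """Fisher enrichment of expression outliers among methylation-outlier pairs.

    Each promoter pair contributes one observation: whether its promoter
    methylation is an outlier (the association flag) crossed with whether a
    carrier's expression of the assigned gene is an outlier (|z| > 2 for
    that individual).  With ``per_gene=True`` pairs hitting the same gene
    collapse to one observation (methylation-outlier if any pair is).
    Returns ``(fold, p, table)`` with
    ``fold = (outlier-expression fraction | meth outlier) /
    (outlier-expression fraction | no meth outlier)``.
    """
    units: dict[str, tuple[bool, bool]] = {}
    for pid, gene in sorted(pair_gene.items()):
        if pid not in pair_assoc or gene not in z.index:
            continue
        carriers = [s for s in pair_carriers.get(pid, []) if s in z.columns]
        if not carriers:
            continue
        expr_out = bool((z.loc[gene, carriers].abs() > z_max).any())
        key = gene if per_gene else pid
        prev = units.get(key, (False, False))
        units[key] = (prev[0] or pair_assoc[pid], prev[1] or expr_out)
    a = b = c = d = 0
    for meth_out, expr_out in units.values():
        if meth_out:
            a += expr_out
            b += not expr_out
        else:
            c += expr_out
            d += not expr_out
    table = [[a, b], [c, d]]
    _, p = fisher_exact_2x2(table)
    if a + b == 0 or c + d == 0 or c == 0:
        fold = None if (a + b == 0 or c + d == 0) else (
            float("inf") if a > 0 else None)
        return fold, p, table
    fold = (a / (a + b)) / (c / (c + d))
    return float(fold), p, table


def residualize(expr: pd.DataFrame, covariates: pd.DataFrame) -> pd.DataFrame:
    """Plain least-squares residualization of expression on sample covariates.

    Provided for cohorts where expression has not already been corrected;
    covariates are one row per sample (numeric, with an intercept added).
    """
    X = np.column_stack([np.ones(len(covariates)),
                         covariates.loc[expr.columns].to_numpy(dtype=float)])
    Y = expr.to_numpy(dtype=float).T  # samples x genes
    coef, *_ = np.linalg.lstsq(X, Y, rcond=None)
    resid = Y - X @ coef
    return pd.DataFrame(resid.T, index=expr.index, columns=expr.columns)
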