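"""Rare-variant filtering, SNV x TFBS intersection, and PWM disruption scoring.

The intersection step pairs each rare SNV with every TF whose motif it
falls inside; overlapping same-TF instances that share the variant are
merged into a single union interval, and a pair built from exactly one
instance is flagged ``isolated``.  Only isolated pairs can be scored for
PWM disruption (delta-PWM), since a merged interval has no unambiguous
motif frame.

Delta-PWM is the absolute difference between the PWM weights of the two
alleles at the variant's motif column.  By default the weight is the raw
base probability at that column, giving scores in [0, 1]; a log2-odds
variant (pseudocount 1e-3) is available via ``method="log2"``.
"""

from __future__ import annotations

import logging
from typing import Sequence

from intervaltree import IntervalTree

from .models import (
    COMPLEMENT,
    DeltaPWM,
    MotifSite,
    PWM,
    SnvTfbsPair,
    Variant,
    is_autosome,
    variant_overlaps,
)

import numpy as np

log = logging.getLogger(__name__)


def filter_rare_variants(variants: Sequence[Variant],
                         cohort_maf_max: float = 0.01,
                         external_maf_max: float = 0.01,
                         max_carriers: int = 2) -> list[Variant]:
    """Keep autosomal SNVs rare in the cohort and in every external database.

    A variant passes when its cohort allele frequency and each external
    frequency are at or below the thresholds and it is carried by at most
    ``max_carriers`` individuals.  Missing external frequencies count as 0
    (logged once per run).
    """
    kept = []
    n_missing_ext = 0
    for v in variants:
        if not is_autosome(v.chrom):
            continue
        if v.cohort_af > cohort_maf_max or len(v.carriers) > max_carriers:
            continue
        if not v.external_afs:
            n_missing_ext += 1
        if any(af > external_maf_max for af in v.external_afs.values()):
            continue
        kept.append(v)
    if n_missing_ext:
        log.info("filter_rare_variants: %d variants had no external AFs "
                 "(treated as 0)", n_missing_ext)
    return kept


def _motif_trees(motifs: Sequence[MotifSite]) -> dict[str, IntervalTree]:
    trees: dict[str, IntervalTree] = {}
    for m in motifs:
        trees.setdefault(m.chrom, IntervalTree()).addi(m.start, m.end, m)
    return trees


def intersect_and_merge(variants: Sequence[Variant],
                        motifs: Sequence[MotifSite]) -> list[SnvTfbsPair]:
    """Pair each variant with the TFs whose motifs it disrupts.

    One pair per (variant, TF); same-TF instances sharing the variant are
    merged to their union interval (they necessarily overlap at the variant
    base) and marked non-isolated.  Exact duplicate instances (identical
    interval, TF and strand) count as one.
    """
    trees = _motif_trees(motifs)
    pairs: list[SnvTfbsPair] = []
    for v in variants:
        tree = trees.get(v.chrom)
        if tree is None:
            continue
        hits = [iv.data for iv in tree.at(v.pos - 1)]  # 1-based pos -> 0-based base
        by_tf: dict[str, list[MotifSite]] = {}
        for m in hits:
            by_tf.setdefault(m.tf_name, []).append(m)
        for tf in sorted(by_tf):
            instances = by_tf[tf]
            start = min(m.start for m in instances)
            end = max(m.end for m in instances)
            isolated = len(instances) == 1
            strand = instances[0].strand if isolated else None
            pairs.append(SnvTfbsPair(v, tf, v.chrom, start, end, isolated, strand))
    return pairs


def find_flank_snvs(variants: Sequence[Variant], motifs: Sequence[MotifSite],
                    flank_bp: int = 1000) -> list[Variant]:
    """Variants near a motif edge but inside no motif of any TF."""
    trees = _motif_trees(motifs)
    flank = []
    for v in variants:
        tree = trees.get(v.chrom)
        if tree is None:
            continue
        pos0 = v.pos - 1
        if tree.at(pos0):
            continue
        if tree.overlap(pos0 - flank_bp, pos0 + flank_bp + 1):
            flank.append(v)
    return flank


def delta_pwm(pair: SnvTfbsPair, pwms: dict[str, PWM],
              method: str = "prob", pseudocount: float = 1e-3) -> DeltaPWM:
    """Score the PWM disruption of an isolated SNV-TFBS pair.

    The motif-frame offset of the variant is ``pos - 1 - start`` on the
    plus strand and ``end - pos`` on the minus strand, where alleles are
    complemented before the PWM lookup.  The computation is
    strand-involutive: scoring a motif and its reverse complement yields
    the same delta.
    """
    if not pair.isolated:
        raise ValueError(f"{pair.pair_id}: delta-PWM undefined for merged motifs")
    pwm = pwms.get(pair.tf_name)
    if pwm is None:
        raise KeyError(f"no PWM for {pair.tf_name}")
    if pair.end - pair.start != pwm.width:
        raise ValueError(f"{pair.pair_id}: motif width {pair.end - pair.start} "
                         f"!= PWM width {pwm.width}")
    v = pair.variant
    if not variant_overlaps(v.pos, pair.start, pair.end):
        raise ValueError(f"{pair.pair_id}: variant outside motif interval")
    if pair.strand == "+":
        offset = v.pos - 1 - pair.start
        ref, alt = v.ref, v.alt
    else:
        offset = pair.end - v.pos
        ref, alt = COMPLEMENT[v.ref], COMPLEMENT[v.alt]
    w_ref, w_alt = pwm.prob(ref, offset), pwm.prob(alt, offset)
    if method == "prob":
        delta = abs(w_ref - w_alt)
    elif method == "log2":
        delta = abs(float(np.log2(w_ref + pseudocount) - np.log2(w_alt + pseudocount)))
    else:
        raise ValueError(f"unknown delta-PWM method {method!r}")
    return DeltaPWM(pair.pair_id, offset, w_ref, w_alt, delta)
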