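"""Rare-variant filters, motif intersection/merging, delta-PWM scoring."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from tfbsmeth.models import MotifSite, PWM, SnvTfbsPair, Variant, variant_overlaps
from tfbsmeth.variant_motif import (
    delta_pwm,
    filter_rare_variants,
    find_flank_snvs,
    intersect_and_merge,
)


def V(chrom="chr1", pos=100, carriers=("S1",), cohort_af=0.002, external=None):
    return Variant(chrom, pos, "A", "T", frozenset(carriers), cohort_af,
                   external if external is not None else {"gnomad": 0.001})


@pytest.mark.parametrize("variant,kept", [
    (V(), True),
    (V(carriers=("S1", "S2", "S3")), False),          # carried by >2 individuals
    (V(external={"gnomad": 0.02}), False),            # common in gnomAD
    (V(cohort_af=0.02), False),                       # common in the cohort
    (V(chrom="chrX"), False),                         # autosomes only
    (V(external={}), True),                           # missing external AF -> 0
])
def test_rare_variant_filter(variant, kept):
    assert (filter_rare_variants([variant]) == [variant]) == kept


def test_merge_same_tf_overlapping_instances():
    motifs = [MotifSite("chr1", 90, 110, "CTCF", "+"),
              MotifSite("chr1", 95, 115, "CTCF", "+")]
    (pair,) = intersect_and_merge([V(pos=100)], motifs)
    assert (pair.start, pair.end) == (90, 115)
    assert not pair.isolated and pair.strand is None


def test_distinct_tfs_give_distinct_pairs():
    motifs = [MotifSite("chr1", 90, 110, "CTCF", "+"),
              MotifSite("chr1", 95, 112, "SP1", "-")]
    pairs = intersect_and_merge([V(pos=100)], motifs)
    assert sorted(p.tf_name for p in pairs) == ["CTCF", "SP1"]
    assert all(p.isolated for p in pairs)


def test_variant_outside_all_motifs_yields_no_pair():
    assert intersect_and_merge([V(pos=500)], [MotifSite("chr1", 90, 110, "CTCF")]) == []


def test_boundary_bases():
    """BED half-open: the base at 1-based `end` is the last motif base;
    1-based `start` is the base before the motif."""
    motif = MotifSite("chr1", 90, 110, "CTCF", "+")
    assert intersect_and_merge([V(pos=110)], [motif])  # last base overlaps
    assert not intersect_and_merge([V(pos=90)], [motif])
    assert intersect_and_merge([V(pos=91)], [motif])   # first base


@given(st.lists(st.tuples(st.integers(0, 60), st.integers(1, 8),
                          st.sampled_from(["TF1", "TF2"])), max_size=15),
       st.lists(st.integers(1, 70), min_size=1, max_size=10))
@settings(max_examples=100, deadline=None)
def test_merge_agrees_with_brute_force(motif_specs, positions):
    """intersect_and_merge matches an O(V x M) scan plus union-by-TF."""
    # exact duplicates count once, matching the implementation's semantics
    motifs = list({MotifSite("chr1", s, s + w, tf) for s, w, tf in motif_specs})
    variants = [Variant("chr1", pos, "A", "C", frozenset({"S1"}))
                for pos in sorted(set(positions))]
    pairs = intersect_and_merge(variants, motifs)
    got = {(p.variant.pos, p.tf_name): (p.start, p.end, p.isolated) for p in pairs}
    expected = {}
    for v in variants:
        for tf in ("TF1", "TF2"):
            hits = [m for m in motifs
                    if m.tf_name == tf and variant_overlaps(v.pos, m.start, m.end)]
            if hits:
                expected[(v.pos, tf)] = (min(m.start for m in hits),
                                         max(m.end for m in hits), len(hits) == 1)
    assert got == expected


def test_flank_snv_rules():
    motifs = [MotifSite("chr1", 1000, 1015, "CTCF", "+")]
    near = V(pos=950)        # 50 bp upstream
    inside = V(pos=1010)
    far = V(pos=2600)        # ~1.6 kb downstream of the motif end
    assert find_flank_snvs([near, inside, far], motifs) == [near]


def uniform_pwm(width=10):
    return PWM("U", np.full((4, width), 0.25))


def test_delta_pwm_uniform_matrix_is_zero():
    pair = SnvTfbsPair(V(pos=105), "U", "chr1", 100, 110, True, "+")
    assert delta_pwm(pair, {"U": uniform_pwm()}).delta == 0.0


def test_delta_pwm_hand_arithmetic():
    """Column with p(A)=0.97 and p(T)=0.01: an A->T substitution scores 0.96."""
    probs = np.full((4, 10), 0.25)
    probs[:, 5] = [0.97, 0.01, 0.01, 0.01]  # A,C,G,T
    pwm = PWM("X", probs)
    v = Variant("chr1", 106, "A", "T", frozenset({"S1"}))  # offset 5 on + strand
    pair = SnvTfbsPair(v, "X", "chr1", 100, 110, True, "+")
    d = delta_pwm(pair, {"X": pwm})
    assert d.motif_offset == 5
    assert d.delta == pytest.approx(0.96)


def test_delta_pwm_minus_strand_uses_complement():
    """On the minus strand the lookup happens at offset end - pos with
    complemented alleles, matching the plus-strand computation on the
    reverse-complement PWM."""
    rng = np.random.default_rng(4)
    for _ in range(20):
        width = int(rng.integers(8, 15))
        pwm = PWM("X", rng.dirichlet(np.ones(4), size=width).T)
        pos = 100 + int(rng.integers(1, width + 1))
        ref, alt = rng.choice(list("ACGT"), size=2, replace=False)
        v = Variant("chr1", pos, ref, alt, frozenset({"S1"}))
        minus = SnvTfbsPair(v, "X", "chr1", 100, 100 + width, True, "-")
        plus_rc = SnvTfbsPair(v, "X", "chr1", 100, 100 + width, True, "+")
        d_minus = delta_pwm(minus, {"X": pwm}).delta
        d_plus = delta_pwm(plus_rc, {"X": pwm.reverse_complement()}).delta
        assert d_minus == pytest.approx(d_plus, abs=1e-12)


def test_delta_pwm_refuses_merged_pairs_and_width_mismatch():
    merged = SnvTfbsPair(V(pos=105), "U", "chr1", 100, 112, False, None)
    with pytest.raises(ValueError, match="merged"):
        delta_pwm(merged, {"U": uniform_pwm()})
    wrong = SnvTfbsPair(V(pos=105), "U", "chr1", 100, 112, True, "+")
    with pytest.raises(ValueError, match="width"):
        delta_pwm(wrong, {"U": uniform_pwm(10)})


def test_log2_method_uses_pseudocount():
    probs = np.full((4, 10), 0.25)
    probs[:, 5] = [0.5, 0.5, 0.0, 0.0]
    pwm = PWM("X", probs)
    v = Variant("chr1", 106, "A", "G", frozenset({"S1"}))
    pair = SnvTfbsPair(v, "X", "chr1", 100, 110, True, "+")
    d = delta_pwm(pair, {"X": pwm}, method="log2", pseudocount=1e-3)
    assert d.delta == pytest.approx(abs(np.log2(0.501) - np.log2(1e-3)))


def test_pairs_satisfy_overlap_contract(small_cohort):
    rare = filter_rare_variants(small_cohort.variants)
    pairs = intersect_and_merge(rare, small_cohort.motifs)
    assert pairs
    for p in pairs:
        assert p.start < p.variant.pos <= p.end
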