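# Methods

## Model and procedure

`tfbsmeth` detects cis-regulatory effects of rare single-nucleotide
variants (SNVs) on DNA methylation without association mapping: with only
one or two carriers per variant, the evidence is that carriers occupy the
*extremes* of the cohort's per-CpG methylation distribution near the
mutated transcription-factor binding site (TFBS).

**Ranking and extreme cells.** For each CpG probe, β-values are ranked
ascending over the n samples; ties are broken by sample id so the ranking
is deterministic.  A (probe, sample) cell is *extreme* when the rank falls
in a tail of k = ⌊0.05·n⌋ ranks per side (k = 12 at n = 247; small
cohorts fall back to the single top/bottom rank) and the sample's β
differs from the mean of all other samples (leave-one-out Δβ) by ≥ 0.05.
The uniform leave-one-out definition makes carrier and non-carrier cells
commensurable and exchangeable under permutation.  Carrier-level *outlier
calls*, which feed the pair-association and direction summaries, instead
measure Δβ against the mean of the variant's non-carriers (with two
carriers, both are excluded from the control mean) — the quantity a
geneticist would report for the carrier.

**Pairs and windows.** Rare SNVs (cohort and every external database MAF
≤ 1%, ≤ 2 carriers, autosomal; a missing external frequency counts as 0)
are intersected with the motif catalogue.  One pair per (variant, TF);
same-TF instances sharing the variant merge to their union interval and
lose "isolated" status.  A pair's local window is its merged interval
± 1 kb; probes are assigned by the convention that a 1-based position p
overlaps a 0-based half-open interval [s, e) iff s < p ≤ e.

**Per-TF permutation test.** Observations pool over a TF's pair windows;
the enrichment ratio is the extreme-cell fraction among carrier cells over
that among non-carrier cells (0 if no carrier outliers, +∞ if only
carriers have outliers — permuted infinities count against significance).
Each permutation redraws every pair's carrier set independently and
uniformly at the same size, preserving per-pair carrier counts and the
pooled statistic; a whole-sample relabelling scheme (one permutation of
samples applied to all pairs, preserving carrier sharing) is available via
`scheme="whole_sample"`.  The p-value uses the add-one estimator
(1 + hits)/(1 + B) so it is never zero; an exact mode enumerates all
carrier assignments when the assignment space is small.  Bonferroni
correction multiplies by the number of TFs tested in the run.

**ΔPWM.** The disruption score of an isolated pair is the absolute
difference of the PWM probabilities of the two alleles at the variant's
motif column (offset pos−1−start on +, end−pos on −, with alleles
complemented on the minus strand).  The raw probability scale keeps scores
in [0,1]; a log2-odds variant with pseudocount 1e−3 is available.  Merged
pairs are refused — a union interval has no unambiguous motif frame.
Constraint analyses: per TF, the medians of ΔPWM among
association-positive and association-negative pairs form one matched
observation for a two-sided Wilcoxon signed-rank test across TFs; CpG
observations binned into eight equal-count bins of |Δβ| yield a Pearson
correlation between per-bin median ΔPWM and median |Δβ|.

**DMRs.** Per sample and direction, a probe qualifies when its β exceeds
the cohort's 95th percentile for that probe (nearest-rank over all n
samples, the tested sample included) and is ≥ 0.1 above the cohort mean
(mirrored for hypomethylation).  A DMR is a maximal run of ≥ 3
same-direction qualifying probes whose first and last CpG lie within 1 kb.
Runs are anchored at qualifying probes, so output is invariant to probe
input order; two overlapping maximal runs are reported separately rather
than merged, which keeps every call's span ≤ 1 kb.

**Distance bins.** CpGs 1–100 kb from the merged interval (local CpGs
excluded) are binned by distance — (1, 10], (10, 20] … (90, 100] kb; the
bin width is a package choice — and the local permutation machinery runs
per (TF, bin) with Bonferroni over TFs within each bin.

**Flank contrast.** SNVs within 1 kb of a motif edge but inside no motif
serve as matched controls; enrichment is pooled per chromosome for both
classes and compared by a two-sided paired t-test over chromosomes
(identical vectors give t = 0, p = 1; a constant non-zero difference is
reported as p → 0 with a zero-variance warning).

**Expression integration.** For small tissue cohorts, genes with mean
RPKM < 1 are dropped, per-gene Z-scores use the sample standard deviation
(ddof = 1), and |z| > 2 (strict) defines expression outliers.  Pairs map
to the closest gene by |interval midpoint − TSS| (TSS strand-aware; a
bedtools-style interval distance is available) and are kept when the
variant lies within TSS ± 2 kb inclusive.  The 2×2 table of
(promoter-methylation outlier) × (carrier expression outlier) over pairs
is tested two-tailed by direct hypergeometric enumeration; pairs sharing a
gene can optionally collapse to one per-gene observation.

## Probe quality control

Before any statistics: probes flagged for a common SNP in the last five
3'-bases or non-unique bisulfite mapping are removed, along with any user
blacklist; the probes most correlated (max |Pearson r| across the six
blood cell fractions) are removed up to ⌊0.05·P⌋ in a single quota cut
(ties by probe id; zero-variance probes score 0 and stay; a per-fraction
variant splits the quota six ways); probes whose body, interrogated CpG or
adjacent base carries one of the tested SNVs are removed.  Each filter is
evaluated on the full probe set so the surviving set is independent of
filter order.  A single 5% quota (rather than 5% per fraction) matches the
observed size of such exclusions on EPIC-scale data relative to the
processed probe count.

## Synthetic cohorts

The generator emulates the data structure the analysis assumes, not raw
arrays or reads:

* **β baseline** — per-probe mean from a 50/50 mixture of Beta(2,18) and
  Beta(18,2) (EPIC-like bimodality, poles ≈ 0.1 / 0.9), so the ± 0.05 Δβ
  criterion is meaningful at both poles; per-cell noise is
  Beta-distributed with concentration κ = 100 (sd ≈ 0.03 at the poles,
  a typical post-normalization technical + biological spread).  Probes in
  one analysis window share a pole, mirroring the local correlation of
  methylation at neighbouring CpGs.
* **genotypes** — heterozygous variants with 1–2 carriers (configurable);
  allele frequencies can refer to a larger notional discovery cohort
  (`af_reference_n`) because a 20-sample tissue subset cannot itself
  express MAF ≤ 1%.
* **motifs/PWMs** — consensus-dominated probability columns (dominant
  base 0.4–0.97) of width 8–20, placed on an even grid so that ± window
  probe sets never overlap between variants; a configurable fraction of
  variant-bearing motifs gains an overlapping same-TF twin to exercise
  merging.
* **planted effects** — carrier-specific shifts at window CpGs, signed
  away from the probe's pole; magnitude constant or ∝ ΔPWM; optional
  exp(−d/τ) decay with τ = 15 kb for long-range scenarios; clipping to
  [0,1] is counted.
* **nuisance probes** — a fraction of background probes gains a
  cell-fraction-correlated component (weight 0.8 on one Dirichlet-drawn
  blood fraction).
* **expression** — one gene per variant with TSS within ± 1.5 kb of it;
  planted pairs shift the carrier's expression by 3 gene-level standard
  deviations opposite in sign to the methylation shift (gain represses).

The generator does **not** model linkage disequilibrium, genuine spatial
autocorrelation beyond the shared-pole windows, probe cross-reactivity
beyond boolean flags, or cell-type interaction effects — so passing tests
demonstrate the statistics behave as designed under the assumed data
model, not that real cohorts satisfy that model.

## Validation experiments and problem sizes

All experiments live in `tfbsmeth.validation`; problem sizes were chosen
so that the full set runs in a few minutes on one core while keeping
observation counts statistically informative.

* *Permutation exactness* — 4 samples, 1 carrier, 1 probe where only the
  carrier is extreme: enumeration gives p = 1/4 exactly.
* *Type-I calibration* — 247 samples, 133 TFs × 10 two-carrier pairs × 6
  CpGs, no effects, 1,000 permutations.  With ~120 carrier cells per TF
  the discrete atom of the p-value at 1 (the probability of zero carrier
  outliers) stays near 1%, small enough for a meaningful KS comparison
  with U(0,1).
* *Planted recovery* — as above with 5 CpGs per window and shift 0.3 for
  20 TFs, 10,000 permutations.
* *ΔPWM coupling* — 45 TFs × 30 pairs, shift = 0.5·ΔPWM (coupled) or a
  constant 0.3 on a random half of pairs (decoupled null for the nominal
  rejection rate).
* *DMR* — 200 four-probe ± 400 bp clusters shifted by 0.25 in one
  carrier; the null run is compared with the analytic union bound
  Σ_anchors P(Binom(m_i, ⌊0.05n⌋/n) ≥ 3) per direction, an upper bound
  because it ignores the ≥ 0.1 mean-distance requirement.
* *Distance decay* — 20 TFs × 10 pairs, 30 probes per ± 100 kb window,
  shift 0.3·exp(−d/15 kb): the decayed shift crosses the 0.05 Δβ
  criterion around 27 kb, so recovery should vanish between 30 and 50 kb.
* *Expression* — 20 samples, 55 TFs × 10 single-carrier pairs, 5 TFs
  planted (50 pairs) with promoter shift 0.3 and z-shift 3.

## Numerical and design choices

* Tail width uses floor (k = ⌊0.05·n⌋), the conservative reading of "5%
  tails" with integer ranks.
* The permutation p-value's add-one estimator is deliberately
  conservative; exact-mode p-values are raw fractions.
* The exact two-sided Fisher p is discrete and conservative by
  construction, so its null distribution cannot be literally uniform:
  calibration is verified on the randomized ("fuzzy") transform
  p − u·pmf(obs), which is exactly U(0,1) if and only if the test is
  calibrated, together with a direct bound on P(p ≤ 0.05).  Reported
  p-values are always the exact ones.
* Significance summaries of the distance experiment tolerate one
  chance-level Bonferroni hit per far bin: with a 0.05 family-wise level
  per bin, a strict "zero far hits" criterion would fail in ~5% of seeds
  for reasons unrelated to correctness.
* Zero-variance degeneracies are handled explicitly: flat probes cannot
  be cell-fraction-excluded, flat genes are dropped before z-scoring,
  zero-variance paired differences give p = 1 (no shift) or p → 0 with a
  warning (constant shift).
* Exact duplicate motif instances count once in intersection/merging.

## Known limitations

* The permutation unit (per-pair carrier redraw) is one of several
  defensible choices; the whole-sample scheme is provided but the two are
  not equivalent when carriers are shared across pairs.
* Enrichment pools (probe, sample) cells, which weights pairs by their
  window CpG count; an unweighted per-pair statistic would behave
  differently for TFs with very uneven windows.
* DMR calls may overlap when two maximal ≤ 1 kb runs share probes; callers
  needing disjoint intervals should merge downstream.
* The expression stage assumes covariate-corrected inputs; the provided
  least-squares residualizer is a convenience, not a replacement for a
  proper covariate model.
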