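"""Core domain objects shared across the pipeline.

Coordinate conventions
----------------------
Variant positions and CpG positions are 1-based (VCF style).  Motif and
probe-body intervals are 0-based half-open (BED style).  A variant at
1-based position ``pos`` overlaps the interval ``[start, end)`` iff
``start < pos <= end``; :func:`variant_overlaps` is the single place this
rule is written down.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional

import numpy as np

BASES = "ACGT"
BASE_INDEX = {b: i for i, b in enumerate(BASES)}
COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A"}
AUTOSOMES = {str(i) for i in range(1, 23)}


def normalize_chrom(chrom: str) -> str:
    """Strip a leading ``chr`` prefix so 'chr1' and '1' compare equal."""
    return chrom[3:] if chrom.lower().startswith("chr") else chrom


def is_autosome(chrom: str) -> bool:
    return normalize_chrom(chrom) in AUTOSOMES


def variant_overlaps(pos: int, start: int, end: int) -> bool:
    """True iff a variant at 1-based ``pos`` falls inside 0-based ``[start, end)``."""
    return start < pos <= end


@dataclass
class Variant:
    """A biallelic single-nucleotide variant with its carrier samples.

    ``cohort_af`` is the alternate-allele frequency in the analysed cohort;
    ``external_afs`` maps reference-database names (e.g. ``gnomad``, ``kg``)
    to the frequency reported there.  A database absent from the map is
    treated as frequency 0 by the rare-variant filter.
    """

    chrom: str
    pos: int  # 1-based
    ref: str
    alt: str
    carriers: frozenset = field(default_factory=frozenset)
    cohort_af: float = 0.0
    external_afs: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.ref == self.alt:
            raise ValueError(f"ref == alt for variant at {self.chrom}:{self.pos}")
        for allele in (self.ref, self.alt):
            if allele not in BASE_INDEX:
                raise ValueError(f"non-ACGT allele {allele!r} at {self.chrom}:{self.pos}")
        self.carriers = frozenset(self.carriers)

    @property
    def key(self) -> str:
        return f"{self.chrom}:{self.pos}:{self.ref}>{self.alt}"


@dataclass(frozen=True)
class MotifSite:
    """One TFBS motif instance: a BED-style interval with TF name and strand."""

    chrom: str
    start: int  # 0-based
    end: int  # half-open
    tf_name: str
    strand: str = "+"

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(f"empty motif interval [{self.start},{self.end})")
        if self.strand not in "+-":
            raise ValueError(f"bad strand {self.strand!r}")

    @property
    def width(self) -> int:
        return self.end - self.start


@dataclass
class PWM:
    """Position probability matrix for one TF, rows ordered A,C,G,T."""

    tf_name: str
    probs: np.ndarray  # shape (4, width)

    def __post_init__(self) -> None:
        self.probs = np.asarray(self.probs, dtype=float)
        if self.probs.ndim != 2 or self.probs.shape[0] != 4:
            raise ValueError(f"PWM {self.tf_name}: expected 4 x width matrix")
        if (self.probs < 0).any():
            raise ValueError(f"PWM {self.tf_name}: negative probabilities")

    @property
    def width(self) -> int:
        return self.probs.shape[1]

    def prob(self, base: str, offset: int) -> float:
        return float(self.probs[BASE_INDEX[base], offset])

    def column_sums(self) -> np.ndarray:
        return self.probs.sum(axis=0)

    def renormalized(self) -> "PWM":
        return PWM(self.tf_name, self.probs / self.probs.sum(axis=0, keepdims=True))

    def reverse_complement(self) -> "PWM":
        # reverse positions and swap A<->T, C<->G rows
        return PWM(self.tf_name, self.probs[::-1, ::-1].copy())


@dataclass
class SnvTfbsPair:
    """A rare SNV paired with the (possibly merged) motif it disrupts.

    ``isolated`` is True when the pair was built from exactly one motif
    instance; only isolated pairs have a defined strand and support PWM
    disruption scoring.
    """

    variant: Variant
    tf_name: str
    chrom: str
    start: int  # 0-based merged interval
    end: int
    isolated: bool
    strand: Optional[str] = None

    @property
    def pair_id(self) -> str:
        return f"{self.variant.key}|{self.tf_name}"


@dataclass(frozen=True)
class DeltaPWM:
    """Binding-disruption score of one variant within one isolated motif."""

    pair_id: str
    motif_offset: int  # 0-based position within the motif, motif orientation
    ref_weight: float
    alt_weight: float
    delta: float


@dataclass(frozen=True)
class OutlierCall:
    probe_id: str
    pair_id: str
    carrier: str
    rank: int
    delta_beta: float
    direction: str  # "gain" | "loss"


@dataclass
class PermutationResult:
    tf_name: str
    bin_label: str  # "local" or e.g. "10-20kb"
    observed_ratio: float
    p_raw: float
    p_bonferroni: float
    n_pairs: int
    n_cpg_obs: int


@dataclass(frozen=True)
class DMR:
    sample: str
    chrom: str
    start: int  # 1-based position of first contributing probe
    end: int  # 1-based position of last contributing probe
    n_probes: int
    direction: str  # "hyper" | "hypo"


@dataclass(frozen=True)
class GeneModel:
    gene_id: str
    chrom: str
    strand: str
    tss: int  # 1-based, strand-aware transcription start
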