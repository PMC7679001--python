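"""Probe-level quality filtering applied before any outlier statistics.

Three filters, mirroring standard EPIC-array hygiene:

1. design flags — probes with a common SNP in the last five bases of the
   3' end, or mapping non-uniquely to the bisulfite-converted genome, plus
   any user-supplied blacklist;
2. cell-composition confounding — the probes most correlated with any of
   the six blood cell-type fractions, removed up to a fixed quota of the
   processed probes (default 5%);
3. assay disruption — probes whose body, interrogated CpG, or the base
   adjacent to the CpG carries one of the rare SNVs under test.

The surviving probe set is order-insensitive: running the filters in any
order removes the same probes, although the reason attributed to a probe
removed by several filters follows first-match order.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .models import Variant, variant_overlaps

log = logging.getLogger(__name__)

FILTER_REASONS = ["snp_in_last5", "multimapping", "user_blacklist",
                  "cellfrac_correlated", "snv_at_probe"]


@dataclass
class ProbeFilterReport:
    """Audit of one filtering pass: per-reason removals plus survivors."""

    n_input: int
    removed: dict[str, list[str]] = field(default_factory=dict)
    surviving: list[str] = field(default_factory=list)

    @property
    def counts(self) -> dict[str, int]:
        return {reason: len(ids) for reason, ids in self.removed.items()}

    @property
    def n_removed(self) -> int:
        return sum(len(ids) for ids in self.removed.values())

    def check(self) -> None:
        assert self.n_removed + len(self.surviving) == self.n_input

    def to_frame(self) -> pd.DataFrame:
        rows = [(pid, reason) for reason, ids in self.removed.items() for pid in ids]
        rows += [(pid, "retained") for pid in self.surviving]
        return pd.DataFrame(rows, columns=["probe_id", "status"])


def filter_flagged_probes(manifest: pd.DataFrame,
                          blacklist: Iterable | None = None) -> ProbeFilterReport:
    """Remove probes with design flags or present in a user blacklist.

    ``blacklist`` entries may be probe ids or ``(chrom, start, end)`` BED
    intervals; a probe matches an interval when its CpG falls inside it.
    Unknown blacklist probe ids are warned about, not fatal.
    """
    ids, intervals = set(), []
    for entry in blacklist or ():
        if isinstance(entry, str):
            ids.add(entry)
        else:
            intervals.append(tuple(entry))
    unknown = ids - set(manifest.index)
    if unknown:
        log.warning("blacklist references %d unknown probe ids", len(unknown))

    removed = {"snp_in_last5": [], "multimapping": [], "user_blacklist": []}
    surviving = []
    for pid, row in manifest.iterrows():
        if row["snp_in_last5"]:
            removed["snp_in_last5"].append(pid)
        elif row["multimapping"]:
            removed["multimapping"].append(pid)
        elif pid in ids or any(c == row["chrom"] and variant_overlaps(row["cpg_pos"], s, e)
                               for c, s, e in intervals):
            removed["user_blacklist"].append(pid)
        else:
            surviving.append(pid)
    report = ProbeFilterReport(len(manifest), removed, surviving)
    report.check()
    return report


def exclude_cellfrac_correlated(beta: pd.DataFrame, fractions: pd.DataFrame,
                                max_excluded_frac: float = 0.05,
                                mode: str = "max") -> ProbeFilterReport:
    """Remove the probes most correlated with any blood cell fraction.

    ``mode="max"`` (default) scores each probe by the maximum absolute
    Pearson correlation against the six cell-type fractions and removes
    the top ``floor(max_excluded_frac * n_probes)`` probes in one cut
    (ties broken by probe id order).  ``mode="per_fraction"`` instead
    removes up to ``floor(max_excluded_frac * n_probes / 6)`` top probes
    separately per fraction and takes the union.  Probes with undefined
    correlation (zero variance on either side) score 0 and are retained.
    """
    if beta.shape[1] < 8:
        raise ValueError("cell-fraction correlation needs >= 8 samples")
    X = beta.to_numpy(dtype=float)                       # P x n
    F = fractions.loc[beta.columns].to_numpy(dtype=float)  # n x 6
    Xc = X - X.mean(axis=1, keepdims=True)
    Fc = F - F.mean(axis=0, keepdims=True)
    xs = np.sqrt((Xc ** 2).sum(axis=1))
    fs = np.sqrt((Fc ** 2).sum(axis=0))
    with np.errstate(divide="ignore", invalid="ignore"):
        r = (Xc @ Fc) / np.outer(xs, fs)
    r = np.nan_to_num(r, nan=0.0, posinf=0.0, neginf=0.0)
    defined = (xs > 0) & (fs > 0).any()
    r = np.where(defined[:, None], np.abs(r), 0.0)

    if mode == "max":
        score = r.max(axis=1)
        quota = int(np.floor(max_excluded_frac * len(beta)))
        n_remove = min(quota, int((score > 0).sum()))
        # descending score; ties broken by probe id order
        order = np.lexsort((beta.index.to_numpy(), -score))[:n_remove]
        removed_ids = beta.index[np.sort(order)].tolist()
    elif mode == "per_fraction":
        quota = int(np.floor(max_excluded_frac * len(beta) / fractions.shape[1]))
        hit = np.zeros(len(beta), dtype=bool)
        for j in range(r.shape[1]):
            score = r[:, j]
            n_remove = min(quota, int((score > 0).sum()))
            hit[np.lexsort((beta.index.to_numpy(), -score))[:n_remove]] = True
        removed_ids = beta.index[hit].tolist()
    else:
        raise ValueError(f"unknown mode {mode!r}")
    surviving = beta.index.difference(removed_ids, sort=False).tolist()
    report = ProbeFilterReport(len(beta), {"cellfrac_correlated": removed_ids},
                               surviving)
    report.check()
    return report


def exclude_snv_overlapping_probes(manifest: pd.DataFrame,
                                   variants: Sequence[Variant]) -> ProbeFilterReport:
    """Remove probes disrupted by one of the rare SNVs under test.

    A probe is removed when a variant lies within its body interval, at the
    interrogated CpG, or at the base immediately following the CpG.
    """
    pos_by_chrom: dict[str, np.ndarray] = {}
    for v in variants:
        pos_by_chrom.setdefault(v.chrom, []).append(v.pos)
    pos_by_chrom = {c: np.array(sorted(p)) for c, p in pos_by_chrom.items()}

    removed, surviving = [], []
    for pid, row in manifest.iterrows():
        positions = pos_by_chrom.get(row["chrom"])
        hit = False
        if positions is not None:
            lo = int(np.searchsorted(positions, row["body_start"] + 1))
            hi = int(np.searchsorted(positions, row["body_end"], side="right"))
            hit = hi > lo
            if not hit:
                cpg = row["cpg_pos"]
                i = int(np.searchsorted(positions, cpg))
                hit = any(i + k < len(positions) and positions[i + k] in (cpg, cpg + 1)
                          for k in (0, 1))
        (removed if hit else surviving).append(pid)
    report = ProbeFilterReport(len(manifest), {"snv_at_probe": removed}, surviving)
    report.check()
    return report


def apply_filters(manifest: pd.DataFrame, beta: pd.DataFrame,
                  fractions: pd.DataFrame | None = None,
                  snv_tfbs_variants: Sequence[Variant] = (),
                  blacklist: Iterable | None = None,
                  max_excluded_frac: float = 0.05) -> ProbeFilterReport:
    """Run all probe filters and combine them into one report.

    Each filter is evaluated on the full input probe set, so the surviving
    set does not depend on the order the filters are listed in; a probe
    caught by several filters is attributed to the first matching reason.
    """
    flagged = filter_flagged_probes(manifest, blacklist)
    reason_of: dict[str, str] = {}
    for reason in ("snp_in_last5", "multimapping", "user_blacklist"):
        for pid in flagged.removed[reason]:
            reason_of.setdefault(pid, reason)
    if fractions is not None:
        cf = exclude_cellfrac_correlated(beta, fractions, max_excluded_frac)
        for pid in cf.removed["cellfrac_correlated"]:
            reason_of.setdefault(pid, "cellfrac_correlated")
    if snv_tfbs_variants:
        snv = exclude_snv_overlapping_probes(manifest, snv_tfbs_variants)
        for pid in snv.removed["snv_at_probe"]:
            reason_of.setdefault(pid, "snv_at_probe")
    removed: dict[str, list[str]] = {r: [] for r in FILTER_REASONS}
    surviving = []
    for pid in manifest.index:
        if pid in reason_of:
            removed[reason_of[pid]].append(pid)
        else:
            surviving.append(pid)
    report = ProbeFilterReport(len(manifest), removed, surviving)
    report.check()
    return report
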