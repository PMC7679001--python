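"""Readers and writers for every external format the pipeline touches.

Formats
-------
* minimal VCF 4.2 (one GT column per sample) for rare-SNV genotypes,
  read through :mod:`pysam`;
* BED6 for motif instances (``name`` = TF, ``strand`` used) and gene models
  (``name`` = gene id; TSS taken from the strand-appropriate end);
* a tab-separated PWM table: ``tf_name  width  A-row  C-row  G-row  T-row``
  with each row a comma-separated list of per-position probabilities;
* tab-separated matrices with a header row for the methylation beta matrix
  (probes x samples), the probe manifest, cell fractions and expression.

Validation is strict: beta values outside [0,1] or missing entries abort
the load (the downstream outlier statistic is rank-based and sensitive to
the number of samples, so silent imputation would bias it); PWM columns
are renormalized when within 1e-3 of summing to one and rejected otherwise.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import pysam

from .models import (
    BASES,
    DMR,
    GeneModel,
    MotifSite,
    OutlierCall,
    PWM,
    PermutationResult,
    Variant,
)

log = logging.getLogger(__name__)

PWM_COLSUM_TOL = 1e-3
MANIFEST_COLUMNS = ["probe_id", "chrom", "cpg_pos", "body_start", "body_end",
                    "snp_in_last5", "multimapping"]
CELL_TYPES = ["CD4T", "CD8T", "B", "NK", "Gran", "Mono"]


# ---------------------------------------------------------------------------
# variants (VCF)
# ---------------------------------------------------------------------------

def load_variants(vcf_path: str | Path) -> tuple[list[Variant], int]:
    """Load biallelic SNVs from a minimal VCF.

    Returns ``(variants, n_skipped)`` where ``n_skipped`` counts records
    dropped for being multiallelic or not single-nucleotide.  Carriers are
    the samples whose genotype contains the alternate allele.  Cohort allele
    frequency comes from INFO/AF when present, otherwise it is computed from
    the genotypes; any INFO key of the form ``<NAME>_AF`` is interpreted as
    an external-database frequency.
    """
    vcf = pysam.VariantFile(str(vcf_path))
    samples = list(vcf.header.samples)
    if len(samples) != len(set(samples)):
        raise ValueError(f"{vcf_path}: duplicate sample ids in VCF header")
    variants: list[Variant] = []
    skipped = 0
    for rec in vcf:
        if rec.alts is None or len(rec.alts) != 1:
            skipped += 1
            continue
        ref, alt = rec.ref, rec.alts[0]
        if len(ref) != 1 or len(alt) != 1 or ref not in BASES or alt not in BASES:
            skipped += 1
            continue
        carriers = []
        alt_alleles = 0
        called_alleles = 0
        for s in samples:
            gt = rec.samples[s].get("GT")
            if gt is None:
                raise ValueError(f"{vcf_path}: missing GT for sample {s} at {rec.chrom}:{rec.pos}")
            n_alt = sum(1 for a in gt if a == 1)
            alt_alleles += n_alt
            called_alleles += sum(1 for a in gt if a is not None)
            if n_alt:
                carriers.append(s)
        info = dict(rec.info)
        if "AF" in info:
            af = info["AF"]
            cohort_af = float(af[0] if isinstance(af, tuple) else af)
        else:
            cohort_af = alt_alleles / called_alleles if called_alleles else 0.0
        external = {}
        for key, val in info.items():
            if key.endswith("_AF") and key != "AF":
                v = val[0] if isinstance(val, tuple) else val
                external[key[:-3].lower()] = float(v)
        variants.append(Variant(rec.chrom, rec.pos, ref, alt,
                                frozenset(carriers), cohort_af, external))
    if skipped:
        log.info("load_variants(%s): skipped %d non-SNV/multiallelic records",
                 vcf_path, skipped)
    return variants, skipped


def write_variants(variants: Sequence[Variant], sample_ids: Sequence[str],
                   path: str | Path, contigs: Iterable[str] = ()) -> None:
    """Write a minimal VCF 4.2 with per-sample GT columns."""
    contigs = list(dict.fromkeys(contigs)) or sorted({v.chrom for v in variants})
    ext_keys = sorted({k for v in variants for k in v.external_afs})
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        for c in contigs:
            fh.write(f"##contig=<ID={c}>\n")
        fh.write('##INFO=<ID=AF,Number=A,Type=Float,Description="Cohort alternate allele frequency">\n')
        for k in ext_keys:
            fh.write(f'##INFO=<ID={k.upper()}_AF,Number=1,Type=Float,'
                     f'Description="{k} alternate allele frequency">\n')
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(sample_ids) + "\n")
        order = sorted(variants, key=lambda v: (contigs.index(v.chrom)
                                                if v.chrom in contigs else len(contigs),
                                                v.pos, v.ref, v.alt))
        for v in order:
            info = [f"AF={v.cohort_af:.6g}"]
            info += [f"{k.upper()}_AF={v.external_afs[k]:.6g}"
                     for k in sorted(v.external_afs)]
            gts = ["0/1" if s in v.carriers else "0/0" for s in sample_ids]
            fh.write(f"{v.chrom}\t{v.pos}\t.\t{v.ref}\t{v.alt}\t.\tPASS\t"
                     + ";".join(info) + "\tGT\t" + "\t".join(gts) + "\n")


# ---------------------------------------------------------------------------
# motifs / gene models / regions (BED)
# ---------------------------------------------------------------------------

def load_motifs(bed_path: str | Path) -> list[MotifSite]:
    """Load motif instances from BED6 (name = TF, score ignored)."""
    motifs = []
    with open(bed_path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 6:
                raise ValueError(f"{bed_path}:{ln}: expected 6 BED columns")
            chrom, start, end, name, _score, strand = fields[:6]
            motifs.append(MotifSite(chrom, int(start), int(end), name, strand))
    return motifs


def write_motifs(motifs: Sequence[MotifSite], path: str | Path) -> None:
    with open(path, "w") as fh:
        for m in sorted(motifs, key=lambda m: (m.chrom, m.start, m.end, m.tf_name)):
            fh.write(f"{m.chrom}\t{m.start}\t{m.end}\t{m.tf_name}\t0\t{m.strand}\n")


def load_gene_models(bed_path: str | Path) -> list[GeneModel]:
    """Gene models from BED6; the TSS is the 5' end with respect to strand."""
    genes = []
    seen = set()
    with open(bed_path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            chrom, start, end, gene_id, _score, strand = line.split("\t")[:6]
            if gene_id in seen:
                raise ValueError(f"{bed_path}:{ln}: duplicate gene id {gene_id}")
            seen.add(gene_id)
            start, end = int(start), int(end)
            tss = start + 1 if strand == "+" else end
            genes.append(GeneModel(gene_id, chrom, strand, tss))
    return genes


def write_gene_models(genes: Sequence[GeneModel], path: str | Path,
                      body_bp: int = 1000) -> None:
    """Write gene models as BED6 intervals extending ``body_bp`` from the TSS."""
    with open(path, "w") as fh:
        for g in sorted(genes, key=lambda g: (g.chrom, g.tss, g.gene_id)):
            if g.strand == "+":
                start, end = g.tss - 1, g.tss - 1 + body_bp
            else:
                start, end = max(0, g.tss - body_bp), g.tss
            fh.write(f"{g.chrom}\t{start}\t{end}\t{g.gene_id}\t0\t{g.strand}\n")


def load_regions(bed_path: str | Path) -> list[tuple[str, int, int]]:
    """Plain BED3 region list (meQTL / HSM intervals, blacklists...)."""
    regions = []
    with open(bed_path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            chrom, start, end = line.split("\t")[:3]
            regions.append((chrom, int(start), int(end)))
    return regions


# ---------------------------------------------------------------------------
# PWMs
# ---------------------------------------------------------------------------

def load_pwms(pwm_path: str | Path) -> dict[str, PWM]:
    """Load the per-TF probability matrices.

    Columns whose sums deviate from 1 by at most ``PWM_COLSUM_TOL`` are
    renormalized (and logged); larger deviations are a load error.
    """
    pwms: dict[str, PWM] = {}
    with open(pwm_path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 6:
                raise ValueError(f"{pwm_path}:{ln}: expected 6 tab-separated fields")
            tf, width = fields[0], int(fields[1])
            rows = [np.fromstring(f, sep=",") for f in fields[2:6]]
            probs = np.vstack(rows)
            if probs.shape != (4, width):
                raise ValueError(f"{pwm_path}:{ln}: {tf}: row lengths do not match width {width}")
            pwm = PWM(tf, probs)
            sums = pwm.column_sums()
            off = np.abs(sums - 1.0)
            if (off > PWM_COLSUM_TOL).any():
                bad = int(np.argmax(off))
                raise ValueError(f"{pwm_path}:{ln}: {tf}: column {bad} sums to {sums[bad]:.6f}")
            if (off > 1e-9).any():
                log.info("load_pwms: renormalized %s (max column deviation %.2g)", tf, off.max())
                pwm = pwm.renormalized()
            if tf in pwms:
                raise ValueError(f"{pwm_path}:{ln}: duplicate PWM for {tf}")
            pwms[tf] = pwm
    return pwms


def write_pwms(pwms: dict[str, PWM], path: str | Path) -> None:
    with open(path, "w") as fh:
        for tf in sorted(pwms):
            p = pwms[tf]
            rows = ["\t" + ",".join(f"{x:.6f}" for x in p.probs[i]) for i in range(4)]
            fh.write(f"{tf}\t{p.width}" + "".join(rows) + "\n")


# ---------------------------------------------------------------------------
# beta matrix + probe manifest
# ---------------------------------------------------------------------------

def load_beta(matrix_path: str | Path, manifest_path: str | Path
              ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Load the beta matrix (probes x samples) and probe manifest.

    The matrix must be complete (no NA) with every value in [0,1] and its
    probe set must exactly match the manifest.
    """
    beta = pd.read_csv(matrix_path, sep="\t", index_col=0)
    manifest = load_manifest(manifest_path)
    if beta.isna().any().any():
        probe = beta.index[beta.isna().any(axis=1)][0]
        raise ValueError(f"{matrix_path}: missing beta value at probe {probe}")
    bad = (beta.values < 0) | (beta.values > 1)
    if bad.any():
        i, j = np.argwhere(bad)[0]
        raise ValueError(f"{matrix_path}: beta value {beta.iat[i, j]} outside [0,1] "
                         f"at probe {beta.index[i]}, sample {beta.columns[j]}")
    if set(beta.index) != set(manifest.index):
        raise ValueError("beta matrix and manifest disagree on probe ids")
    return beta.loc[manifest.index], manifest


def load_manifest(manifest_path: str | Path) -> pd.DataFrame:
    manifest = pd.read_csv(manifest_path, sep="\t", dtype={"chrom": str})
    missing = set(MANIFEST_COLUMNS) - set(manifest.columns)
    if missing:
        raise ValueError(f"{manifest_path}: missing columns {sorted(missing)}")
    if manifest["probe_id"].duplicated().any():
        raise ValueError(f"{manifest_path}: duplicate probe ids")
    manifest = manifest.set_index("probe_id")
    inside = ((manifest["cpg_pos"] >= manifest["body_start"]) &
              (manifest["cpg_pos"] <= manifest["body_end"] + 1))
    if not inside.all():
        probe = manifest.index[~inside][0]
        raise ValueError(f"{manifest_path}: cpg_pos outside probe body for {probe}")
    manifest["snp_in_last5"] = manifest["snp_in_last5"].astype(bool)
    manifest["multimapping"] = manifest["multimapping"].astype(bool)
    return manifest


def write_beta(beta: pd.DataFrame, manifest: pd.DataFrame,
               matrix_path: str | Path, manifest_path: str | Path) -> None:
    beta.rename_axis("probe_id").to_csv(matrix_path, sep="\t", float_format="%.6f")
    out = manifest.copy()
    out["snp_in_last5"] = out["snp_in_last5"].astype(int)
    out["multimapping"] = out["multimapping"].astype(int)
    out.rename_axis("probe_id").to_csv(manifest_path, sep="\t")


# ---------------------------------------------------------------------------
# cell fractions / expression
# ---------------------------------------------------------------------------

def load_cell_fractions(path: str | Path) -> pd.DataFrame:
    frac = pd.read_csv(path, sep="\t", index_col=0)
    missing = set(CELL_TYPES) - set(frac.columns)
    if missing:
        raise ValueError(f"{path}: missing cell types {sorted(missing)}")
    frac = frac[CELL_TYPES]
    totals = frac.sum(axis=1)
    bad = (totals < 0.9) | (totals > 1.1)
    if bad.any():
        raise ValueError(f"{path}: fractions for sample {totals.index[bad][0]} "
                         f"sum to {totals[bad].iloc[0]:.3f}, outside [0.9, 1.1]")
    return frac


def write_cell_fractions(frac: pd.DataFrame, path: str | Path) -> None:
    frac.rename_axis("sample_id").to_csv(path, sep="\t", float_format="%.6f")


def load_expression(path: str | Path) -> tuple[pd.DataFrame, pd.Series]:
    """Expression matrix: first column ``mean_rpkm``, then one column per sample."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    if "mean_rpkm" not in df.columns:
        raise ValueError(f"{path}: expected a mean_rpkm column")
    rpkm = df["mean_rpkm"]
    return df.drop(columns=["mean_rpkm"]), rpkm


def write_expression(expr: pd.DataFrame, rpkm_means: pd.Series, path: str | Path) -> None:
    out = expr.copy()
    out.insert(0, "mean_rpkm", rpkm_means)
    out.rename_axis("gene_id").to_csv(path, sep="\t", float_format="%.6f")


# ---------------------------------------------------------------------------
# result tables
# ---------------------------------------------------------------------------

def write_outlier_calls(calls: Sequence[OutlierCall], path: str | Path) -> None:
    rows = [(c.probe_id, c.pair_id, c.carrier, c.rank, c.delta_beta, c.direction)
            for c in calls]
    pd.DataFrame(rows, columns=["probe_id", "pair_id", "carrier", "rank",
                                "delta_beta", "direction"]
                 ).to_csv(path, sep="\t", index=False, float_format="%.6f")


def write_tf_results(results: Sequence[PermutationResult], path: str | Path) -> None:
    rows = [(r.tf_name, r.bin_label, r.observed_ratio, r.p_raw, r.p_bonferroni,
             r.n_pairs, r.n_cpg_obs) for r in results]
    pd.DataFrame(rows, columns=["tf_name", "bin", "enrichment_ratio", "p_raw",
                                "p_bonferroni", "n_pairs", "n_cpg_obs"]
                 ).to_csv(path, sep="\t", index=False, float_format="%.6g")


def write_dmrs(dmrs: Sequence[DMR], path: str | Path) -> None:
    """DMR BED-like table: chrom, start, end, sample, direction, n_probes."""
    with open(path, "w") as fh:
        for d in sorted(dmrs, key=lambda d: (d.chrom, d.start, d.end, d.sample)):
            fh.write(f"{d.chrom}\t{d.start - 1}\t{d.end}\t{d.sample}\t"
                     f"{d.direction}\t{d.n_probes}\n")


def write_pair_table(rows: Iterable[dict], path: str | Path) -> None:
    pd.DataFrame(list(rows)).to_csv(path, sep="\t", index=False, float_format="%.6g")
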