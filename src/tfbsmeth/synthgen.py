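"""Synthetic cohort generator with planted regulatory effects.

Emulates the statistical structure the outlier analysis assumes: a cohort of
unrelated samples genotyped for rare SNVs (1-2 heterozygous carriers each),
a catalogue of TF motif instances with per-TF probability matrices, an
EPIC-like methylation beta matrix (bimodal baseline, Beta-distributed
per-probe noise, optional cell-fraction-correlated nuisance probes), blood
cell-type fractions, and optionally a gene-expression matrix whose planted
outliers are coupled to promoter methylation shifts.

Planted effects are carrier-specific beta shifts at the CpGs surrounding a
mutated motif.  The shift magnitude is either constant
(``effect_beta_shift``) or proportional to the PWM disruption of the planted
allele (``effect_pwm_coupling``); its sign pushes away from the probe's
methylation pole (gains at hypomethylated probes, losses at hypermethylated
ones) so that the +/-0.05 delta-beta criterion is exercised at both poles.
Probes within one window share a methylation pole, mirroring the local
correlation of methylation levels at neighbouring CpGs.

Every draw flows from a single :class:`numpy.random.Generator` seeded from
``SimConfig.seed``, so a fixed config yields byte-identical output files.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from . import io as fio
from .models import BASES, COMPLEMENT, GeneModel, MotifSite, PWM, Variant

log = logging.getLogger(__name__)


@dataclass
class SimConfig:
    """Parameters of one synthetic cohort.

    The defaults describe the reference blood-cohort condition: 247 samples,
    133 TFs, five variant-bearing motifs per TF with five CpG probes within
    +/-1 kb of each, Beta noise with concentration 100 (per-probe standard
    deviation about 0.03 at the methylation poles), and no planted effects.
    """

    n_samples: int = 247
    n_probes: int = 5000
    n_tfs: int = 133
    n_motif_instances: int = 800
    n_variants: int = 665
    frac_effect_tfs: float = 0.0
    effect_beta_shift: float = 0.3
    effect_pwm_coupling: bool = False
    noise_concentration: float = 100.0
    frac_nuisance_probes: float = 0.02
    expression_effect_z: float = 3.0
    seed: int = 0
    genome_length_per_chrom: int = 5_000_000
    n_chroms: int = 4
    # placement details
    carriers_min: int = 1
    carriers_max: int = 2
    af_reference_n: Optional[int] = None  # cohort-AF denominator cohort size
    frac_effect_pairs: float = 1.0
    probes_per_window: int = 5
    probe_window_bp: int = 1000
    frac_overlapping_motifs: float = 0.0
    frac_flagged_probes: float = 0.0
    n_flank_variants: int = 0
    distance_decay: bool = False
    decay_tau_bp: int = 15_000
    with_expression: bool = False
    frac_low_expressed: float = 0.1
    nuisance_weight: float = 0.8

    def validate(self) -> None:
        if not 1 <= self.carriers_min <= self.carriers_max:
            raise ValueError("carrier count range invalid")
        for name in ("frac_effect_tfs", "frac_nuisance_probes",
                     "frac_overlapping_motifs", "frac_flagged_probes",
                     "frac_low_expressed", "effect_beta_shift",
                     "frac_effect_pairs"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} = {v} outside [0, 1]")
        for name in ("n_samples", "n_probes", "n_tfs", "n_motif_instances",
                     "n_chroms", "genome_length_per_chrom", "probes_per_window",
                     "probe_window_bp"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.n_samples < 4:
            raise ValueError("n_samples < 4: carrier-label permutations degenerate")
        if self.n_variants > self.n_motif_instances:
            raise ValueError("n_variants exceeds n_motif_instances")
        total = self.n_chroms * self.genome_length_per_chrom
        spacing = total // max(1, self.n_motif_instances + self.n_flank_variants)
        if spacing < 2 * self.probe_window_bp + 200:
            raise ValueError(
                f"genome too small: motif spacing {spacing} bp cannot hold "
                f"non-overlapping +/-{self.probe_window_bp} bp probe windows")


@dataclass
class Cohort:
    """In-memory bundle of everything :func:`generate_cohort` produces."""

    config: SimConfig
    sample_ids: list[str]
    variants: list[Variant]
    motifs: list[MotifSite]
    pwms: dict[str, PWM]
    beta: pd.DataFrame
    manifest: pd.DataFrame
    fractions: pd.DataFrame
    truth: pd.DataFrame
    expression: Optional[pd.DataFrame] = None
    rpkm_means: Optional[pd.Series] = None
    genes: Optional[list[GeneModel]] = None
    clip_events: int = 0


def _make_pwms(rng: np.random.Generator, tf_names: list[str]) -> dict[str, PWM]:
    """Consensus-dominated probability matrices with varied column entropy."""
    pwms = {}
    for tf in tf_names:
        width = int(rng.integers(8, 21))
        probs = np.empty((4, width))
        for j in range(width):
            dom = int(rng.integers(0, 4))
            p_dom = rng.uniform(0.4, 0.97)
            rest = rng.dirichlet(np.ones(3)) * (1.0 - p_dom)
            col = np.insert(rest, dom, p_dom)
            probs[:, j] = col
        pwms[tf] = PWM(tf, probs)
    return pwms


def _genomic_slot(index: int, spacing: int, chrom_len: int) -> tuple[int, int]:
    g = index * spacing + spacing // 2
    return g // chrom_len, g % chrom_len


def generate_cohort(config: SimConfig) -> Cohort:
    """Generate a fully self-consistent synthetic cohort with a truth table."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    n, P = config.n_samples, config.n_probes
    sample_ids = [f"S{i + 1:04d}" for i in range(n)]
    af_n = config.af_reference_n or n
    chrom_names = [f"chr{i + 1}" for i in range(config.n_chroms)]
    L = config.genome_length_per_chrom

    # --- TFs and PWMs ------------------------------------------------------
    tf_names = [f"TF{i + 1:03d}" for i in range(config.n_tfs)]
    pwms = _make_pwms(rng, tf_names)
    n_effect = int(round(config.frac_effect_tfs * config.n_tfs))
    effect_tfs = set(rng.permutation(tf_names)[:n_effect])

    # --- motif placement on an even grid -----------------------------------
    n_slots = config.n_motif_instances + config.n_flank_variants
    spacing = (config.n_chroms * L) // n_slots
    tf_cycle = list(rng.permutation(tf_names))
    motifs: list[MotifSite] = []
    for i in range(config.n_motif_instances):
        ci, start = _genomic_slot(i, spacing, L)
        tf = tf_cycle[i % config.n_tfs]
        width = pwms[tf].width
        strand = "+" if rng.random() < 0.5 else "-"
        motifs.append(MotifSite(chrom_names[ci], start, start + width, tf, strand))

    # --- variants inside the first n_variants motifs ------------------------
    variants: list[Variant] = []
    truth_rows: list[dict] = []
    extra_motifs: list[MotifSite] = []
    planted_meta: list[dict] = []  # per-variant planting info for the beta stage
    for i in range(config.n_variants):
        m = motifs[i]
        pwm = pwms[m.tf_name]
        w = pwm.width
        j = int(rng.integers(0, w))            # genome-frame column
        pos = m.start + j + 1                  # 1-based
        offset = j if m.strand == "+" else w - 1 - j
        col = pwm.probs[:, offset]
        ref_mf = BASES[int(np.argmax(col))]    # consensus base, motif frame
        alt_mf = rng.choice([b for b in BASES if b != ref_mf])
        delta = abs(pwm.prob(ref_mf, offset) - pwm.prob(alt_mf, offset))
        if m.strand == "+":
            ref, alt = ref_mf, alt_mf
        else:
            ref, alt = COMPLEMENT[ref_mf], COMPLEMENT[alt_mf]
        n_carriers = int(rng.integers(config.carriers_min, config.carriers_max + 1))
        carriers = frozenset(
            sample_ids[k] for k in rng.choice(n, n_carriers, replace=False))
        v = Variant(m.chrom, pos, ref, alt, carriers,
                    cohort_af=n_carriers / (2 * af_n),
                    external_afs={"gnomad": float(rng.uniform(0, 0.005)),
                                  "kg": float(rng.uniform(0, 0.005))})
        variants.append(v)
        planted = (m.tf_name in effect_tfs
                   and rng.random() < config.frac_effect_pairs)
        mag = config.effect_beta_shift * (delta if config.effect_pwm_coupling else 1.0)
        planted_meta.append({"variant": v, "motif": m, "planted": planted,
                             "magnitude": mag if planted else 0.0,
                             "delta_pwm": delta})
        if rng.random() < config.frac_overlapping_motifs:
            # add an overlapping same-TF instance still containing the variant
            pos0 = pos - 1
            if pos0 > m.start:
                s2 = m.start + int(rng.integers(1, pos0 - m.start + 1))
            else:
                s2 = m.start - int(rng.integers(1, 5))
            extra_motifs.append(MotifSite(m.chrom, s2, s2 + w, m.tf_name, m.strand))

    # flank-only variants: near a motif edge but outside every motif
    flank_meta: list[dict] = []
    for i in range(config.n_flank_variants):
        slot = config.n_motif_instances + i
        ci, start = _genomic_slot(slot, spacing, L)
        pos = start + int(rng.integers(50, 500))
        ref = rng.choice(list(BASES))
        alt = rng.choice([b for b in BASES if b != ref])
        n_carriers = int(rng.integers(config.carriers_min, config.carriers_max + 1))
        carriers = frozenset(
            sample_ids[k] for k in rng.choice(n, n_carriers, replace=False))
        v = Variant(chrom_names[ci], pos, ref, alt, carriers,
                    cohort_af=n_carriers / (2 * af_n),
                    external_afs={"gnomad": 0.0, "kg": 0.0})
        variants.append(v)
        # anchor motif placed just downstream so the variant sits in its flank
        tf = tf_cycle[slot % config.n_tfs]
        w = pwms[tf].width
        m_start = pos + int(rng.integers(100, config.probe_window_bp - 100))
        extra_motifs.append(MotifSite(chrom_names[ci], m_start, m_start + w, tf, "+"))
        flank_meta.append({"variant": v})
    motifs.extend(extra_motifs)

    # --- probe placement ----------------------------------------------------
    probe_rows: list[dict] = []   # chrom, cpg_pos, window index (-1 = background)
    window_intervals: dict[str, list[tuple[int, int]]] = {c: [] for c in chrom_names}
    half = config.probe_window_bp
    for wi, meta in enumerate(planted_meta):
        m: MotifSite = meta["motif"]
        v: Variant = meta["variant"]
        mid = (m.start + m.end) // 2
        window_intervals[m.chrom].append((mid - half - 50, mid + half + 50))
        pole_low = bool(rng.random() < 0.5)
        meta["pole_low"] = pole_low
        placed = 0
        while placed < config.probes_per_window:
            cpg = mid + int(rng.integers(-half, half + 1))
            if cpg < 60 or cpg > L - 60:
                continue
            if abs(cpg - v.pos) < 30:
                continue  # keep the SNV out of the probe body and CpG vicinity
            probe_rows.append({"chrom": m.chrom, "cpg_pos": cpg, "window": wi,
                               "pole_low": pole_low})
            placed += 1
    for meta in flank_meta:
        v: Variant = meta["variant"]
        window_intervals[v.chrom].append((v.pos - half - 50, v.pos + half + 50))
        pole_low = bool(rng.random() < 0.5)
        placed = 0
        while placed < config.probes_per_window:
            cpg = v.pos + int(rng.integers(-half, half + 1))
            if cpg < 60 or cpg > L - 60 or abs(cpg - v.pos) < 30:
                continue
            probe_rows.append({"chrom": v.chrom, "cpg_pos": cpg, "window": -1,
                               "pole_low": pole_low})
            placed += 1
    n_window_probes = len(probe_rows)
    n_bg = P - n_window_probes
    if n_bg < 0:
        raise ValueError(f"n_probes={P} too small for "
                         f"{n_window_probes} window probes")
    sorted_windows = {c: np.array(sorted(iv)) if iv else np.empty((0, 2), dtype=int)
                      for c, iv in window_intervals.items()}
    placed = 0
    while placed < n_bg:
        ci = int(rng.integers(0, config.n_chroms))
        cpg = int(rng.integers(60, L - 60))
        iv = sorted_windows[chrom_names[ci]]
        if len(iv):
            k = np.searchsorted(iv[:, 0], cpg, side="right") - 1
            if k >= 0 and cpg <= iv[k, 1]:
                continue  # inside an analysis window: resample
        probe_rows.append({"chrom": chrom_names[ci], "cpg_pos": cpg, "window": -1,
                           "pole_low": bool(rng.random() < 0.5)})
        placed += 1

    probes = pd.DataFrame(probe_rows)
    probes = probes.sort_values(["chrom", "cpg_pos"], kind="mergesort").reset_index(drop=True)
    probes["probe_id"] = [f"cg{i + 1:08d}" for i in range(len(probes))]

    # --- baseline beta ------------------------------------------------------
    pole_low = probes["pole_low"].to_numpy()
    mu = np.where(pole_low, rng.beta(2, 18, size=P), rng.beta(18, 2, size=P))
    kappa = config.noise_concentration
    beta_vals = rng.beta(np.outer(mu * kappa, np.ones(n)),
                         np.outer((1 - mu) * kappa, np.ones(n)))

    # --- cell fractions and nuisance probes --------------------------------
    alpha = np.array([6.0, 3.2, 2.0, 2.0, 24.0, 3.2])  # blood-like composition
    frac_vals = rng.dirichlet(alpha, size=n)
    fractions = pd.DataFrame(frac_vals, index=sample_ids, columns=fio.CELL_TYPES)
    bg_idx = probes.index[probes["window"] < 0].to_numpy()
    n_nui = int(np.floor(config.frac_nuisance_probes * P))
    nuisance_idx = rng.permutation(bg_idx)[:n_nui]
    probes["nuisance"] = False
    probes.loc[nuisance_idx, "nuisance"] = True
    for pi in nuisance_idx:
        col = int(rng.integers(0, 6))
        f = frac_vals[:, col]
        beta_vals[pi] += config.nuisance_weight * (f - f.mean())

    # --- planted carrier shifts --------------------------------------------
    sample_index = {s: k for k, s in enumerate(sample_ids)}
    window_of = probes["window"].to_numpy()
    for wi, meta in enumerate(planted_meta):
        probe_idx = np.flatnonzero(window_of == wi)
        affected: list[str] = []
        shift_signed = 0.0
        if meta["planted"] and meta["magnitude"] > 0:
            m: MotifSite = meta["motif"]
            sign = 1.0 if meta["pole_low"] else -1.0
            carrier_idx = [sample_index[s] for s in meta["variant"].carriers]
            for pi in probe_idx:
                cpg0 = probes.at[pi, "cpg_pos"] - 1
                if cpg0 < m.start:
                    d = m.start - cpg0
                elif cpg0 >= m.end:
                    d = cpg0 - m.end + 1
                else:
                    d = 0
                decay = np.exp(-d / config.decay_tau_bp) if config.distance_decay else 1.0
                beta_vals[pi, carrier_idx] += sign * meta["magnitude"] * decay
                affected.append(probes.at[pi, "probe_id"])
            shift_signed = sign * meta["magnitude"]
        meta["affected"] = affected
        meta["shift_signed"] = shift_signed

    clip_events = int(((beta_vals < 0) | (beta_vals > 1)).sum())
    if clip_events:
        log.info("generate_cohort: clipped %d beta values to [0,1]", clip_events)
    beta_vals = np.clip(beta_vals, 0.0, 1.0)
    beta = pd.DataFrame(beta_vals, index=probes["probe_id"], columns=sample_ids)

    # --- manifest -----------------------------------------------------------
    flags = rng.random((P, 2)) < config.frac_flagged_probes
    manifest = pd.DataFrame({
        "chrom": probes["chrom"].to_numpy(),
        "cpg_pos": probes["cpg_pos"].to_numpy(),
        "body_start": probes["cpg_pos"].to_numpy() - 11,
        "body_end": probes["cpg_pos"].to_numpy() + 39,
        "snp_in_last5": flags[:, 0],
        "multimapping": flags[:, 1],
    }, index=pd.Index(probes["probe_id"], name="probe_id"))

    # --- expression ---------------------------------------------------------
    expression = rpkm_means = genes = None
    if config.with_expression:
        gene_rows, expr_rows, gene_ids = [], [], []
        for wi, meta in enumerate(planted_meta):
            v: Variant = meta["variant"]
            gid = f"G{wi + 1:05d}"
            tss = v.pos + int(rng.integers(-1500, 1501))
            strand = "+" if rng.random() < 0.5 else "-"
            gene_rows.append(GeneModel(gid, v.chrom, strand, max(1, tss)))
            mean_g = rng.uniform(2.0, 50.0)
            sd_g = 0.2 * mean_g
            vals = mean_g + sd_g * rng.standard_normal(n)
            if meta["planted"] and meta["magnitude"] > 0:
                # methylation gain at the promoter represses; loss activates
                z_sign = -np.sign(meta["shift_signed"])
                for s in v.carriers:
                    vals[sample_index[s]] += z_sign * config.expression_effect_z * sd_g
            expr_rows.append(vals)
            gene_ids.append(gid)
            meta["gene_id"] = gid
        n_low = int(np.floor(config.frac_low_expressed * len(gene_rows)))
        for k in range(n_low):
            gid = f"GL{k + 1:04d}"
            ci = int(rng.integers(0, config.n_chroms))
            tss = int(rng.integers(1000, L - 1000))
            gene_rows.append(GeneModel(gid, chrom_names[ci], "+", tss))
            expr_rows.append(rng.uniform(0.0, 1.0, size=n))
            gene_ids.append(gid)
        expression = pd.DataFrame(expr_rows, index=pd.Index(gene_ids, name="gene_id"),
                                  columns=sample_ids)
        rpkm_means = expression.mean(axis=1)
        genes = gene_rows

    # --- truth table --------------------------------------------------------
    for meta in planted_meta:
        truth_rows.append({
            "variant_key": meta["variant"].key,
            "tf_name": meta["motif"].tf_name,
            "planted": meta["planted"],
            "planted_shift": meta["shift_signed"],
            "delta_pwm": meta["delta_pwm"],
            "affected_probes": ",".join(meta["affected"]),
            "gene_id": meta.get("gene_id", ""),
        })
    truth = pd.DataFrame(truth_rows, columns=["variant_key", "tf_name", "planted",
                                              "planted_shift", "delta_pwm",
                                              "affected_probes", "gene_id"])

    return Cohort(config=config, sample_ids=sample_ids, variants=variants,
                  motifs=motifs, pwms=pwms, beta=beta, manifest=manifest,
                  fractions=fractions, truth=truth, expression=expression,
                  rpkm_means=rpkm_means, genes=genes, clip_events=clip_events)


def write_cohort(cohort: Cohort, out_dir: str | Path) -> dict[str, Path]:
    """Write every cohort component to ``out_dir``; returns the file map."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    chroms = [f"chr{i + 1}" for i in range(cohort.config.n_chroms)]
    paths = {
        "vcf": out / "variants.vcf",
        "motifs": out / "motifs.bed",
        "pwms": out / "pwms.tsv",
        "beta": out / "beta.tsv",
        "manifest": out / "manifest.tsv",
        "fractions": out / "cell_fractions.tsv",
        "truth": out / "truth.tsv",
    }
    fio.write_variants(cohort.variants, cohort.sample_ids, paths["vcf"], contigs=chroms)
    fio.write_motifs(cohort.motifs, paths["motifs"])
    fio.write_pwms(cohort.pwms, paths["pwms"])
    fio.write_beta(cohort.beta, cohort.manifest, paths["beta"], paths["manifest"])
    fio.write_cell_fractions(cohort.fractions, paths["fractions"])
    cohort.truth.to_csv(paths["truth"], sep="\t", index=False, float_format="%.6f")
    if cohort.expression is not None:
        paths["expression"] = out / "expression.tsv"
        paths["genes"] = out / "genes.bed"
        fio.write_expression(cohort.expression, cohort.rpkm_means, paths["expression"])
        fio.write_gene_models(cohort.genes, paths["genes"])
    return paths
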