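import pytest

from tfbsmeth.synthgen import SimConfig, generate_cohort, write_cohort


SMALL_CONFIG = dict(n_samples=40, n_tfs=8, n_variants=40, n_motif_instances=48,
                    n_probes=300, probes_per_window=4, seed=7,
                    frac_effect_tfs=0.25, effect_beta_shift=0.3,
                    with_expression=True, n_flank_variants=4,
                    frac_flagged_probes=0.02, frac_overlapping_motifs=0.2,
                    frac_nuisance_probes=0.03, af_reference_n=247,
                    n_chroms=4, genome_length_per_chrom=1_000_000)


@pytest.fixture(scope="session")
def small_cohort():
    """A 40-sample cohort exercising every feature of the generator."""
    return generate_cohort(SimConfig(**SMALL_CONFIG))


@pytest.fixture(scope="session")
def cohort_dir(small_cohort, tmp_path_factory):
    out = tmp_path_factory.mktemp("cohort")
    paths = write_cohort(small_cohort, out)
    return paths
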