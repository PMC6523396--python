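import pytest

from transgeno.simulate import SimConfig, simulate_all


@pytest.fixture(scope="session")
def clean_bundle(tmp_path_factory):
    """Noise-free fixture bundle: planted truth is exactly recoverable."""
    return simulate_all(SimConfig(seed=11).noise_free(), tmp_path_factory.mktemp("clean"))


@pytest.fixture(scope="session")
def noisy_bundle(tmp_path_factory):
    """Default (noisy) fixture bundle emulating the study conditions."""
    return simulate_all(SimConfig(seed=12), tmp_path_factory.mktemp("noisy"))


@pytest.fixture(scope="session")
def discordance_truth():
    """Large two-library simulation with 5% planted replicate discordance.

    Sized so the shared-site count exceeds 2,000, enough for a binomial
    interval check on the recovered disagreement rate.
    """
    from transgeno import simulate as S

    cfg = SimConfig(
        seed=7,
        n_chrom=2,
        chrom_len=700_000,
        n_loci=120,
        locus_len=5_000,
        n_clean_markers=2600,
        n_singletons=0,
        n_close_pairs=0,
        n_multiallelic=0,
        het_rate=0.0,
        missing_rate=0.0,
        replicate_discordance_rate=0.05,
    )
    genome = S.simulate_genome(cfg)
    loci = S.simulate_annotation(cfg, genome)
    _, _, truth = S.simulate_strain_vcf(cfg, loci, genome)
    return truth
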