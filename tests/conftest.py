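import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from famevo import pipeline, synthetic

settings.register_profile(
    "ci", derandomize=True, max_examples=50,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("ci")


def small_sim_config() -> synthetic.SimConfig:
    """Desk-scale configuration for fast unit tests."""
    return synthetic.SimConfig(
        n_chromosomes=2, genes_per_chromosome=200, family_fraction=0.08,
        tandem_cluster_sizes=(3, 2), n_segmental_blocks=2,
        cds_codons=120, n_constitutive=4, n_specific=3, n_inactive=4,
        n_induced=3, n_suppressed=4,
        pop_n_chromosomes=2, pop_chrom_length=400_000, n_wild=12,
        n_cultivated=30, n_sweep_regions=1, sweep_span=60_000)


@pytest.fixture(scope="session")
def small_config():
    return small_sim_config()


@pytest.fixture(scope="session")
def genome_bundle(small_config):
    return synthetic.gen_genome(small_config, seed=11)


@pytest.fixture(scope="session")
def bundle_paths(genome_bundle, tmp_path_factory):
    outdir = tmp_path_factory.mktemp("bundle")
    return genome_bundle.write(outdir)


@pytest.fixture(scope="session")
def synthetic_run(small_config, tmp_path_factory):
    """A complete small synthetic run bundle plus its RunConfig."""
    outdir = tmp_path_factory.mktemp("run")
    cfg = pipeline.make_synthetic_run(str(outdir), seed=5,
                                      sim_config=small_config)
    cfg.bootstrap_reps = 30  # plenty for a smoke run at this scale
    return cfg


@pytest.fixture
def rng():
    return np.random.default_rng(0)
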