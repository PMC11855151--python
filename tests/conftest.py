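import numpy as np
import pytest

from lncnet import synthetic


@pytest.fixture(scope="session")
def small_config():
    """Down-scaled study: 1,000 transcripts, 100 planted signals, 2 hubs, 2 blocks."""
    return synthetic.SimulationConfig(
        n_transcripts=1000,
        lncrna_fraction=0.3,
        n_significant=100,
        n_hub_lncrnas=2,
        hub_degree=30,
        background_degree_max=10,
        n_equivalence_blocks=2,
        block_size=3,
        block_target_overlap=0.9,
        n_gene_sets=50,
        planted_enriched_set_overlap=15,
        n_samples=2000,
        seed=7,
    )


@pytest.fixture(scope="session")
def de_bundle(small_config):
    return synthetic.simulate_de_table(small_config, "test")


@pytest.fixture(scope="session")
def interaction_bundle(small_config, de_bundle):
    de_df, de_truth = de_bundle
    return synthetic.simulate_interaction_table(small_config, de_df, de_truth)


@pytest.fixture(scope="session")
def full_truth(de_bundle, interaction_bundle):
    _, de_truth = de_bundle
    _, net_truth = interaction_bundle
    return de_truth.merge(net_truth)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
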