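import numpy as np
import pytest

from ntsr_f2map.synthetic_data import SimConfig, simulate_dataset


@pytest.fixture(scope="session")
def small_config() -> SimConfig:
    """A reduced pseudo-F2 configuration for fast unit tests."""
    return SimConfig(
        n_scaffolds=4,
        scaffold_length_bp=6_000_000,
        genes_per_scaffold=80,
        n_f2=60,
        causal_scaffold=1,
        causal_pos_bp=3_000_000,
        trait_b_scaffold=3,
        trait_b_pos_bp=3_000_000,
        n_cis_genes=8,
        cluster_span_bp=1_500_000,
        seed=11,
    )


@pytest.fixture(scope="session")
def small_dataset(small_config):
    return simulate_dataset(small_config)


@pytest.fixture(scope="session")
def sim_dir(small_config, tmp_path_factory):
    out = tmp_path_factory.mktemp("simdata")
    simulate_dataset(small_config, out_dir=out)
    return out


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
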