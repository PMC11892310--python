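import pytest
from hypothesis import settings

from cottonmine import SimConfig, simulate_dataset, write_dataset

settings.register_profile("deterministic", derandomize=True, max_examples=50)
settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def small_config():
    return SimConfig(
        n_rils=60, n_genes=100, loci_per_chromosome=20, seed=7
    )


@pytest.fixture(scope="session")
def small_dataset(small_config):
    return simulate_dataset(small_config)


@pytest.fixture(scope="session")
def small_dataset_dir(small_dataset, tmp_path_factory):
    out = tmp_path_factory.mktemp("smallds")
    paths = write_dataset(small_dataset, out)
    return paths


@pytest.fixture(scope="session")
def default_dataset():
    """The full study-scale simulation: 550 RILs, 2,000 genes, 10% eQTL."""
    return simulate_dataset(SimConfig(seed=11))
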