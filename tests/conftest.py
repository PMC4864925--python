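import numpy as np
import pytest

from ptmdriver import SimulationConfig, simulate_bundle, write_bundle


@pytest.fixture(scope="session")
def small_config():
    return SimulationConfig(seed=11, n_proteins=50, protein_length_mean=250,
                            n_samples=80, burden_mean=15.0, n_gene_sets=20)


@pytest.fixture(scope="session")
def small_bundle(small_config):
    return simulate_bundle(small_config)


@pytest.fixture(scope="session")
def bundle_dir(small_bundle, tmp_path_factory):
    path = tmp_path_factory.mktemp("bundle")
    write_bundle(small_bundle, path)
    return path


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
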