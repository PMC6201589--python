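import numpy as np
import pytest

from biomesite import otu_table, synthetic


@pytest.fixture(scope="session")
def default_dataset():
    """The standard simulation: 5 sites x 300 samples, planted markers."""
    cfg = synthetic.default_config()
    table, meta, truth = synthetic.generate_dataset(cfg)
    return cfg, table, meta, truth


@pytest.fixture(scope="session")
def default_binary(default_dataset):
    _, table, _, _ = default_dataset
    return otu_table.binarize(table)


@pytest.fixture(scope="session")
def small_dataset():
    """A fast, strongly separable dataset for classifier tests."""
    cfg = synthetic.default_config(
        samples_per_site=[40] * 5, n_noise=40, n_indirect=5,
        n_studies=3, seed=7)
    table, meta, truth = synthetic.generate_dataset(cfg)
    return cfg, table, meta, truth


@pytest.fixture
def rng():
    return np.random.default_rng(123)
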