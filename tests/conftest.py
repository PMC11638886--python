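import numpy as np
import pytest

from pvsignal.cohort import build_analytic_dataset
from pvsignal.io import deduplicate_dataset
from pvsignal.synthetic import default_config, default_synonym_map, generate_dataset


@pytest.fixture(scope="session")
def small_config():
    return default_config(seed=7, n_cases=4000)


@pytest.fixture(scope="session")
def small_dataset(small_config):
    dataset, ledger = generate_dataset(small_config)
    return dataset, ledger


@pytest.fixture(scope="session")
def analytic(small_dataset):
    dataset, _ = small_dataset
    clean = deduplicate_dataset(dataset)
    return build_analytic_dataset(clean, default_synonym_map())


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
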