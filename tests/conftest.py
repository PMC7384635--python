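import numpy as np
import pytest

from fusedggm import GeneratorConfig, GroupedDataset, Hyperparameters


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_dataset(rng):
    """Two groups, p = 3, easy scale."""
    Y = rng.standard_normal((40, 3))
    groups = np.repeat([1, 2], 20)
    return GroupedDataset(Y, groups)


@pytest.fixture
def quick_hyper():
    return Hyperparameters(n_iter=60, burn_in=10)
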