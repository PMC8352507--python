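import numpy as np
import pytest

from rfpt import Dataset, SynthSpec, TreeConfig, generate_dataset


@pytest.fixture
def stump_config():
    return TreeConfig(n_features_per_neuron=1)


@pytest.fixture
def xor_like():
    """Single feature whose extremes are class 0 and middle class 1."""
    return Dataset(np.array([[1.0], [2.0], [3.0], [4.0]]), [0, 1, 1, 0])


@pytest.fixture
def separable_1d():
    return Dataset(np.array([[1.0], [2.0], [3.0], [4.0]]), [0, 0, 1, 1])


@pytest.fixture
def planted_dataset():
    """50 features, one perfectly separable, the rest noise."""
    data, amap = generate_dataset(SynthSpec(n_samples=40, n_features=50, n_separable=1, seed=11))
    return data, amap


def random_small_instance(rng, max_samples=8, tie_prone=False):
    m = int(rng.integers(2, max_samples + 1))
    if tie_prone:
        x = rng.integers(0, 4, size=m).astype(float)
    else:
        x = rng.normal(size=m)
    y = rng.integers(0, 2, size=m)
    if len(np.unique(y)) < 2:
        y[0] = 1 - y[0]
    return Dataset(x[:, None], y)
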