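import numpy as np
import pytest

from epsvm import LabeledDataset, SimulationSpec, simulate_dataset


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def data1():
    """One realization of the 3-class block-structured simulation."""
    return simulate_dataset(SimulationSpec(index=1, seed=42))


@pytest.fixture
def two_class_toy(rng):
    """40 samples, 2 classes separated along 3 of 10 features."""
    X = rng.normal(size=(40, 10))
    y = np.repeat([1, 2], 20)
    X[y == 1, :3] += 2.0
    return LabeledDataset(X=X, y=y)


def make_binary(rng, n=60, p=8, shift=2.0, n_pos=20):
    """+1/-1 toy with the first two features informative."""
    X = rng.normal(size=(n, p))
    y = np.r_[np.ones(n_pos, dtype=int), -np.ones(n - n_pos, dtype=int)]
    X[y == 1, :2] += shift
    return X, y
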