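import numpy as np
import pytest

from litchivision.experiments import train_benchmark_models


@pytest.fixture(scope="session")
def trained_models():
    """Four classifiers trained once on synthetic orchard patches."""
    return train_benchmark_models(seed=2017, n_per_class=60)


@pytest.fixture(scope="session")
def separable_features():
    """Well-separated two-class 10-feature set (class means ±8 sigma apart,
    on opposite rays so the separation holds in angle as well as distance)."""
    rng = np.random.default_rng(7)
    n = 40
    fruit = rng.normal(8.0, 1.0, size=(n, 10))
    background = rng.normal(-8.0, 1.0, size=(n, 10))
    X = np.vstack([fruit, background])
    y = np.concatenate([np.ones(n, int), np.zeros(n, int)])
    return X, y


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
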