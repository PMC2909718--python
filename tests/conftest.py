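import numpy as np
import pytest

import poolsim as ps


@pytest.fixture
def rng():
    return np.random.default_rng(0)


@pytest.fixture
def small_cfg():
    """A reduced dataset configuration for fast unit tests."""
    return ps.SimulationConfig(
        n_per_class=10, n_features=60, n_de_genes=10, n_patterns=5
    )


@pytest.fixture
def fast_clf_cfg():
    """Classifier settings scaled down for unit-test speed."""
    return ps.ClassifierConfig(n_trees=100)


@pytest.fixture
def separable_data(rng):
    """Two well-separated point clouds: gap much larger than spread."""
    a = rng.normal(0.0, 0.3, size=(12, 4))
    b = rng.normal(6.0, 0.3, size=(12, 4))
    X = np.vstack([a, b])
    y = np.array(["A"] * 12 + ["B"] * 12)
    return X, y
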