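import numpy as np
import pandas as pd
import pytest

from evoselect.search_space import build_space
from evoselect.synthetic import SyntheticSpec, generate


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_space():
    """Linear-profile space over a 30-feature pool."""
    return build_space("linear", [f"f{i:03d}" for i in range(30)], subset_max=50)


@pytest.fixture
def planted_regression():
    """300 x 30 regression dataset with 3 planted informative features."""
    spec = SyntheticSpec(
        n_samples=300,
        n_features=30,
        n_informative=3,
        n_redundant=0,
        skewed_fraction=0.0,
        noise_sd=0.5,
        seed=7,
    )
    X, y, truth = generate(spec, np.random.default_rng(7))
    return X, y, truth


@pytest.fixture
def planted_classification():
    spec = SyntheticSpec(
        n_samples=300,
        n_features=30,
        n_informative=3,
        n_redundant=0,
        skewed_fraction=0.0,
        task="classification",
        class_balance=0.35,
        seed=11,
    )
    X, y, truth = generate(spec, np.random.default_rng(11))
    return X, y, truth
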