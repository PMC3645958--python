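import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("stable", derandomize=True, deadline=None)
settings.load_profile("stable")

from rglm import EnsembleConfig, SimDesign, dichotomize_median, simulate_expression, train_rglm


@pytest.fixture(scope="session")
def toy_gaussian_8x2():
    """Fixed 8x2 design (intercept + slope) with a known least-squares fit."""
    rng = np.random.default_rng(42)
    x = rng.normal(size=8)
    y = 1.5 + 2.0 * x + rng.normal(scale=0.3, size=8)
    design = np.column_stack([np.ones(8), x])
    return design, y


@pytest.fixture(scope="session")
def toy_forward_12x4():
    """Fixed 12x4 gaussian candidate set for the forward-path oracle."""
    rng = np.random.default_rng(7)
    X = rng.normal(size=(12, 4))
    y = 1.0 + 2.0 * X[:, 1] - 1.5 * X[:, 3] + rng.normal(scale=0.5, size=12)
    return X, y


@pytest.fixture(scope="session")
def small_binary_model():
    """A small trained binomial ensemble on module-structured expression data."""
    design = SimDesign(n_samples=80, n_genes=60, seed=11)
    X, y_cont, _ = simulate_expression(design)
    y = dichotomize_median(y_cont)
    cfg = EnsembleConfig(n_bags=30, seed=5)
    return train_rglm(X, y, cfg), X, y
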