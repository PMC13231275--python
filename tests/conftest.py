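import numpy as np
import pytest

from osnn.simulate import SimulationConfig, generate_dataset


@pytest.fixture(scope="session")
def tiny_dataset():
    """Small replicate (p=3, q=2) for fast training/gradient tests."""
    cfg = SimulationConfig(
        n_train=40, n_val=20, n_test=30, p=3, q=2, n_important=2, rho_ar=0.0, seed=7
    )
    return generate_dataset(cfg)


@pytest.fixture(scope="session")
def small_dataset():
    """Moderate replicate (p=10, q=3) for end-to-end fitting tests."""
    cfg = SimulationConfig(
        n_train=200, n_val=100, n_test=200, p=10, q=3, n_important=3, rho_ar=0.25, seed=5
    )
    return generate_dataset(cfg)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
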