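import numpy as np
import pytest

from qpcrcens import ScenarioConfig, simulate_dataset


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def scenario1():
    """Moderate-censoring scenario: beta0=3, beta1=0.5, sigma=1.5."""
    return ScenarioConfig(beta0=3.0, beta1=0.5, sigma=1.5)


@pytest.fixture
def small_dataset(rng):
    """A small simulated dataset with a realistic mix of censoring."""
    cfg = ScenarioConfig(beta0=3.0, beta1=0.5, sigma=1.5, n_samples=60)
    return simulate_dataset(cfg, rng)
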