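import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import hsiq

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def small_dataset() -> hsiq.Dataset:
    """40 samples, default spectral design, fixed seed."""
    return hsiq.simulate_dataset(hsiq.SyntheticConfig(n_samples=40, seed=7))


@pytest.fixture(scope="session")
def selection_dataset() -> hsiq.Dataset:
    """Low-noise 200-sample dataset used by the selection-recovery checks."""
    return hsiq.simulate_dataset(
        hsiq.SyntheticConfig(n_samples=200, noise_sd=0.01, seed=1)
    )


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
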