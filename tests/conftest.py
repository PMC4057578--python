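import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import nse

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def grid977():
    """The canonical 3-12 Hz grid at 977 Hz (periods 325..81)."""
    return nse.build_period_grid(977.0, 3.0, 12.0)


@pytest.fixture(scope="session")
def small_grid():
    """A fast grid at 100 Hz (periods 33..8) for brute-force oracles."""
    return nse.build_period_grid(100.0, 3.0, 12.0)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def white_noise_signal(rng, n, rate=977.0):
    """Normalized white-noise signal of length n."""
    return nse.normalize_signal(nse.Signal(rng.standard_normal(n), rate))
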