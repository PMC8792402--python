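import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci", derandomize=True, max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def ar1_series(rng, phi, t, n=1, sd=1.0):
    """Exact AR(1) sample paths (stationary start), shape (t, n)."""
    x = np.empty((t, n))
    x[0] = rng.normal(0, sd / np.sqrt(1 - phi**2), size=n)
    eps = rng.normal(0, sd, size=(t, n))
    for k in range(1, t):
        x[k] = phi * x[k - 1] + eps[k]
    return x


@pytest.fixture
def make_ar1():
    return ar1_series
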