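import numpy as np
import pytest

from growthgp import CovarianceSpec, TimeSeries, mixed_noisy_curve


@pytest.fixture
def rng():
    return np.random.default_rng(20160913)


@pytest.fixture
def se_spec():
    return CovarianceSpec.default("squared_exponential", [0.2, -0.5, -2.0])


@pytest.fixture
def small_series(rng):
    """A short noisy exponential on the log scale: f(t) = -1 + 0.4 t."""
    t = np.linspace(0.0, 5.0, 12)
    y = -1.0 + 0.4 * t + rng.normal(0, 0.05, t.size)
    return TimeSeries(t, y, transformed=True)


@pytest.fixture(scope="session")
def synthetic_dataset():
    return mixed_noisy_curve(n_points=100, seed=77)
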