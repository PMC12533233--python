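import numpy as np
import pytest

from plantsync import OscillatorParams, make_pseudo_dyads, simulate_population


@pytest.fixture(scope="session")
def small_population():
    """8 real dyads + their pseudo shuffles at a reduced series length."""
    base = OscillatorParams(n_samples=256)
    real = simulate_population(8, base=(base, base), heterogeneity=0.24, seed=11)
    pseudo = make_pseudo_dyads(real, seed=12)
    return real, pseudo


@pytest.fixture
def rng():
    return np.random.default_rng(2024)


def sinusoid(n, dt, period, phase=0.0, amplitude=1.0):
    t = np.arange(n) * dt
    return amplitude * np.sin(2.0 * np.pi * t / period + phase)


@pytest.fixture
def make_sinusoid():
    return sinusoid
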