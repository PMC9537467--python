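import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import biologger as bl

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def det_config() -> bl.DetectorConfig:
    return bl.DetectorConfig()


@pytest.fixture(scope="session")
def overnight_1h() -> bl.SynthRecording:
    """One hour of the default synthetic recording, shared across tests."""
    return bl.make_overnight(bl.SynthConfig(duration=3600.0, seed=11))


@pytest.fixture(scope="session")
def overnight_8h_rate3() -> bl.SynthRecording:
    """Full-night recording with a 3 cycles/hour SW-power modulation."""
    return bl.make_overnight(bl.SynthConfig(duration=8 * 3600.0, seed=5, cycle_rate=3.0))


def random_buffer(rng: np.random.Generator, config: bl.DetectorConfig) -> np.ndarray:
    """A random 2-s buffer mixing oscillations and noise.

    Drawn to straddle the detector's gates: frequency may fall in or out
    of the SW band, amplitudes bracket the amplitude threshold, and
    broadband noise perturbs the power ratio.
    """
    n = config.buffer_n
    t = np.arange(n) / config.fs
    x = np.zeros(n)
    for _ in range(rng.integers(1, 4)):
        f = rng.uniform(0.3, 15.0)
        a = rng.uniform(10.0, 200.0)
        x += a * np.cos(2 * np.pi * f * t + rng.uniform(0, 2 * np.pi))
    x += rng.normal(0.0, rng.uniform(1.0, 40.0), size=n)
    return x
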