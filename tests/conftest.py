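import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")

from lmr import AccelTrace, SimConfig, simulate_dog


def stationary_trace(
    incline_deg: float = 0.0,
    duration_s: float = 30.0,
    sampling_rate: float = 100.0,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> AccelTrace:
    """Noise-free (or lightly noised) trace at a fixed head-incline."""
    n = int(round(duration_s * sampling_rate))
    rng = np.random.default_rng(seed)
    phi = np.deg2rad(incline_deg)
    ax = np.zeros(n)
    ay = np.full(n, np.sin(phi))
    az = np.full(n, np.cos(phi))
    if noise_sd > 0:
        ax = ax + rng.normal(0, noise_sd, n)
        ay = ay + rng.normal(0, noise_sd, n)
        az = az + rng.normal(0, noise_sd, n)
    return AccelTrace(sampling_rate, ax, ay, az)


@pytest.fixture(scope="session")
def default_dog():
    """One default-condition simulated recording, shared across tests."""
    trace, track = simulate_dog(SimConfig(duration_s=1800.0, seed=11))
    return trace, track
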