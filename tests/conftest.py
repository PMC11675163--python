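import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from respcoupling import PreprocessConfig, RunConfig, SignalTrace

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[
        HealthCheck.too_slow,
        HealthCheck.function_scoped_fixture,
    ],
)
settings.load_profile("suite")


@pytest.fixture
def rng():
    return np.random.default_rng(0)


@pytest.fixture
def small_config():
    """Run configuration scaled to short, low-rate test recordings."""
    return RunConfig(
        preprocess=PreprocessConfig(segment_seconds=60.0),
        max_lag_s=10.0,
    )


def make_trace(samples, fs, label="x"):
    return SignalTrace(np.asarray(samples, dtype=float), fs, label)


@pytest.fixture
def sine_trace():
    """0.25 Hz unit sinusoid, 60 s at 250 Hz."""
    t = np.arange(15000) / 250.0
    return SignalTrace(np.sin(2 * np.pi * 0.25 * t), 250.0, "sine")
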