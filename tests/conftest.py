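import numpy as np
import pytest

from dailygait.synthetic import (
    BoutSpec,
    GaitProtocol,
    WeekConfig,
    synthesize_recording,
    synthesize_week,
)


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture
def clean_walk():
    """Noise-free 20-step walk at 120 steps/min with ground truth."""
    proto = GaitProtocol(
        duration=30.0,
        bouts=[BoutSpec(start=5.0, n_steps=20, cadence=120.0, step_length=0.6)],
        noise_sd=0.0,
    )
    return synthesize_recording(proto, rate=100.0)


@pytest.fixture(scope="session")
def week():
    """Desk-scale synthetic week (compressed 600 s days), noise-free."""
    cfg = WeekConfig(n_days=7, day_seconds=600.0, mean_bouts_per_day=5, noise_sd=0.0)
    return synthesize_week(cfg, seed=5)
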