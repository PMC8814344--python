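"""Shared fixtures: default pendulum, noiseless and noisy synthetic trials."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import settings

from stancefit.biomech import PendulumParams
from stancefit.cohort import (
    EMGModelSpec,
    HybridControllerSpec,
    PlatformProfile,
    SensorNoiseSpec,
    simulate_trial,
)

settings.register_profile("ci", deadline=None, max_examples=25, derandomize=True)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def params() -> PendulumParams:
    return PendulumParams()


@pytest.fixture(scope="session")
def profile() -> PlatformProfile:
    return PlatformProfile()


@pytest.fixture(scope="session")
def noiseless_trial(params, profile):
    """Fully noiseless EO trial: no torque, sensor or EMG measurement noise."""
    return simulate_trial(
        1, "EO", params,
        HybridControllerSpec(torque_noise_sd=0.0),
        EMGModelSpec(noise_sd=0.0),
        profile, seed=0,
        sensor_noise=SensorNoiseSpec.noiseless(),
    )


@pytest.fixture(scope="session")
def default_trial(params, profile):
    """EO trial at the default (study-condition) noise levels."""
    return simulate_trial(
        1, "EO", params, HybridControllerSpec(), EMGModelSpec(), profile, seed=0,
    )


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)
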