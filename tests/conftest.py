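import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from ladderflow import ChannelConfig, PopulationParams

settings.register_profile(
    "default", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("default")


@pytest.fixture
def small_params() -> PopulationParams:
    """A modest, well-behaved population for fast tests."""
    return PopulationParams(
        name="test",
        copies_mean=(1.0e6, 1.0e4, 8.0e4),
        copies_sd=(2.0e5, 2.0e3, 1.6e4),
        diameter_mean=15.0,
        diameter_sd=2.0,
        velocity_mean=15.0,
        velocity_sd=3.0,
        arrival_rate=100.0,
    )


@pytest.fixture
def noiseless_cfg() -> ChannelConfig:
    return ChannelConfig(noise_sd_mV=0.0)


@pytest.fixture
def default_cfg() -> ChannelConfig:
    return ChannelConfig()


def make_cell(copies=(30000, 0, 0), diameter=15.0, velocity=15.0,
              arrival=0.005):
    from ladderflow import GroundTruthCell
    return GroundTruthCell(copies=tuple(int(c) for c in copies),
                           diameter_um=diameter,
                           velocity_um_per_ms=velocity,
                           arrival_time_s=arrival)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
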