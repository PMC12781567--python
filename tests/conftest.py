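import numpy as np
import pytest

from flapwave.synth import SimConfig, gen_cohort, gen_hourly_table


@pytest.fixture(scope="session")
def default_config() -> SimConfig:
    return SimConfig(seed=0)


@pytest.fixture(scope="session")
def hourly_table():
    """Hourly flight table with both wind and swell effects, 24 birds."""
    return gen_hourly_table(SimConfig(seed=0), seed=4, n_birds=24, hours_per_bird=60)


@pytest.fixture(scope="session")
def tiny_cohort():
    """Two-bird, six-hour cohort exercising every input stream."""
    return gen_cohort(SimConfig(seed=2, n_birds=2, trip_hours=6.0))


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
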