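import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("default")

from ceekit.simulate import (  # noqa: E402
    SimConfig,
    simulate_genome,
    simulate_tf_peaks,
)


@pytest.fixture(scope="session")
def default_config() -> SimConfig:
    return SimConfig(seed=0)


@pytest.fixture(scope="session")
def default_genome(default_config):
    return simulate_genome(default_config)


@pytest.fixture(scope="session")
def default_peaks(default_config, default_genome):
    return simulate_tf_peaks(default_config, default_genome)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
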