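import pytest
from hypothesis import HealthCheck, settings

from mfcflux.simulate import SimulationConfig, simulate_batch_cycle

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def noise_free_cycle():
    """Default-condition cycle without measurement noise, plus ground truth."""
    return simulate_batch_cycle(SimulationConfig(noise_cv=0.0), seed=7)


@pytest.fixture(scope="session")
def noisy_cycle():
    """Default-condition cycle with the standard 2% measurement noise."""
    return simulate_batch_cycle(SimulationConfig(), seed=7)
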