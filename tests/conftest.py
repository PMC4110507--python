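import pytest

from tremorkit.io_formats import SensorConfiguration
from tremorkit.synth import SynthConfig, make_fixture_suite, simulate_trial

THREE_SENSOR_CONFIGS = [
    SensorConfiguration.THREE_MIMU_DISTAL,
    SensorConfiguration.THREE_MIMU_PROXIMAL,
]


@pytest.fixture(scope="session")
def default_sim():
    """One default-condition simulated trial (noise on, lag off)."""
    return simulate_trial(SynthConfig(seed=42))


@pytest.fixture(scope="session")
def clean_sim():
    """A noise-free, lag-free trial for exact-construction checks."""
    return simulate_trial(SynthConfig(seed=42, noise_sd=0.0))


@pytest.fixture(scope="session")
def suite3():
    """Twelve labelled three-sensor trials across tremor severities."""
    return make_fixture_suite(12, seed=11, configurations=THREE_SENSOR_CONFIGS)
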