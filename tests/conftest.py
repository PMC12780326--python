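import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")

from wheatflux.simulate import ScenarioConfig, ScenarioGenerator


@pytest.fixture(scope="session")
def default_generator():
    """Generator at the study's default conditions, fixed seed."""
    return ScenarioGenerator(ScenarioConfig(seed=0))


@pytest.fixture(scope="session")
def noise_free_generator():
    """Exact forward-model output: every noise sd zeroed."""
    return ScenarioGenerator(ScenarioConfig(
        seed=0,
        noise_sd_gsw_rel=0.0,
        noise_sd_aci_a=0.0,
        noise_sd_aci_gsw=0.0,
        noise_sd_kinetics_gsw=0.0,
        gsw_surface_noise_sd=0.0,
    ))


@pytest.fixture(scope="session")
def steady_records(default_generator):
    return default_generator.generate_steady_state()
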