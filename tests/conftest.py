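import pytest
from hypothesis import HealthCheck, settings

import strokestop as ss

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=100,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def table3():
    """The bundled 70-patient cohort table."""
    return ss.load_table3()


@pytest.fixture(scope="session")
def default_sim_config():
    return ss.default_config(seed=0)
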