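import pytest
from hypothesis import HealthCheck, settings

import emtsens as es

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    max_examples=30,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def table_params():
    """Baseline dimensional parameter values."""
    return es.default_dimensional_params()


@pytest.fixture(scope="session")
def dim_groups():
    """The 8 dimensional treatment groups (contact x TGF-beta)."""
    return es.treatment_groups("dimensional")


@pytest.fixture(scope="session")
def nondim_groups():
    return es.treatment_groups("nondimensional")
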