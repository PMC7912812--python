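import pytest
from hypothesis import HealthCheck, settings

from ventcea import baseline_fixture

settings.register_profile(
    "default", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("default")


@pytest.fixture(scope="session")
def baseline():
    """Shipped baseline configuration bundle."""
    return baseline_fixture()


@pytest.fixture(scope="session")
def baseline_traces(baseline):
    """Cohort traces of both arms under the baseline configuration."""
    return baseline.run()
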