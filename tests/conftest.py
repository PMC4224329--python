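import pytest
from hypothesis import HealthCheck, settings

from palaeomito.fixtures import bundled_reference, make_study_fixture

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def reference():
    return bundled_reference()


@pytest.fixture(scope="session")
def study_fixture():
    return make_study_fixture(seed=11)
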