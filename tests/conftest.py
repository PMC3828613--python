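import pytest
from hypothesis import HealthCheck, settings

from exorna import simdata

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def reference():
    """Default toy reference shared across tests (read-only)."""
    return simdata.build_reference(simdata.default_reference_spec(seed=11))


@pytest.fixture(scope="session")
def rrna_index(reference):
    from exorna.rrna import RrnaIndex

    return RrnaIndex(reference.rrna)
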