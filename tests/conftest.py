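import pytest
from hypothesis import HealthCheck, settings

from memspike import REFERENCE_PARAMS

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def ref():
    """The reference circuit parameter set (charge threshold exactly 1)."""
    return REFERENCE_PARAMS
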