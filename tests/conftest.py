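import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=100,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

from ccdecomp import enumerate_decompositions  # noqa: E402


@pytest.fixture(scope="session")
def enum40():
    """Enumeration of all periods up to 40 (shared across tests)."""
    return enumerate_decompositions(40)
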