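import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=60,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("ci")

from karyoevo import load_fixture_records, load_fixture_tree  # noqa: E402


@pytest.fixture
def fixture_tree():
    return load_fixture_tree()


@pytest.fixture
def fixture_records():
    return load_fixture_records()
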