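import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")

from mipkit.features import FrogerTable, ReferenceSet  # noqa: E402


@pytest.fixture(scope="session")
def refset() -> ReferenceSet:
    return ReferenceSet.load()


@pytest.fixture(scope="session")
def froger_table() -> FrogerTable:
    return FrogerTable.load()
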