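import pytest

from gabapbpk.engine import GABAPENTIN, Regimen, simulate
from gabapbpk.physiology import representative_individual


@pytest.fixture(scope="session")
def adult():
    return representative_individual("adult")


@pytest.fixture(scope="session")
def adult_400mg_profile(adult):
    """Reference single-dose simulation reused across test modules."""
    return simulate(adult, GABAPENTIN, Regimen.single(400.0, 48.0))
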