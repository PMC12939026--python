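import pytest
from hypothesis import settings

from cocoflux.doe import table1

settings.register_profile("deterministic", derandomize=True, max_examples=50)
settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def pilot():
    """The embedded 29-sample pilot design."""
    return table1()
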