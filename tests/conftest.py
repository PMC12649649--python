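import pytest

from respicpg.network import default_connectivity, simulate


@pytest.fixture(scope="session")
def default_raster_120s():
    """One 120 s default-network simulation shared by the acceptance tests."""
    return simulate(default_connectivity(), duration=120_000.0, seed=1)
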