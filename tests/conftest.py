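import pytest

from aeronts.config import RunConfig
from aeronts.synthetic import generate_campaign


@pytest.fixture(scope="session")
def config():
    return RunConfig()


@pytest.fixture(scope="session")
def small_campaign():
    """A small seasonal campaign with planted PFAS, shared across tests."""
    return generate_campaign(n_samples=30, n_features=250, n_blanks=8, seed=42,
                             pfas_chain_lengths=(6, 8, 10), pfas_region=3)
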