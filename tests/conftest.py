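import pytest

from lincatlas import simulate_paper_shape


@pytest.fixture(scope="session")
def bundle():
    """One desk-scale synthetic dataset shared across tests (fixed seed)."""
    return simulate_paper_shape(1)
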