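import pytest

from topoqspr import load_sulfonamides, index_table


@pytest.fixture(scope="session")
def sulfonamides():
    """The five bundled study compounds (partition + MP/FW)."""
    return load_sulfonamides()


@pytest.fixture(scope="session")
def indices_df(sulfonamides):
    return index_table(sulfonamides)
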