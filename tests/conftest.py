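import pytest

from logicpool.fixtures import rcc_network, toy_network


@pytest.fixture(scope="session")
def toy():
    return toy_network()


@pytest.fixture(scope="session")
def rcc():
    return rcc_network()


TOY_PKN_TEXT = """
A -> A +
A -> B +
B -> D +
D -> C +?
function B = A
function D = B
"""


@pytest.fixture()
def toy_pkn_text():
    return TOY_PKN_TEXT
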