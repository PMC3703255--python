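import pytest

from pathcards.fixtures import paper_fixtures


@pytest.fixture(scope="session")
def corpora():
    """The six hand-coded mini-corpora (built once per session)."""
    return paper_fixtures()


@pytest.fixture()
def arginase(corpora):
    return corpora["arginase"]


@pytest.fixture()
def ctps(corpora):
    return corpora["ctps"]


@pytest.fixture()
def deoxyuridine(corpora):
    return corpora["deoxyuridine"]


@pytest.fixture()
def succinate(corpora):
    return corpora["succinate_coa_ligase"]
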