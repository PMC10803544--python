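import pytest

from fcgrseq.gene_models import load_gene_config


@pytest.fixture(scope="session")
def genes():
    """Packaged FcγR gene models (validated on load)."""
    return load_gene_config()


@pytest.fixture(scope="session")
def fcgr1(genes):
    return genes["FCGR1"]


@pytest.fixture(scope="session")
def fcgr2a(genes):
    return genes["FCGR2A"]


@pytest.fixture(scope="session")
def fcgr2b(genes):
    return genes["FCGR2B"]


@pytest.fixture(scope="session")
def fcgr3(genes):
    return genes["FCGR3"]
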