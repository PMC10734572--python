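import pytest

from resmine import GeneRecord, GeneTable, Role


def rec(organism="orgA", gene_id="g1", scaffold="s1", start=100, stop=200, **kw):
    return GeneRecord(organism=organism, gene_id=gene_id, scaffold=scaffold,
                      start=start, stop=stop, **kw)


def table(role, *records):
    return GeneTable(role, tuple(records), source="test")


@pytest.fixture
def make_rec():
    return rec


@pytest.fixture
def make_table():
    return table
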