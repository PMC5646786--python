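import pytest

from sweepoverlap import GeneRecord, build_pool


@pytest.fixture
def sample_records():
    def make(symbol, species="dog", gene_class="protein_coding"):
        return GeneRecord(
            symbol_raw=symbol,
            symbol=symbol,
            species=species,
            comparison="test",
            source="unit",
            gene_class=gene_class,
        )

    return make


@pytest.fixture
def make_pool(sample_records):
    def _make(label, symbols, species="dog"):
        return build_pool(label, [sample_records(s, species=species) for s in symbols])

    return _make
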