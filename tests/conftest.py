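import numpy as np
import pandas as pd
import pytest

from tbxsplice.exon_quant import COUNT_COLUMNS, SpliceEventAnnotation


def make_event(
    event_id="ev1",
    gene_id="g1",
    chrom="chr1",
    strand="+",
    exons=((100, 200), (1200, 1300), (2300, 2400)),
    alt=(1,),
):
    return SpliceEventAnnotation.cassette(event_id, gene_id, chrom, strand, exons, alt)


@pytest.fixture
def toy_event():
    return make_event()


def counts_row(event_id, sample_id, condition, compartment, replicate, exon, gene, lib):
    return dict(zip(COUNT_COLUMNS, (event_id, sample_id, condition, compartment, replicate, exon, gene, lib)))


def make_counts(rows):
    return pd.DataFrame(rows, columns=COUNT_COLUMNS)


@pytest.fixture
def rng():
    return np.random.default_rng(20240911)
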