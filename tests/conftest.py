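import numpy as np
import pytest

from splicegrammar.genome_annotation_io import (
    Genome,
    GenomeSequence,
    TranscriptModel,
    donor_window,
)


@pytest.fixture
def d5():
    """Donor-window factory from ``XX//YYYYY`` notation."""
    return donor_window


@pytest.fixture
def toy_genome():
    # chrom of 40 nt: exon [0,10) | intron [10,30) | exon [30,40)
    #                 ...GATTC | GTGAGTTTTTTTTTTTGCAG | CATTTGGGGG
    seq = "ATCGAGATTC" + "GTGAGTTTTTTTTTTTGCAG" + "CATTTGGGGG"
    return Genome([GenomeSequence("chr1", seq)])


@pytest.fixture
def toy_transcripts():
    t1 = TranscriptModel("T1", "G1", "chr1", "+", ((0, 10), (30, 40)))
    return [t1]


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
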