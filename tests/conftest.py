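import numpy as np
import pytest

from mirpollen.annotation_io import GenomicInterval, TranscriptModel


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240901)


def make_transcript(
    tid="t1",
    gene="g1",
    strand="+",
    exons=((0, 100),),
    cds=(),
    utr5=(),
    utr3=(),
    chrom="chr1",
):
    mk = lambda ivs: tuple(GenomicInterval(chrom, s, e, strand) for s, e in ivs)
    return TranscriptModel(
        tid, gene, strand, mk(exons), cds=mk(cds), utr5=mk(utr5), utr3=mk(utr3)
    )


@pytest.fixture
def transcript_factory():
    return make_transcript
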