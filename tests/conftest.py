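import numpy as np
import pytest

from luatscan.types import GenomeAssembly, StrandedReadSet, TranscriptModel


def make_tx(tid, exons, strand="+", gene=None, chrom="chr1", coding=True):
    return TranscriptModel(
        transcript_id=tid,
        gene_id=gene or tid.split(".")[0],
        chrom=chrom,
        strand=strand,
        exons=tuple(exons),
        is_coding=coding,
    )


def make_reads(records):
    """records: iterable of (chrom, start, end, strand)."""
    return StrandedReadSet.from_records(records)


@pytest.fixture
def flat_genome():
    """Two featureless 100 kb chromosomes (all A) for coordinate tests."""
    return GenomeAssembly({"chr1": "A" * 100_000, "chr2": "A" * 100_000})


@pytest.fixture
def rng():
    return np.random.default_rng(2024)
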