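import pytest

from locusforge.intervals import GenomicInterval
from locusforge.io_formats import TranscriptModel
from locusforge.synthetic_fixtures import (
    FixtureParams,
    simulate_annotation_fixture,
)


def iv(start, end, seq="chr1", strand="+"):
    return GenomicInterval(seq, start, end, strand)


def mk_model(
    model_id,
    exons,
    cds=None,
    gene_id=None,
    source="test",
    seq="chr1",
    strand="+",
    protein_length=None,
):
    """Build a TranscriptModel from (start, end) tuples."""
    exon_ivs = tuple(iv(s, e, seq, strand) for s, e in exons)
    cds_ivs = tuple(iv(s, e, seq, strand) for s, e in (cds or ()))
    if protein_length is None and cds_ivs:
        protein_length = max(sum(c.length for c in cds_ivs) // 3, 1)
    return TranscriptModel(
        model_id=model_id,
        gene_id=gene_id or model_id.split(".")[0],
        source=source,
        exons=exon_ivs,
        cds=cds_ivs,
        protein_length=protein_length,
    )


def per_base_set(intervals):
    """Brute-force oracle: the explicit set of (seq_id, position) bases."""
    out = set()
    for i in intervals:
        for pos in range(i.start, i.end + 1):
            out.add((i.seq_id, pos))
    return out


@pytest.fixture(scope="session")
def small_fixture():
    """A 30-gene annotation fixture shared by read-only tests."""
    return simulate_annotation_fixture(FixtureParams(seed=7, n_genes=30))
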