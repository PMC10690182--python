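import pytest

from spliceunion.model import AnnotationSet, ShortReadEvidence, Transcript
from spliceunion.graph import build_splice_graph


@pytest.fixture
def toy_annotation() -> AnnotationSet:
    """One + strand gene: 4-exon full transcript and an exon-3-skipping one.

    Annotated junctions: (201,300), (401,500), (601,700) and the skip
    junction (401,700).
    """
    transcripts = [
        Transcript(
            "T1", "G1", "chr1", "+",
            ((101, 200), (301, 400), (501, 600), (701, 800)),
        ),
        Transcript(
            "T2", "G1", "chr1", "+",
            ((101, 200), (301, 400), (701, 800)),
        ),
    ]
    return AnnotationSet.from_transcripts(transcripts)


@pytest.fixture
def toy_short() -> ShortReadEvidence:
    ev = ShortReadEvidence(sample="toy")
    ev.junctions = {
        ("chr1", "+", 201, 300): 15,
        ("chr1", "+", 401, 500): 8,
        ("chr1", "+", 401, 700): 20,
        ("chr1", "+", 201, 340): 5,  # novel acceptor inside exon 2
    }
    ev.introns = {("chr1", "+", 601, 700): 12}
    return ev


@pytest.fixture
def toy_long() -> list[Transcript]:
    return [
        Transcript(
            "L1", "G1", "chr1", "+",
            ((101, 200), (301, 400), (501, 600), (701, 800)),
            read_count=4.0, source="long_reads",
        ),
        Transcript(  # skip isoform, truncated start inside exon 1 (pTSS)
            "L2", "G1", "chr1", "+",
            ((150, 200), (301, 400), (701, 800)),
            read_count=2.0, source="long_reads",
        ),
    ]


@pytest.fixture
def toy_graph(toy_annotation, toy_short, toy_long):
    return build_splice_graph(
        "G1", toy_annotation, toy_short, toy_long, short_min_reads=2
    )
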