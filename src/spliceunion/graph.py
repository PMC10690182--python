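"""Build per-gene unified splice graphs from annotation, short and long evidence.

The graph's edge set is the union over the three evidence sources. A
short-read junction supports an edge only when its unique-read count reaches
``short_min_reads``; long-read support requires at least one surviving
transcript containing the junction, and the edge's ``long_count`` is the sum
of read counts of those transcripts. Retained introns come from the
short-read IR table and from long-read transcripts whose exon fully spans an
annotated or short-observed intron. Annotation-only edges are kept in the
graph (for display/export) but are excluded from detected-element statistics.
"""

from __future__ import annotations

import logging
from typing import Iterable, Optional

from intervaltree import IntervalTree

from .model import (
    ANNOTATION,
    AnnotationSet,
    GeneAnnotation,
    Interval,
    JUNCTION,
    LONG,
    RETAINED_INTRON,
    SHORT,
    ShortReadEvidence,
    SpliceGraph,
    SpliceGraphEdge,
    Transcript,
    ValidationError,
    merge_intervals,
)

logger = logging.getLogger(__name__)


def junctions_of(transcript: Transcript) -> list[Interval]:
    """Intron intervals between consecutive exons of a transcript."""
    return transcript.junctions()


def assign_long_transcripts(
    long_transcripts: Iterable[Transcript], annotation: AnnotationSet
) -> dict[str, list[Transcript]]:
    """Assign long-read transcripts to annotated genes by exonic overlap.

    Each transcript goes to the same-strand gene with the largest exonic
    overlap (ties broken by lexicographically smaller gene_id); transcripts
    overlapping no gene are dropped with a logged count.
    """
    trees: dict[tuple[str, str], IntervalTree] = {}
    for gene in annotation.genes.values():
        key = (gene.chromosome, gene.strand)
        tree = trees.setdefault(key, IntervalTree())
        start, end = gene.span
        tree.addi(start, end + 1, gene.gene_id)

    exon_cache = {
        g.gene_id: g.exon_intervals() for g in annotation.genes.values()
    }
    assigned: dict[str, list[Transcript]] = {}
    dropped = 0
    for t in sorted(long_transcripts, key=lambda t: t.transcript_id):
        tree = trees.get((t.chromosome, t.strand))
        best: Optional[tuple[int, str]] = None
        if tree is not None:
            for hit in tree.overlap(t.start, t.end + 1):
                gid = hit.data
                overlap = _exonic_overlap(t.exons, exon_cache[gid])
                if overlap > 0 and (
                    best is None
                    or overlap > best[0]
                    or (overlap == best[0] and gid < best[1])
                ):
                    best = (overlap, gid)
        if best is None:
            dropped += 1
            continue
        assigned.setdefault(best[1], []).append(t)
    if dropped:
        logger.warning(
            "%d long-read transcripts overlapped no annotated gene and were dropped",
            dropped,
        )
    return assigned


def _exonic_overlap(exons_a: Iterable[Interval], exons_b: Iterable[Interval]) -> int:
    total = 0
    for s1, e1 in exons_a:
        for s2, e2 in exons_b:
            total += max(0, min(e1, e2) - max(s1, s2) + 1)
    return total


def build_splice_graph(
    gene_id: str,
    annotation: AnnotationSet,
    short: Optional[ShortReadEvidence] = None,
    long_transcripts: Iterable[Transcript] = (),
    short_min_reads: int = 2,
) -> SpliceGraph:
    """Build the unified splice graph of one gene.

    ``long_transcripts`` must already be gene-assigned (see
    :func:`assign_long_transcripts`) and count-filtered.
    """
    long_transcripts = list(long_transcripts)
    ann: Optional[GeneAnnotation] = annotation.genes.get(gene_id)
    if ann is None and not long_transcripts:
        raise ValidationError(f"gene {gene_id} unknown to all sources")

    if ann is not None:
        chromosome, strand = ann.chromosome, ann.strand
    else:
        chromosome, strand = long_transcripts[0].chromosome, long_transcripts[0].strand
    for t in long_transcripts:
        if (t.chromosome, t.strand) != (chromosome, strand):
            raise ValidationError(
                f"gene {gene_id}: long-read transcript {t.transcript_id} on "
                f"contradictory chromosome/strand"
            )

    ann_transcripts = list(ann.transcripts) if ann is not None else []
    all_transcripts = ann_transcripts + long_transcripts
    span_start = min(t.start for t in all_transcripts)
    span_end = max(t.end for t in all_transcripts)

    edges: dict[tuple[str, int, int], SpliceGraphEdge] = {}

    def edge(kind: str, start: int, end: int) -> SpliceGraphEdge:
        key = (kind, start, end)
        if key not in edges:
            edges[key] = SpliceGraphEdge(kind=kind, start=start, end=end)
        return edges[key]

    # annotation junctions
    if ann is not None:
        for start, end in sorted(ann.junctions):
            edge(JUNCTION, start, end).support.add(ANNOTATION)

    # short-read junctions within the gene span, strand-matched ('.' resolves
    # to this gene's strand by coordinates)
    if short is not None:
        for (chrom, jstrand, start, end), count in sorted(short.junctions.items()):
            if chrom != chromosome or jstrand not in (strand, "."):
                continue
            if start < span_start or end > span_end:
                continue
            if count >= short_min_reads:
                e = edge(JUNCTION, start, end)
                e.support.add(SHORT)
                e.short_count += count

    # long-read junctions
    for t in long_transcripts:
        for start, end in t.junctions():
            e = edge(JUNCTION, start, end)
            e.support.add(LONG)
            e.long_count += t.read_count or 0.0

    # retained introns: short IR table rows ...
    if short is not None:
        for (chrom, istrand, start, end), count in sorted(short.introns.items()):
            if chrom != chromosome or istrand not in (strand, "."):
                continue
            if start < span_start or end > span_end:
                continue
            e = edge(RETAINED_INTRON, start, end)
            e.support.add(SHORT)
            e.short_count += count

    # ... and long-read exons fully spanning an annotated or short-observed
    # intron (both flanking splice sites strictly inside the exon).
    comparison_introns: set[Interval] = set()
    if ann is not None:
        comparison_introns |= set(ann.junctions)
    comparison_introns |= {
        (e.start, e.end)
        for e in edges.values()
        if e.kind == JUNCTION and SHORT in e.support
    }
    for t in long_transcripts:
        for ex_start, ex_end in t.exons:
            for i_start, i_end in comparison_introns:
                if ex_start < i_start and i_end < ex_end:
                    e = edge(RETAINED_INTRON, i_start, i_end)
                    e.support.add(LONG)
                    e.long_count += t.read_count or 0.0

    # merged exons across all sources; orphan edge endpoints (short-only
    # junctions landing outside any known exon) get a minimal anchoring exon.
    exon_ivs = [iv for t in all_transcripts for iv in t.exons]
    merged = merge_intervals(exon_ivs)
    orphan_anchors = []
    for e in edges.values():
        for pos in (e.start - 1, e.end + 1):
            if not any(s <= pos <= en for s, en in merged):
                orphan_anchors.append((pos, pos))
    if orphan_anchors:
        merged = merge_intervals(merged + orphan_anchors)

    graph = SpliceGraph(
        gene_id=gene_id,
        chromosome=chromosome,
        strand=strand,
        exons=merged,
        edges=dict(sorted(edges.items())),
        transcripts=all_transcripts,
        tss={
            ANNOTATION: {t.tss for t in ann_transcripts},
            LONG: {t.tss for t in long_transcripts},
        },
        tes={
            ANNOTATION: {t.tes for t in ann_transcripts},
            LONG: {t.tes for t in long_transcripts},
        },
    )
    graph.validate()
    return graph


def detect_ptss_ptes(
    transcript: Transcript,
    annotation: AnnotationSet,
    boundary_window: int = 0,
) -> tuple[bool, bool]:
    """Flag putative TSS/TES of a long-read transcript.

    pTSS is true iff the transcript's strand-aware 5' endpoint matches no
    annotated TSS of its gene within ``boundary_window`` nt; pTES analogously
    for the 3' endpoint. Internal splice sites never affect the flags.
    """
    ann = annotation.genes.get(transcript.gene_id)
    if ann is None or not ann.transcripts:
        logger.warning(
            "gene %s has no annotated transcripts; pTSS/pTES default to true",
            transcript.gene_id,
        )
        return (True, True)
    ptss = all(abs(transcript.tss - t) > boundary_window for t in ann.tss)
    ptes = all(abs(transcript.tes - t) > boundary_window for t in ann.tes)
    return (ptss, ptes)
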