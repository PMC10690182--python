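"""Classify detected elements by evidence source and by novelty taxonomy.

Three nested taxonomies:

* six-way source category of any detected junction/retained intron — which
  subset of {annotation, short reads, long reads} supports it (annotation
  alone means the element was never detected in reads and is excluded);
* de novo junctions split into those using at least one novel splice site
  versus a novel combination of two annotated sites;
* long-read novel-splice-site elements refined into alternative 5'/3' splice
  site, mixed, retained intron or new-exon types;
* novel long-read transcripts placed in a seven-class Venn over
  {novel combination, novel splice site, pTSS/pTES}.
"""

from __future__ import annotations

from typing import Optional

import pandas as pd

from .model import (
    ANNOTATION,
    DenovoClass,
    GeneAnnotation,
    Interval,
    JUNCTION,
    LONG,
    NovelSsType,
    RETAINED_INTRON,
    SHORT,
    SixCategory,
    SpliceGraph,
    SpliceGraphEdge,
    Transcript,
    TranscriptVenn,
    ValidationError,
    donor_acceptor,
)
from .graph import detect_ptss_ptes

_CATEGORY_BY_SUPPORT = {
    frozenset({ANNOTATION, SHORT, LONG}): SixCategory.ALL,
    frozenset({SHORT, LONG}): SixCategory.BOTH_DENOVO,
    frozenset({ANNOTATION, SHORT}): SixCategory.SHORT_ANNOT,
    frozenset({ANNOTATION, LONG}): SixCategory.LONG_ANNOT,
    frozenset({SHORT}): SixCategory.SHORT_ONLY,
    frozenset({LONG}): SixCategory.LONG_ONLY,
    frozenset({ANNOTATION}): SixCategory.NOT_DETECTED,
}


def six_category(edge_or_support) -> SixCategory:
    """Six-way source category of an edge (or raw support set)."""
    support = (
        edge_or_support.support
        if isinstance(edge_or_support, SpliceGraphEdge)
        else edge_or_support
    )
    if not support:
        raise ValidationError("element with empty support set")
    try:
        return _CATEGORY_BY_SUPPORT[frozenset(support)]
    except KeyError:
        raise ValidationError(f"unknown support set {support!r}") from None


def _site_novelty(
    junction: Interval, gene: GeneAnnotation
) -> tuple[bool, bool]:
    """(donor novel, acceptor novel) of a junction against the gene's sites."""
    donor, acceptor = donor_acceptor(junction, gene.strand)
    return donor not in gene.donors, acceptor not in gene.acceptors


def classify_denovo_junction(
    junction: Interval, gene: GeneAnnotation
) -> DenovoClass:
    """NOVEL_COMBINATION iff both splice sites are annotated but the pair is
    not an annotated junction; any novel site makes it NOVEL_SPLICE_SITE."""
    if tuple(junction) in gene.junctions:
        raise ValidationError(
            f"junction {junction} is annotated; not a de novo element"
        )
    donor_novel, acceptor_novel = _site_novelty(junction, gene)
    if not donor_novel and not acceptor_novel:
        return DenovoClass.NOVEL_COMBINATION
    return DenovoClass.NOVEL_SPLICE_SITE


def _exon_boundaries_novel(exon: Interval, gene: GeneAnnotation) -> bool:
    """True iff neither splice site defining the exon is annotated.

    The acceptor creating the exon's left boundary sits at ``start - 1`` (an
    intron end) and the donor at ``end + 1`` (an intron start).
    """
    starts = {s for s, _ in gene.junctions}
    ends = {e for _, e in gene.junctions}
    return (exon[0] - 1) not in ends and (exon[1] + 1) not in starts


def _inside_annotated_intron(exon: Interval, gene: GeneAnnotation) -> bool:
    return any(s <= exon[0] and exon[1] <= e for s, e in gene.junctions)


def classify_novel_ss_type(
    edge: SpliceGraphEdge,
    gene: GeneAnnotation,
    long_transcripts: list[Transcript],
) -> NovelSsType:
    """Refine a long-read novel-splice-site element into its variation type.

    Precedence IR > NEW_EXON > ALT/MIXED: retained-intron edges are IR; a
    junction whose novel boundary belongs to a transcript exon lying wholly
    inside an annotated intron with both boundaries novel is NEW_EXON; else
    the novel side(s) decide ALT_5SS / ALT_3SS / MIXED.
    """
    if edge.kind == RETAINED_INTRON:
        return NovelSsType.IR
    junction = edge.interval
    donor_novel, acceptor_novel = _site_novelty(junction, gene)
    if not donor_novel and not acceptor_novel:
        raise ValidationError(f"junction {junction} has no novel splice site")
    # new-exon geometry: an adjacent exon of a containing transcript sits
    # entirely within an annotated intron with both boundaries unannotated
    for t in long_transcripts:
        if junction not in set(t.junctions()):
            continue
        for exon in t.exons:
            if exon[1] == junction[0] - 1 or exon[0] == junction[1] + 1:
                if _inside_annotated_intron(exon, gene) and _exon_boundaries_novel(
                    exon, gene
                ):
                    return NovelSsType.NEW_EXON
    if donor_novel and acceptor_novel:
        return NovelSsType.MIXED
    return NovelSsType.ALT_5SS if donor_novel else NovelSsType.ALT_3SS


_VENN_BY_FEATURES = {
    frozenset({"novel_combination"}): TranscriptVenn.I,
    frozenset({"novel_splice_site"}): TranscriptVenn.II,
    frozenset({"novel_combination", "novel_splice_site"}): TranscriptVenn.III,
    frozenset({"novel_combination", "ptss_ptes"}): TranscriptVenn.IV,
    frozenset({"novel_splice_site", "ptss_ptes"}): TranscriptVenn.V,
    frozenset(
        {"novel_combination", "novel_splice_site", "ptss_ptes"}
    ): TranscriptVenn.VI,
    frozenset({"ptss_ptes"}): TranscriptVenn.VII,
}


def classify_long_transcript(
    transcript: Transcript,
    gene: GeneAnnotation,
    ptss: bool,
    ptes: bool,
) -> Optional[TranscriptVenn]:
    """Venn class of a long-read transcript, or None if fully annotated.

    Features: contains >=1 novel-combination junction; contains >=1
    novel-splice-site junction; has pTSS or pTES. Class VII (pTSS/pTES only)
    is excluded from short/long comparisons downstream.
    """
    features = set()
    for junction in transcript.junctions():
        if junction in gene.junctions:
            continue
        cls = classify_denovo_junction(junction, gene)
        features.add(
            "novel_combination"
            if cls is DenovoClass.NOVEL_COMBINATION
            else "novel_splice_site"
        )
    if ptss or ptes:
        features.add("ptss_ptes")
    if not features:
        return None
    return _VENN_BY_FEATURES[frozenset(features)]


def classify_graph(
    graph: SpliceGraph,
    gene: Optional[GeneAnnotation],
    boundary_window: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Classify every edge and long transcript of one gene's splice graph.

    Returns ``(elements, transcripts)`` tables. Elements: one row per edge
    with its six-way category and, for de novo elements, the de novo class
    and (long-read elements) the novel-splice-site type. Transcripts: one
    row per long-read transcript with Venn class and pTSS/pTES flags.
    """
    long_transcripts = [t for t in graph.transcripts if t.source == "long_reads"]
    rows = []
    for edge in sorted(graph.edges.values(), key=lambda e: e.key):
        cat = six_category(edge)
        denovo = None
        ss_type = None
        if (
            gene is not None
            and cat is not SixCategory.NOT_DETECTED
            and ANNOTATION not in edge.support
        ):
            if edge.kind == JUNCTION:
                denovo = classify_denovo_junction(edge.interval, gene)
            else:
                denovo = DenovoClass.NOVEL_SPLICE_SITE
            if LONG in edge.support:
                if edge.kind == RETAINED_INTRON:
                    ss_type = NovelSsType.IR
                elif denovo is DenovoClass.NOVEL_SPLICE_SITE:
                    ss_type = classify_novel_ss_type(edge, gene, long_transcripts)
        rows.append(
            {
                "gene_id": graph.gene_id,
                "kind": edge.kind,
                "start": edge.start,
                "end": edge.end,
                "six_category": cat.value,
                "denovo_class": denovo.value if denovo else None,
                "novel_ss_type": ss_type.value if ss_type else None,
                "short_count": edge.short_count,
                "long_count": edge.long_count,
            }
        )
    elements = pd.DataFrame(
        rows,
        columns=[
            "gene_id", "kind", "start", "end", "six_category",
            "denovo_class", "novel_ss_type", "short_count", "long_count",
        ],
    )

    trows = []
    if gene is not None:
        from .model import AnnotationSet  # local to avoid cycle at import time

        for t in long_transcripts:
            # register the gene under the transcript's own gene_id so the
            # lookup works even when gene assignment renamed the gene
            ann_set = AnnotationSet(genes={t.gene_id: gene})
            ptss, ptes = detect_ptss_ptes(t, ann_set, boundary_window)
            venn = classify_long_transcript(t, gene, ptss, ptes)
            trows.append(
                {
                    "gene_id": graph.gene_id,
                    "transcript_id": t.transcript_id,
                    "venn": venn.value if venn else None,
                    "ptss": ptss,
                    "ptes": ptes,
                    "excluded": venn is TranscriptVenn.VII,
                }
            )
    transcripts = pd.DataFrame(
        trows,
        columns=["gene_id", "transcript_id", "venn", "ptss", "ptes", "excluded"],
    )
    return elements, transcripts
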