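"""Core domain types: transcripts, annotation indices, evidence and splice graphs.

All genomic intervals are 1-based inclusive (GTF native). A junction is keyed
by its intronic interval ``[donor_exon.end + 1, acceptor_exon.start - 1]``; a
retained intron uses the same interval convention. The 5' side of a junction
is the donor and the 3' side the acceptor, strand-aware.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Iterable, Optional

ANNOTATION = "annotation"
SHORT = "short"
LONG = "long"
SOURCES = (ANNOTATION, SHORT, LONG)

Interval = tuple[int, int]


class ValidationError(ValueError):
    """An input object violates a structural invariant."""


@dataclass(frozen=True)
class Transcript:
    """One transcript model: an ordered exon chain on a single chromosome/strand.

    ``read_count`` is only present for long-read transcript models (the per
    transcript counts emitted by callers such as FLAIR/ESPRESSO/IsoQuant/Bambu).
    """

    transcript_id: str
    gene_id: str
    chromosome: str
    strand: str
    exons: tuple[Interval, ...]
    read_count: Optional[float] = None
    source: str = ANNOTATION

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValidationError(
                f"transcript {self.transcript_id}: bad strand {self.strand!r}"
            )
        if not self.exons:
            raise ValidationError(f"transcript {self.transcript_id}: no exons")
        for start, end in self.exons:
            if start > end:
                raise ValidationError(
                    f"transcript {self.transcript_id}: exon {start}-{end} inverted"
                )
        for (s1, e1), (s2, e2) in zip(self.exons, self.exons[1:]):
            if e1 >= s2 - 1:
                raise ValidationError(
                    f"transcript {self.transcript_id}: exons {e1} / {s2} overlap "
                    "or leave a zero-length intron"
                )
        if self.read_count is not None and self.read_count < 0:
            raise ValidationError(
                f"transcript {self.transcript_id}: negative read count"
            )
        if self.source not in (ANNOTATION, "long_reads"):
            raise ValidationError(f"unknown transcript source {self.source!r}")

    @property
    def start(self) -> int:
        return self.exons[0][0]

    @property
    def end(self) -> int:
        return self.exons[-1][1]

    @property
    def tss(self) -> int:
        """Transcription start position (strand-aware)."""
        return self.start if self.strand == "+" else self.end

    @property
    def tes(self) -> int:
        """Transcription end position (strand-aware)."""
        return self.end if self.strand == "+" else self.start

    def junctions(self) -> list[Interval]:
        """Intron intervals between consecutive exons (empty for single-exon)."""
        return [
            (e1 + 1, s2 - 1) for (_, e1), (s2, _) in zip(self.exons, self.exons[1:])
        ]


def donor_acceptor(junction: Interval, strand: str) -> tuple[int, int]:
    """Return (donor, acceptor) intron-boundary coordinates of a junction."""
    start, end = junction
    return (start, end) if strand == "+" else (end, start)


@dataclass
class GeneAnnotation:
    """Annotated transcripts of one gene plus derived splice-site indices."""

    gene_id: str
    chromosome: str
    strand: str
    transcripts: list[Transcript]
    donors: frozenset[int] = field(default_factory=frozenset)
    acceptors: frozenset[int] = field(default_factory=frozenset)
    junctions: frozenset[Interval] = field(default_factory=frozenset)
    tss: frozenset[int] = field(default_factory=frozenset)
    tes: frozenset[int] = field(default_factory=frozenset)

    @classmethod
    def from_transcripts(
        cls, gene_id: str, transcripts: Iterable[Transcript]
    ) -> "GeneAnnotation":
        transcripts = sorted(transcripts, key=lambda t: (t.start, t.end, t.transcript_id))
        if not transcripts:
            raise ValidationError(f"gene {gene_id}: no transcripts")
        chroms = {t.chromosome for t in transcripts}
        strands = {t.strand for t in transcripts}
        if len(chroms) > 1 or len(strands) > 1:
            raise ValidationError(
                f"gene {gene_id}: transcripts on mixed chromosomes/strands"
            )
        strand = transcripts[0].strand
        donors: set[int] = set()
        acceptors: set[int] = set()
        junctions: set[Interval] = set()
        for t in transcripts:
            for j in t.junctions():
                junctions.add(j)
                d, a = donor_acceptor(j, strand)
                donors.add(d)
                acceptors.add(a)
        return cls(
            gene_id=gene_id,
            chromosome=transcripts[0].chromosome,
            strand=strand,
            transcripts=transcripts,
            donors=frozenset(donors),
            acceptors=frozenset(acceptors),
            junctions=frozenset(junctions),
            tss=frozenset(t.tss for t in transcripts),
            tes=frozenset(t.tes for t in transcripts),
        )

    @property
    def span(self) -> Interval:
        return (
            min(t.start for t in self.transcripts),
            max(t.end for t in self.transcripts),
        )

    def exon_intervals(self) -> list[Interval]:
        return merge_intervals(
            iv for t in self.transcripts for iv in t.exons
        )


@dataclass
class AnnotationSet:
    """All annotated genes, keyed by gene_id."""

    genes: dict[str, GeneAnnotation] = field(default_factory=dict)

    @classmethod
    def from_transcripts(cls, transcripts: Iterable[Transcript]) -> "AnnotationSet":
        by_gene: dict[str, list[Transcript]] = {}
        for t in transcripts:
            by_gene.setdefault(t.gene_id, []).append(t)
        return cls(
            genes={
                g: GeneAnnotation.from_transcripts(g, ts)
                for g, ts in sorted(by_gene.items())
            }
        )


JunctionKey = tuple[str, str, int, int]  # chromosome, strand, start, end


@dataclass
class ShortReadEvidence:
    """Per-sample short-read junction and intron-retention unique-read counts.

    Junction keys use 1-based intron coordinates; strand may be ``"."`` for
    undetermined-strand rows, resolved against gene models at graph build.
    """

    sample: str = "sample"
    junctions: dict[JunctionKey, int] = field(default_factory=dict)
    introns: dict[JunctionKey, int] = field(default_factory=dict)

    def validate(self) -> None:
        for table, label in ((self.junctions, "junction"), (self.introns, "intron")):
            for (chrom, strand, start, end), count in table.items():
                if start > end:
                    raise ValidationError(
                        f"{label} ({chrom},{strand},{start},{end}): start > end"
                    )
                if count < 0 or int(count) != count:
                    raise ValidationError(
                        f"{label} ({chrom},{strand},{start},{end}): bad count {count}"
                    )


JUNCTION = "junction"
RETAINED_INTRON = "retained_intron"

EdgeKey = tuple[str, int, int]  # kind, start, end


@dataclass
class SpliceGraphEdge:
    """A junction or retained-intron edge with tri-source support and counts."""

    kind: str
    start: int
    end: int
    support: set[str] = field(default_factory=set)
    short_count: int = 0
    long_count: float = 0.0

    @property
    def interval(self) -> Interval:
        return (self.start, self.end)

    @property
    def key(self) -> EdgeKey:
        return (self.kind, self.start, self.end)

    def validate(self) -> None:
        if self.kind not in (JUNCTION, RETAINED_INTRON):
            raise ValidationError(f"bad edge kind {self.kind!r}")
        if not self.support:
            raise ValidationError(f"edge {self.key}: empty support")
        if not self.support <= set(SOURCES):
            raise ValidationError(f"edge {self.key}: unknown support {self.support}")
        if self.end < self.start:
            raise ValidationError(f"edge {self.key}: interval length < 1")
        if self.short_count > 0 and SHORT not in self.support:
            raise ValidationError(f"edge {self.key}: short count without support")
        if self.long_count > 0 and LONG not in self.support:
            raise ValidationError(f"edge {self.key}: long count without support")


@dataclass
class SpliceGraph:
    """Per-gene unified splice graph over annotation, short and long evidence."""

    gene_id: str
    chromosome: str
    strand: str
    exons: list[Interval]
    edges: dict[EdgeKey, SpliceGraphEdge]
    transcripts: list[Transcript]
    tss: dict[str, set[int]] = field(default_factory=dict)
    tes: dict[str, set[int]] = field(default_factory=dict)

    def junction_edges(self) -> list[SpliceGraphEdge]:
        return [e for e in self.edges.values() if e.kind == JUNCTION]

    def intron_edges(self) -> list[SpliceGraphEdge]:
        return [e for e in self.edges.values() if e.kind == RETAINED_INTRON]

    def exon_at(self, position: int) -> Optional[Interval]:
        """The merged exon containing ``position``, if any."""
        for start, end in self.exons:
            if start <= position <= end:
                return (start, end)
        return None

    def validate(self) -> None:
        for (s1, e1), (s2, e2) in zip(self.exons, self.exons[1:]):
            if s2 <= e1:
                raise ValidationError(
                    f"gene {self.gene_id}: merged exons overlap at {e1}/{s2}"
                )
        for edge in self.edges.values():
            edge.validate()
            # Edge endpoints must abut exonic positions: the last exonic base
            # before the intron and the first after it both lie in some exon.
            if self.exon_at(edge.start - 1) is None or self.exon_at(edge.end + 1) is None:
                raise ValidationError(
                    f"gene {self.gene_id}: edge {edge.key} endpoints not anchored "
                    "to any exon"
                )
            # DAG under genomic order: every edge runs strictly left to right
            # between distinct exonic positions, so cycles are impossible.
            if edge.start > edge.end:
                raise ValidationError(f"gene {self.gene_id}: inverted edge {edge.key}")


def merge_intervals(intervals: Iterable[Interval]) -> list[Interval]:
    """Merge overlapping or book-ended 1-based inclusive intervals."""
    ivs = sorted(intervals)
    merged: list[Interval] = []
    for start, end in ivs:
        if merged and start <= merged[-1][1] + 1:
            merged[-1] = (merged[-1][0], max(merged[-1][1], end))
        else:
            merged.append((start, end))
    return merged


class SixCategory(enum.Enum):
    """Which subset of {annotation, short, long} supports a detected element."""

    ALL = "ALL"
    BOTH_DENOVO = "BOTH_DENOVO"
    SHORT_ANNOT = "SHORT_ANNOT"
    LONG_ANNOT = "LONG_ANNOT"
    SHORT_ONLY = "SHORT_ONLY"
    LONG_ONLY = "LONG_ONLY"
    NOT_DETECTED = "NOT_DETECTED"


class DenovoClass(enum.Enum):
    NOVEL_SPLICE_SITE = "NOVEL_SPLICE_SITE"
    NOVEL_COMBINATION = "NOVEL_COMBINATION"


class NovelSsType(enum.Enum):
    ALT_5SS = "ALT_5SS"
    ALT_3SS = "ALT_3SS"
    MIXED = "MIXED"
    IR = "IR"
    NEW_EXON = "NEW_EXON"


class TranscriptVenn(enum.Enum):
    """Roman-numeral classes of novel long-read transcripts.

    Classes are the non-empty subsets of {novel combination junction, novel
    splice-site junction, pTSS/pTES}; VII (pTSS/pTES only) is excluded from
    short/long comparisons because short-read callers do not report TSS/TES.
    """

    I = "I"      # novel combination only
    II = "II"    # novel splice site only
    III = "III"  # novel combination + novel splice site
    IV = "IV"    # novel combination + pTSS/pTES
    V = "V"      # novel splice site + pTSS/pTES
    VI = "VI"    # all three
    VII = "VII"  # pTSS/pTES only (excluded from comparison)
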