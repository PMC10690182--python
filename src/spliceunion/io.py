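"""Readers and writers for the external formats the pipeline touches.

Formats: GTF (GENCODE dialect, exon features) for annotation and long-read
transcript models, STAR ``SJ.out.tab`` for short-read junction counts, a
5-column TSV for short-read intron-retention counts, a 2-column sidecar TSV
for long-read transcript counts, and TSV/JSON outputs. Every in-memory
coordinate is 1-based inclusive (GTF native); STAR intron coordinates are
already 1-based so no shift is applied.
"""

from __future__ import annotations

import json
import logging
import os
from typing import Iterable, Optional, Union

import pandas as pd
import pyranges as pr

from .model import (
    ANNOTATION,
    AnnotationSet,
    JUNCTION,
    RETAINED_INTRON,
    ShortReadEvidence,
    SpliceGraph,
    SpliceGraphEdge,
    Transcript,
    ValidationError,
)

logger = logging.getLogger(__name__)

PathLike = Union[str, os.PathLike]


class FormatError(ValueError):
    """A file does not conform to its declared dialect."""


# ---------------------------------------------------------------------------
# GTF
# ---------------------------------------------------------------------------

def _exon_frame(path: PathLike) -> pd.DataFrame:
    """Exon features of a GTF as a DataFrame with 1-based inclusive Start."""
    if os.path.getsize(path) == 0 or _no_feature_lines(path):
        return pd.DataFrame(
            columns=["Chromosome", "Strand", "Start", "End", "gene_id", "transcript_id"]
        )
    df = pr.read_gtf(path, as_df=True)
    df = df[df["Feature"] == "exon"].copy()
    for attr in ("gene_id", "transcript_id"):
        if attr not in df.columns or df[attr].isna().any():
            bad = 0 if attr not in df.columns else int(df.index[df[attr].isna()][0])
            raise FormatError(
                f"{path}: exon feature missing {attr} attribute "
                f"(first offending feature line index {bad})"
            )
    df["Start"] = df["Start"].astype(int) + 1  # pyranges is 0-based half-open
    df["End"] = df["End"].astype(int)
    return df


def _no_feature_lines(path: PathLike) -> bool:
    with open(path) as fh:
        return not any(line.strip() and not line.startswith("#") for line in fh)


def _group_transcripts(
    df: pd.DataFrame,
    source: str,
    counts: Optional[dict[str, float]] = None,
) -> list[Transcript]:
    transcripts = []
    for tid, sub in df.groupby("transcript_id", sort=True):
        chroms = sub["Chromosome"].unique()
        strands = sub["Strand"].unique()
        if len(chroms) > 1 or len(strands) > 1:
            raise ValidationError(
                f"transcript {tid}: exons on mixed chromosomes/strands"
            )
        exons = tuple(
            sorted((int(s), int(e)) for s, e in zip(sub["Start"], sub["End"]))
        )
        transcripts.append(
            Transcript(
                transcript_id=str(tid),
                gene_id=str(sub["gene_id"].iloc[0]),
                chromosome=str(chroms[0]),
                strand=str(strands[0]),
                exons=exons,
                read_count=None if counts is None else counts.get(str(tid), 0.0),
                source=source,
            )
        )
    return transcripts


def read_annotation_gtf(path: PathLike) -> AnnotationSet:
    """Read a reference annotation GTF into an :class:`AnnotationSet`.

    Builds per-gene splice-site, junction and TSS/TES indices. Only ``exon``
    features are required; coordinates stay 1-based inclusive.
    """
    df = _exon_frame(path)
    if df.empty:
        logger.warning("annotation %s contains no exon features", path)
        return AnnotationSet()
    return AnnotationSet.from_transcripts(_group_transcripts(df, ANNOTATION))


def read_long_read_gtf(
    path: PathLike,
    counts: Optional[PathLike] = None,
    min_count: float = 1.0,
    count_attribute: str = "read_count",
) -> list[Transcript]:
    """Read long-read transcript models, applying the read-count filter.

    Counts come either from a numeric transcript attribute (``count_attribute``,
    default ``read_count``) or from a 2-column sidecar TSV (transcript_id,
    count). Transcripts with count < ``min_count`` are dropped (default 1.0,
    the recommended filter for callers that echo unexpressed reference
    transcripts); a transcript absent from the counts table is treated as
    count 0 and filtered with a warning.
    """
    df = _exon_frame(path)
    if df.empty:
        logger.warning("long-read GTF %s contains no exon features", path)
        return []
    count_map: dict[str, float] = {}
    if counts is not None:
        side = pd.read_csv(
            counts, sep="\t", header=None, names=["transcript_id", "count"],
            comment="#",
        )
        count_map = {
            str(t): float(c) for t, c in zip(side["transcript_id"], side["count"])
        }
    elif count_attribute in df.columns:
        for tid, sub in df.groupby("transcript_id", sort=True):
            val = sub[count_attribute].iloc[0]
            count_map[str(tid)] = 0.0 if pd.isna(val) else float(val)
    transcripts = _group_transcripts(df, "long_reads", counts=count_map)
    kept = []
    for t in transcripts:
        if t.read_count is None or (counts is not None and t.transcript_id not in count_map):
            logger.warning(
                "transcript %s has no read count; treated as 0 and filtered",
                t.transcript_id,
            )
            continue
        if t.read_count < min_count:
            continue
        kept.append(t)
    logger.info(
        "long-read GTF %s: kept %d of %d transcripts (min_count=%g)",
        path, len(kept), len(transcripts), min_count,
    )
    return kept


def write_gtf(transcripts: Iterable[Transcript], path: PathLike) -> None:
    """Write transcripts as exon features in GENCODE-dialect GTF."""
    with open(path, "w") as fh:
        for t in transcripts:
            for start, end in t.exons:
                attrs = f'gene_id "{t.gene_id}"; transcript_id "{t.transcript_id}";'
                if t.read_count is not None:
                    attrs += f' read_count "{t.read_count:g}";'
                fh.write(
                    f"{t.chromosome}\tspliceunion\texon\t{start}\t{end}\t.\t"
                    f"{t.strand}\t.\t{attrs}\n"
                )


# ---------------------------------------------------------------------------
# STAR SJ.out.tab and the IR table
# ---------------------------------------------------------------------------

_SJ_STRAND = {0: ".", 1: "+", 2: "-"}


def read_star_sj(path: PathLike, sample: Optional[str] = None) -> ShortReadEvidence:
    """Read a STAR ``SJ.out.tab`` into junction evidence.

    Columns: chrom, intron start, intron end (both 1-based), strand code
    (0 undetermined / 1 ``+`` / 2 ``-``), motif, annotated flag, unique reads,
    multi-mapping reads, max overhang. Only the unique-read column is used;
    multi-mapping reads are ignored as unreliable junction evidence.
    """
    evidence = ShortReadEvidence(sample=sample or os.path.basename(str(path)))
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            fields = line.split()
            if len(fields) != 9:
                raise FormatError(
                    f"{path}:{lineno}: expected 9 columns, found {len(fields)}"
                )
            chrom = fields[0]
            start, end = int(fields[1]), int(fields[2])
            strand = _SJ_STRAND.get(int(fields[3]))
            if strand is None:
                raise FormatError(f"{path}:{lineno}: bad strand code {fields[3]}")
            unique = int(fields[6])
            if unique < 0:
                raise ValidationError(f"{path}:{lineno}: negative unique-read count")
            key = (chrom, strand, start, end)
            if key in evidence.junctions:
                raise ValidationError(f"{path}:{lineno}: duplicate junction {key}")
            evidence.junctions[key] = unique
    evidence.validate()
    return evidence


def read_ir_table(
    path: PathLike, evidence: Optional[ShortReadEvidence] = None
) -> ShortReadEvidence:
    """Read the 5-column intron-retention TSV (chrom, strand, start, end, reads).

    Returns ``evidence`` with its intron table filled (a fresh
    :class:`ShortReadEvidence` if none is given).
    """
    evidence = evidence or ShortReadEvidence(sample=os.path.basename(str(path)))
    df = pd.read_csv(
        path, sep="\t", comment="#", header=None,
        names=["chromosome", "strand", "intron_start", "intron_end", "supporting_reads"],
        skiprows=_header_rows(path),
    )
    for row in df.itertuples(index=False):
        if row.intron_start > row.intron_end:
            raise ValidationError(
                f"{path}: intron {row.intron_start}-{row.intron_end} inverted"
            )
        key = (str(row.chromosome), str(row.strand), int(row.intron_start), int(row.intron_end))
        if key in evidence.introns:
            raise ValidationError(f"{path}: duplicate intron {key}")
        evidence.introns[key] = int(row.supporting_reads)
    evidence.validate()
    return evidence


def _header_rows(path: PathLike) -> int:
    with open(path) as fh:
        first = fh.readline()
    return 1 if first.startswith("chromosome") else 0


# ---------------------------------------------------------------------------
# Tables and the splice-graph JSON document
# ---------------------------------------------------------------------------

def write_tables(results: pd.DataFrame, path: PathLike) -> None:
    """Write a reporting table as TSV: header always present, deterministic
    column order (as given), floats at 6 significant digits."""
    results.to_csv(path, sep="\t", index=False, float_format="%.6g")


def splice_graph_to_dict(graph: SpliceGraph) -> dict:
    return {
        "gene_id": graph.gene_id,
        "chromosome": graph.chromosome,
        "strand": graph.strand,
        "exons": [list(iv) for iv in graph.exons],
        "edges": [
            {
                "kind": e.kind,
                "start": e.start,
                "end": e.end,
                "support": sorted(e.support),
                "short_count": e.short_count,
                "long_count": e.long_count,
            }
            for e in sorted(graph.edges.values(), key=lambda e: e.key)
        ],
        "transcripts": [
            {
                "transcript_id": t.transcript_id,
                "source": t.source,
                "exons": [list(iv) for iv in t.exons],
                "read_count": t.read_count,
            }
            for t in graph.transcripts
        ],
        "tss": {src: sorted(v) for src, v in sorted(graph.tss.items())},
        "tes": {src: sorted(v) for src, v in sorted(graph.tes.items())},
    }


def write_splice_graph_json(graph: SpliceGraph, path: PathLike) -> None:
    with open(path, "w") as fh:
        json.dump(splice_graph_to_dict(graph), fh, indent=1, sort_keys=True)
        fh.write("\n")


def read_splice_graph_json(path: PathLike) -> SpliceGraph:
    with open(path) as fh:
        doc = json.load(fh)
    edges = {}
    for ed in doc["edges"]:
        edge = SpliceGraphEdge(
            kind=ed["kind"],
            start=ed["start"],
            end=ed["end"],
            support=set(ed["support"]),
            short_count=ed["short_count"],
            long_count=ed["long_count"],
        )
        edges[edge.key] = edge
    transcripts = [
        Transcript(
            transcript_id=td["transcript_id"],
            gene_id=doc["gene_id"],
            chromosome=doc["chromosome"],
            strand=doc["strand"],
            exons=tuple(tuple(iv) for iv in td["exons"]),
            read_count=td["read_count"],
            source=td["source"],
        )
        for td in doc["transcripts"]
    ]
    return SpliceGraph(
        gene_id=doc["gene_id"],
        chromosome=doc["chromosome"],
        strand=doc["strand"],
        exons=[tuple(iv) for iv in doc["exons"]],
        edges=edges,
        transcripts=transcripts,
        tss={src: set(v) for src, v in doc["tss"].items()},
        tes={src: set(v) for src, v in doc["tes"].items()},
    )
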