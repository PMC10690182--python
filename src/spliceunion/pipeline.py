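"""End-to-end orchestration: build -> classify -> LSV -> quantify -> report.

Genes are processed independently (streaming per gene); every output is a
deterministic function of the inputs and configuration, so reruns are
byte-identical.
"""

from __future__ import annotations

import json
import logging
import os
from dataclasses import asdict, dataclass, field
from typing import Iterable, Optional, Sequence

import pandas as pd

from . import __version__
from .classify import classify_graph
from .fuzzy import fuzzy_match
from .graph import assign_long_transcripts, build_splice_graph
from .io import write_splice_graph_json, write_tables
from .model import AnnotationSet, JUNCTION, ShortReadEvidence, SpliceGraph, Transcript
from .model import LONG, SHORT
from .quantify import Lsv, define_lsvs, is_quantifiable, psi_posterior
from .report import (
    DISTANCE_BINS,
    READ_BINS,
    category_counts,
    detection_vs_coverage,
    detection_vs_psi,
    ir_comparison,
    junction_table,
    lsv_table,
    missed_fraction,
    nonquantifiable_fractions,
    read_length_distribution,
)

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Thresholds and bin edges for a comparison run (printed defaults)."""

    short_min_reads: int = 2
    long_min_count: float = 1.0
    lsv_min_reads: int = 10
    fuzzy_windows: tuple[int, ...] = (3, 4, 5, 6, 7, 8)
    coverage_bins: tuple[float, ...] = READ_BINS
    distance_bins: tuple[float, ...] = DISTANCE_BINS
    boundary_window: int = 0
    psi_bin_width: float = 0.05
    read_length_thresholds: tuple[float, ...] = (3000,)
    write_graph_json: bool = False

    def validate(self) -> None:
        if min(self.short_min_reads, self.lsv_min_reads, self.boundary_window) < 0:
            raise ValueError("thresholds must be >= 0")
        if list(self.fuzzy_windows) != sorted(self.fuzzy_windows):
            raise ValueError("fuzzy windows must be sorted ascending")


@dataclass
class CompareResult:
    """All per-replicate graphs, LSVs and reporting tables of one run."""

    graphs: list[dict[str, SpliceGraph]]      # one dict per replicate
    lsvs: list[dict[str, list[Lsv]]]
    tables: dict[str, pd.DataFrame] = field(default_factory=dict)
    manifest: dict = field(default_factory=dict)


def build_all_graphs(
    annotation: AnnotationSet,
    short: Optional[ShortReadEvidence],
    long_transcripts: Sequence[Transcript],
    short_min_reads: int = 2,
) -> dict[str, SpliceGraph]:
    """Unified splice graph per gene over the union of all sources' genes."""
    assigned = assign_long_transcripts(long_transcripts, annotation)
    genes = sorted(set(annotation.genes) | set(assigned))
    graphs: dict[str, SpliceGraph] = {}
    for gene_id in genes:
        graphs[gene_id] = build_splice_graph(
            gene_id,
            annotation,
            short,
            assigned.get(gene_id, []),
            short_min_reads=short_min_reads,
        )
    return graphs


def fuzzy_sweep_table(
    graphs: Iterable[SpliceGraph], windows: Sequence[int]
) -> pd.DataFrame:
    """Aggregate per-window six-category junction counts over all genes."""
    frames = []
    graphs = list(graphs)
    for window in windows:
        counts_before: dict[str, int] = {}
        counts_after: dict[str, int] = {}
        n_reassigned = 0
        for g in graphs:
            res = fuzzy_match(g, window)
            for cat, n in res.counts_before.items():
                counts_before[cat] = counts_before.get(cat, 0) + n
            for cat, n in res.counts_after.items():
                counts_after[cat] = counts_after.get(cat, 0) + n
            n_reassigned += len(res.reassigned)
        cats = sorted(set(counts_before) | set(counts_after))
        frames.append(
            pd.DataFrame(
                {
                    "window": window,
                    "category": cats,
                    "count_before": [counts_before.get(c, 0) for c in cats],
                    "count_after": [counts_after.get(c, 0) for c in cats],
                    "n_reassigned": n_reassigned,
                }
            )
        )
    return pd.concat(frames, ignore_index=True)


def lsv_psi_table(
    lsvs_by_gene: dict[str, list[Lsv]], min_reads: int = 10
) -> pd.DataFrame:
    """Per-element LSV table with counts and posterior means for both sources."""
    rows = []
    for gene_id in sorted(lsvs_by_gene):
        for lsv in lsvs_by_gene[gene_id]:
            post = {src: psi_posterior(lsv.counts(src)) for src in (SHORT, LONG)}
            for idx, element in enumerate(lsv.elements):
                rows.append(
                    {
                        "gene_id": gene_id,
                        "lsv_id": lsv.lsv_id,
                        "direction": lsv.direction,
                        "J": lsv.J,
                        "kind": element.kind,
                        "start": element.start,
                        "end": element.end,
                        "short_count": element.short_count,
                        "long_count": element.long_count,
                        "psi_short": float(post[SHORT].means[idx]),
                        "psi_long": float(post[LONG].means[idx]),
                        "alpha_long": float(post[LONG].alpha[idx]),
                        "beta_long": float(post[LONG].beta[idx]),
                        "quantifiable_short": is_quantifiable(lsv, SHORT, min_reads),
                        "quantifiable_long": is_quantifiable(lsv, LONG, min_reads),
                    }
                )
    return pd.DataFrame(
        rows,
        columns=[
            "gene_id", "lsv_id", "direction", "J", "kind", "start", "end",
            "short_count", "long_count", "psi_short", "psi_long",
            "alpha_long", "beta_long", "quantifiable_short", "quantifiable_long",
        ],
    )


def run_compare(
    annotation: AnnotationSet,
    short_replicates: Sequence[ShortReadEvidence],
    long_transcripts: Sequence[Transcript],
    config: Optional[RunConfig] = None,
    read_lengths: Optional[Sequence[float]] = None,
    out_dir: Optional[str] = None,
) -> CompareResult:
    """Run the full comparison and optionally write every report table."""
    config = config or RunConfig()
    config.validate()
    if not short_replicates:
        short_replicates = [ShortReadEvidence(sample="empty")]

    rep_graphs: list[dict[str, SpliceGraph]] = []
    rep_lsvs: list[dict[str, list[Lsv]]] = []
    for evidence in short_replicates:
        graphs = build_all_graphs(
            annotation, evidence, long_transcripts, config.short_min_reads
        )
        rep_graphs.append(graphs)
        rep_lsvs.append({g: define_lsvs(graph) for g, graph in graphs.items()})

    # classification on the first replicate (element tables are per dataset)
    graphs0 = rep_graphs[0]
    lsvs0 = rep_lsvs[0]
    elements_frames = []
    transcripts_frames = []
    for gene_id in sorted(graphs0):
        gene = annotation.genes.get(gene_id)
        el, tr = classify_graph(graphs0[gene_id], gene, config.boundary_window)
        elements_frames.append(el)
        transcripts_frames.append(tr)
    elements = pd.concat(elements_frames, ignore_index=True)
    transcripts = pd.concat(transcripts_frames, ignore_index=True)

    graphs_list = [list(g.values()) for g in rep_graphs]
    tables: dict[str, pd.DataFrame] = {
        "elements": elements,
        "transcripts": transcripts,
        "category_counts_junctions": category_counts(graphs_list, JUNCTION),
        "category_counts_introns": category_counts(graphs_list, "retained_intron"),
    }

    junctions = junction_table(graphs0.values(), lsvs0, config.lsv_min_reads)
    tables["junctions"] = junctions
    tables["detection_vs_psi"] = detection_vs_psi(junctions, config.psi_bin_width)
    tables["detection_vs_coverage"] = detection_vs_coverage(junctions)
    lsvs_df = lsv_table(graphs0.values(), lsvs0, config.lsv_min_reads)
    tables["lsvs"] = lsvs_df
    tables["lsv_psi"] = lsv_psi_table(lsvs0, config.lsv_min_reads)
    tables["nonquantifiable_by_coverage"] = nonquantifiable_fractions(
        lsvs_df, "coverage", config.coverage_bins
    )
    tables["nonquantifiable_by_distance"] = nonquantifiable_fractions(
        lsvs_df, "distance3p", config.distance_bins
    )
    tables["fuzzy_sweep"] = fuzzy_sweep_table(
        graphs0.values(), config.fuzzy_windows
    )
    ir = ir_comparison(graphs0.values(), lsvs0, config.lsv_min_reads)
    tables["ir_counts"] = ir["counts"]
    tables["ir_lengths"] = ir["lengths"]
    tables["ir_detection"] = ir["detection"]
    tables["ir_events"] = ir["events"]
    if read_lengths is not None:
        rl = read_length_distribution(read_lengths, config.read_length_thresholds)
        tables["read_length_fractions"] = rl["fractions"]

    manifest = {
        "version": __version__,
        "config": {
            k: (list(v) if isinstance(v, tuple) else v)
            for k, v in asdict(config).items()
        },
        "n_replicates": len(short_replicates),
        "stage_counts": {
            "genes": len(graphs0),
            "edges": int(sum(len(g.edges) for g in graphs0.values())),
            "detected_elements": int(
                (elements["six_category"] != "NOT_DETECTED").sum()
            ),
            "long_transcripts": len(long_transcripts),
            "lsvs": int(sum(len(v) for v in lsvs0.values())),
        },
    }
    result = CompareResult(
        graphs=rep_graphs, lsvs=rep_lsvs, tables=tables, manifest=manifest
    )
    if out_dir is not None:
        write_outputs(result, out_dir, config)
    return result


def write_outputs(result: CompareResult, out_dir: str, config: RunConfig) -> None:
    os.makedirs(out_dir, exist_ok=True)
    for name, table in sorted(result.tables.items()):
        write_tables(table, os.path.join(out_dir, f"{name}.tsv"))
    if config.write_graph_json:
        graph_dir = os.path.join(out_dir, "splicegraphs")
        os.makedirs(graph_dir, exist_ok=True)
        for gene_id, graph in sorted(result.graphs[0].items()):
            write_splice_graph_json(
                graph, os.path.join(graph_dir, f"{gene_id}.json")
            )
    with open(os.path.join(out_dir, "manifest.json"), "w") as fh:
        json.dump(result.manifest, fh, indent=1, sort_keys=True)
        fh.write("\n")
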