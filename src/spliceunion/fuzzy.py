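"""Fuzzy re-matching of long-read splice sites to short-read/annotated sites.

Splice sites reported only by long reads are matched, per site and greedily
nearest-first, against short-read sites within a +/- window, falling back to
annotated sites when no short-read site is close enough. Matched long-read
sites snap to the target coordinate and the six-way categories are
recomputed on the snapped intervals. Each original edge keeps its identity
(the total element count is conserved at every window); `apply_fuzzy`
additionally produces the physically merged graph.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import pandas as pd

from .model import (
    ANNOTATION,
    EdgeKey,
    JUNCTION,
    LONG,
    SHORT,
    SixCategory,
    SpliceGraph,
    SpliceGraphEdge,
    ValidationError,
)
from .classify import six_category


@dataclass
class FuzzyMatchResult:
    """Category counts before/after matching at one window size."""

    window: int
    counts_before: dict[str, int]
    counts_after: dict[str, int]
    reassigned: list[dict] = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        cats = [c.value for c in SixCategory]
        return pd.DataFrame(
            {
                "window": self.window,
                "category": cats,
                "count_before": [self.counts_before.get(c, 0) for c in cats],
                "count_after": [self.counts_after.get(c, 0) for c in cats],
            }
        )


def _site_sets(graph: SpliceGraph, side: int) -> tuple[set[int], set[int]]:
    """(short-supported, annotated) coordinates of junction side 0/1."""
    short_sites: set[int] = set()
    annot_sites: set[int] = set()
    for e in graph.junction_edges():
        coord = e.interval[side]
        if SHORT in e.support:
            short_sites.add(coord)
        if ANNOTATION in e.support:
            annot_sites.add(coord)
    return short_sites, annot_sites


def _snap(coord: int, targets: set[int], window: int) -> Optional[int]:
    """Nearest target within the window; ties go to the smaller coordinate."""
    best: Optional[int] = None
    for t in sorted(targets):
        if abs(t - coord) <= window and (
            best is None or abs(t - coord) < abs(best - coord)
        ):
            best = t
    return best


def _snap_maps(graph: SpliceGraph, window: int) -> list[dict[int, int]]:
    """Per-side mapping long-read-only coordinate -> snapped coordinate."""
    maps: list[dict[int, int]] = []
    for side in (0, 1):
        short_sites, annot_sites = _site_sets(graph, side)
        known = short_sites | annot_sites
        mapping: dict[int, int] = {}
        for e in graph.junction_edges():
            if LONG not in e.support:
                continue
            coord = e.interval[side]
            if coord in known:
                continue
            target = _snap(coord, short_sites, window)
            if target is None:
                target = _snap(coord, annot_sites, window)
            if target is not None:
                mapping[coord] = target
        maps.append(mapping)
    return maps


def _effective_intervals(
    graph: SpliceGraph, window: int
) -> dict[EdgeKey, tuple[int, int]]:
    """Snapped interval of every edge (non-junction / non-long unchanged)."""
    maps = _snap_maps(graph, window)
    out: dict[EdgeKey, tuple[int, int]] = {}
    for e in graph.edges.values():
        if e.kind == JUNCTION and LONG in e.support:
            out[e.key] = (
                maps[0].get(e.start, e.start),
                maps[1].get(e.end, e.end),
            )
        else:
            out[e.key] = e.interval
    return out


def fuzzy_match(graph: SpliceGraph, window: int) -> FuzzyMatchResult:
    """Recompute six-way junction categories after fuzzy site matching.

    Every original edge keeps its identity; edges sharing a snapped interval
    pool their support sets, so a matched long-read-only junction and its
    target both move to the union category.
    """
    if window < 0:
        raise ValidationError("fuzzy window must be >= 0")
    effective = _effective_intervals(graph, window)
    junctions = graph.junction_edges()

    support_by_interval: dict[tuple[int, int], set[str]] = {}
    for e in junctions:
        support_by_interval.setdefault(effective[e.key], set()).update(e.support)

    counts_before: dict[str, int] = {}
    counts_after: dict[str, int] = {}
    reassigned = []
    for e in sorted(junctions, key=lambda e: e.key):
        old = six_category(e).value
        new = six_category(support_by_interval[effective[e.key]]).value
        counts_before[old] = counts_before.get(old, 0) + 1
        counts_after[new] = counts_after.get(new, 0) + 1
        if old != new:
            shift = max(
                abs(effective[e.key][0] - e.start),
                abs(effective[e.key][1] - e.end),
            )
            reassigned.append(
                {
                    "kind": e.kind,
                    "start": e.start,
                    "end": e.end,
                    "new_start": effective[e.key][0],
                    "new_end": effective[e.key][1],
                    "old_category": old,
                    "new_category": new,
                    "shift": shift,
                }
            )
    return FuzzyMatchResult(
        window=window,
        counts_before=counts_before,
        counts_after=counts_after,
        reassigned=reassigned,
    )


def fuzzy_sweep(graph: SpliceGraph, windows: list[int]) -> list[FuzzyMatchResult]:
    """Independent (non-cumulative) fuzzy matching at each window size."""
    if sorted(windows) != list(windows):
        raise ValidationError("windows must be sorted ascending")
    return [fuzzy_match(graph, w) for w in windows]


def apply_fuzzy(graph: SpliceGraph, window: int) -> SpliceGraph:
    """Return a new graph with snapped long-read junctions physically merged.

    Edges whose snapped intervals collide merge into one edge with unioned
    support and summed counts. Matching again at the same window is then a
    no-op (idempotence).
    """
    effective = _effective_intervals(graph, window)
    edges: dict[EdgeKey, SpliceGraphEdge] = {}
    for e in sorted(graph.edges.values(), key=lambda e: e.key):
        start, end = effective[e.key]
        key = (e.kind, start, end)
        if key not in edges:
            edges[key] = SpliceGraphEdge(kind=e.kind, start=start, end=end)
        merged = edges[key]
        merged.support.update(e.support)
        merged.short_count += e.short_count
        merged.long_count += e.long_count
    out = SpliceGraph(
        gene_id=graph.gene_id,
        chromosome=graph.chromosome,
        strand=graph.strand,
        exons=list(graph.exons),
        edges=dict(sorted(edges.items())),
        transcripts=list(graph.transcripts),
        tss={k: set(v) for k, v in graph.tss.items()},
        tes={k: set(v) for k, v in graph.tes.items()},
    )
    return out
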