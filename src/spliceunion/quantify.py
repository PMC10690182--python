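"""Local splicing variations (LSVs) and their PSI quantification.

An LSV is a split in the splice graph: at least two detected edges leaving a
reference exon on its 3' side (source LSV) or entering on its 5' side
(target LSV), strand-aware. Per-element inclusion PSI is quantified with a
beta-binomial model: reads for element j among the LSV's total are binomial
with rate Psi_j, under the Jeffreys-style prior Beta(1/J, 1 - 1/J) that
favours extreme inclusion values, giving the conjugate posterior

    Psi_j | r ~ Beta(1/J + r_j,  1 - 1/J + sum_{j' != j} r_{j'}).

The same posterior machinery is applied to short-read and long-read counts;
for long reads r_j is the summed read count of surviving transcript models
containing the element.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np

from .model import (
    ANNOTATION,
    EdgeKey,
    Interval,
    JUNCTION,
    LONG,
    RETAINED_INTRON,
    SHORT,
    SixCategory,
    SpliceGraph,
    SpliceGraphEdge,
    Transcript,
    ValidationError,
)

SOURCE_LSV = "source"
TARGET_LSV = "target"


@dataclass
class Lsv:
    """One local splicing variation: reference exon, direction and elements."""

    gene_id: str
    reference_exon: Interval
    direction: str  # "source" or "target"
    elements: list[SpliceGraphEdge]

    def __post_init__(self) -> None:
        if self.J < 2:
            raise ValidationError(f"LSV {self.lsv_id}: fewer than 2 elements")

    @property
    def J(self) -> int:
        return len(self.elements)

    @property
    def lsv_id(self) -> str:
        s, e = self.reference_exon
        return f"{self.gene_id}:{self.direction[0]}:{s}-{e}"

    def counts(self, source: str) -> np.ndarray:
        if source == SHORT:
            return np.array([e.short_count for e in self.elements], dtype=float)
        if source == LONG:
            return np.array([e.long_count for e in self.elements], dtype=float)
        raise ValidationError(f"unknown evidence source {source!r}")

    def element_keys(self) -> list[EdgeKey]:
        return [e.key for e in self.elements]


@dataclass
class PsiPosterior:
    """Per-element Beta posteriors over PSI for one LSV and source."""

    alpha: np.ndarray
    beta: np.ndarray

    @property
    def means(self) -> np.ndarray:
        return self.alpha / (self.alpha + self.beta)


def _attachment_sides(edge_iv: Interval, exon: Interval) -> tuple[bool, bool]:
    """Does the edge leave the exon rightward / enter it leftward (genomic)?

    An edge (intron interval [s, e]) attaches to the exon's right side when
    its last upstream exonic base s-1 lies in the exon, and to the left side
    when its first downstream exonic base e+1 does.
    """
    s, e = edge_iv
    right = exon[0] <= s - 1 <= exon[1]
    left = exon[0] <= e + 1 <= exon[1]
    return right, left


def define_lsvs(graph: SpliceGraph) -> list[Lsv]:
    """Enumerate all LSVs of a built splice graph.

    Only detected edges (support beyond annotation alone) are elements;
    retained-intron edges adjacent to the reference exon are included.
    """
    detected = [
        e
        for e in sorted(graph.edges.values(), key=lambda e: e.key)
        if e.support != {ANNOTATION}
    ]
    lsvs: list[Lsv] = []
    for exon in graph.exons:
        right_elems = []
        left_elems = []
        for e in detected:
            right, left = _attachment_sides(e.interval, exon)
            if right:
                right_elems.append(e)
            if left:
                left_elems.append(e)
        if graph.strand == "+":
            source_elems, target_elems = right_elems, left_elems
        else:
            source_elems, target_elems = left_elems, right_elems
        if len(source_elems) >= 2:
            lsvs.append(Lsv(graph.gene_id, exon, SOURCE_LSV, source_elems))
        if len(target_elems) >= 2:
            lsvs.append(Lsv(graph.gene_id, exon, TARGET_LSV, target_elems))
    return lsvs


def psi_posterior(counts: Sequence[float]) -> PsiPosterior:
    """Beta posterior per element from a count vector (J >= 2)."""
    r = np.asarray(counts, dtype=float)
    J = r.size
    if J < 2:
        raise ValidationError("PSI posterior requires J >= 2 elements")
    if np.any(r < 0):
        raise ValidationError("negative read counts")
    total = r.sum()
    alpha = 1.0 / J + r
    beta = 1.0 - 1.0 / J + (total - r)
    return PsiPosterior(alpha=alpha, beta=beta)


def psi_long_posterior(lsv: Lsv) -> PsiPosterior:
    """Posterior over PSI from long-read transcript-sum counts."""
    return psi_posterior(lsv.counts(LONG))


def psi_short(lsv: Lsv) -> PsiPosterior:
    """Posterior over PSI from short-read junction counts (same model)."""
    return psi_posterior(lsv.counts(SHORT))


def psi_means(lsv: Lsv, source: str) -> np.ndarray:
    return psi_posterior(lsv.counts(source)).means


def is_quantifiable(lsv: Lsv, source: str, min_reads: int = 10) -> bool:
    """True iff the LSV's elements accumulate >= min_reads from the source."""
    return float(lsv.counts(source).sum()) >= min_reads


def junction_min_psi(
    junction: EdgeKey | Interval,
    lsvs: Iterable[Lsv],
    source: str,
    min_reads: int = 10,
) -> Optional[float]:
    """Lowest posterior-mean PSI of a junction across its quantifiable LSVs.

    Returns None (excluded) when the junction sits in no quantifiable LSV.
    """
    key = junction if len(junction) == 3 else (JUNCTION, *junction)
    best: Optional[float] = None
    for lsv in lsvs:
        if not is_quantifiable(lsv, source, min_reads):
            continue
        keys = lsv.element_keys()
        if key in keys:
            value = float(psi_means(lsv, source)[keys.index(key)])
            best = value if best is None else min(best, value)
    return best


def ir_psi(
    intron: EdgeKey | Interval,
    lsvs: Iterable[Lsv],
    source: str,
    min_reads: int = 10,
) -> Optional[float]:
    """Lowest posterior-mean PSI of a retained intron across qualifying LSVs.

    LSVs whose total reads fall below ``min_reads`` are excluded; None when
    no LSV qualifies.
    """
    key = intron if len(intron) == 3 else (RETAINED_INTRON, *intron)
    return junction_min_psi(key, lsvs, source, min_reads)


def distance_to_3prime(
    lsv: Lsv, transcripts: Iterable[Transcript]
) -> Optional[float]:
    """Shortest spliced distance from the LSV's reference exon to a 3' end.

    For every annotation transcript containing the reference exon, sum the
    exonic bases strictly 3' of the exon's LSV-side boundary down to the
    transcript's TES; return the minimum (conservative under multiple 3'
    ends). None when no annotation transcript contains the exon.
    """
    exon = lsv.reference_exon
    best: Optional[int] = None
    for t in transcripts:
        if t.source != ANNOTATION:
            continue
        if not any(s <= exon[1] and exon[0] <= e for s, e in t.exons):
            continue
        if t.strand == "+":
            boundary = exon[1] if lsv.direction == SOURCE_LSV else exon[0]
            dist = sum(
                max(0, e - max(s, boundary + 1) + 1) for s, e in t.exons
            )
        else:
            boundary = exon[0] if lsv.direction == SOURCE_LSV else exon[1]
            dist = sum(
                max(0, min(e, boundary - 1) - s + 1) for s, e in t.exons
            )
        best = dist if best is None else min(best, dist)
    return None if best is None else float(best)
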