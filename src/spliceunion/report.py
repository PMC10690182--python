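"""Figure-level summary statistics across one or more replicates.

Everything here is a deterministic function of its inputs: six-category
count bars with replicate mean +/- SEM, detection-versus-PSI and
detection-versus-coverage tables with CDFs, non-quantifiable LSV fractions
binned by coverage or 3'-distance, retained-intron comparisons, and read
length distributions.
"""

from __future__ import annotations

import math
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from .model import (
    JUNCTION,
    LONG,
    RETAINED_INTRON,
    SHORT,
    SixCategory,
    SpliceGraph,
)
from .classify import six_category
from .quantify import (
    Lsv,
    distance_to_3prime,
    ir_psi,
    is_quantifiable,
    junction_min_psi,
    psi_means,
)

#: default read-coverage bin edges (left-closed; last bin open-ended)
READ_BINS: tuple[float, ...] = (10, 20, 50, 100, math.inf)
#: default 3'-distance bin edges in spliced nt
DISTANCE_BINS: tuple[float, ...] = (0, 500, 1000, 2500, math.inf)

DETECTED_CATEGORIES = [c.value for c in SixCategory if c is not SixCategory.NOT_DETECTED]


def category_counts(
    replicates: Sequence[Sequence[SpliceGraph]], kind: str = JUNCTION
) -> pd.DataFrame:
    """Six-category counts per replicate with mean and standard error.

    ``replicates`` is one list of per-gene splice graphs per replicate. SEM
    is the sample standard deviation over replicates divided by sqrt(n);
    zero for a single replicate.
    """
    per_rep = []
    for graphs in replicates:
        counts = dict.fromkeys(DETECTED_CATEGORIES, 0)
        for g in graphs:
            for e in g.edges.values():
                if e.kind != kind:
                    continue
                cat = six_category(e)
                if cat is not SixCategory.NOT_DETECTED:
                    counts[cat.value] += 1
        per_rep.append(counts)
    n = len(per_rep)
    rows = []
    for cat in DETECTED_CATEGORIES:
        values = np.array([c[cat] for c in per_rep], dtype=float)
        sem = 0.0 if n < 2 else float(values.std(ddof=1) / math.sqrt(n))
        row = {"category": cat, "mean": float(values.mean()), "sem": sem}
        row.update({f"rep_{i}": int(v) for i, v in enumerate(values)})
        rows.append(row)
    return pd.DataFrame(rows)


def junction_table(
    graphs: Iterable[SpliceGraph],
    lsvs_by_gene: dict[str, list[Lsv]],
    min_reads: int = 10,
) -> pd.DataFrame:
    """Per-junction table for detection analyses.

    One row per detected junction edge: support category, counts, whether
    long reads detect it, and its lowest short-read PSI across quantifiable
    LSVs (None when the junction sits in no quantifiable LSV).
    """
    rows = []
    for g in graphs:
        lsvs = lsvs_by_gene.get(g.gene_id, [])
        for e in sorted(g.junction_edges(), key=lambda e: e.key):
            cat = six_category(e)
            if cat is SixCategory.NOT_DETECTED:
                continue
            rows.append(
                {
                    "gene_id": g.gene_id,
                    "start": e.start,
                    "end": e.end,
                    "six_category": cat.value,
                    "short_count": e.short_count,
                    "long_count": e.long_count,
                    "short_detected": SHORT in e.support,
                    "long_detected": LONG in e.support,
                    "psi_short": junction_min_psi(e.key, lsvs, SHORT, min_reads),
                }
            )
    return pd.DataFrame(
        rows,
        columns=[
            "gene_id", "start", "end", "six_category", "short_count",
            "long_count", "short_detected", "long_detected", "psi_short",
        ],
    )


def _bin_fractions(
    values: np.ndarray,
    detected: np.ndarray,
    edges: Sequence[float],
) -> pd.DataFrame:
    rows = []
    for lo, hi in zip(edges, list(edges[1:]) + [math.inf]):
        mask = (values >= lo) & (values < hi)
        n = int(mask.sum())
        frac = float(detected[mask].mean()) if n else float("nan")
        rows.append({"bin_left": lo, "bin_right": hi, "n": n, "fraction": frac})
    return pd.DataFrame(rows)


def detection_vs_psi(
    junctions: pd.DataFrame, bin_width: float = 0.05
) -> pd.DataFrame:
    """Fraction of short-read junctions also long-detected, binned by PSI.

    Input rows must be short-detected junctions with a quantified
    ``psi_short``; includes a CDF column over PSI of the short junctions.
    """
    df = junctions[junctions["short_detected"] & junctions["psi_short"].notna()]
    edges = np.round(np.arange(0.0, 1.0 + bin_width, bin_width), 10)
    psi = df["psi_short"].to_numpy(dtype=float)
    detected = df["long_detected"].to_numpy(dtype=bool)
    rows = []
    total = len(df)
    cum = 0
    for lo, hi in zip(edges[:-1], edges[1:]):
        mask = (psi >= lo) & (psi < hi) if hi < 1.0 else (psi >= lo) & (psi <= hi)
        n = int(mask.sum())
        cum += n
        rows.append(
            {
                "bin_left": lo,
                "bin_right": hi,
                "n_short": n,
                "n_long_detected": int(detected[mask].sum()),
                "fraction_long_detected": (
                    float(detected[mask].mean()) if n else float("nan")
                ),
                "cdf_short": cum / total if total else float("nan"),
            }
        )
    return pd.DataFrame(rows)


def missed_fraction(junctions: pd.DataFrame, psi_threshold: float = 0.2) -> float:
    """Fraction of short junctions with PSI >= threshold missed by long reads."""
    df = junctions[junctions["short_detected"] & junctions["psi_short"].notna()]
    df = df[df["psi_short"] >= psi_threshold]
    if df.empty:
        return float("nan")
    return float(1.0 - df["long_detected"].mean())


def detection_vs_coverage(
    junctions: pd.DataFrame, bins: Sequence[float] = (0,) + READ_BINS[:-1]
) -> pd.DataFrame:
    """Fraction of short-read junctions long-detected, by short coverage bin."""
    df = junctions[junctions["short_detected"]]
    return _bin_fractions(
        df["short_count"].to_numpy(dtype=float),
        df["long_detected"].to_numpy(dtype=bool),
        bins,
    )


def lsv_table(
    graphs: Iterable[SpliceGraph],
    lsvs_by_gene: dict[str, list[Lsv]],
    min_reads: int = 10,
) -> pd.DataFrame:
    """Per-LSV table: counts, quantifiability per source, 3'-distance."""
    rows = []
    for g in graphs:
        for lsv in lsvs_by_gene.get(g.gene_id, []):
            rows.append(
                {
                    "gene_id": g.gene_id,
                    "lsv_id": lsv.lsv_id,
                    "direction": lsv.direction,
                    "J": lsv.J,
                    "short_total": float(lsv.counts(SHORT).sum()),
                    "long_total": float(lsv.counts(LONG).sum()),
                    "quantifiable_short": is_quantifiable(lsv, SHORT, min_reads),
                    "quantifiable_long": is_quantifiable(lsv, LONG, min_reads),
                    "distance_3p": distance_to_3prime(lsv, g.transcripts),
                }
            )
    return pd.DataFrame(
        rows,
        columns=[
            "gene_id", "lsv_id", "direction", "J", "short_total", "long_total",
            "quantifiable_short", "quantifiable_long", "distance_3p",
        ],
    )


def nonquantifiable_fractions(
    lsvs: pd.DataFrame,
    axis: str = "coverage",
    bins: Optional[Sequence[float]] = None,
) -> pd.DataFrame:
    """Among short-quantifiable LSVs, fraction not quantifiable by long reads.

    ``axis`` is "coverage" (short-read total reads, default bins 10/20/50/100)
    or "distance3p" (spliced nt to the 3' end, default bins 0/500/1000/2500).
    """
    if axis == "coverage":
        bins = tuple(bins) if bins is not None else READ_BINS
        values = lsvs["short_total"]
    elif axis == "distance3p":
        bins = tuple(bins) if bins is not None else DISTANCE_BINS
        values = lsvs["distance_3p"]
    else:
        raise ValueError(f"unknown axis {axis!r}")
    df = lsvs[lsvs["quantifiable_short"] & values.notna()]
    out = _bin_fractions(
        df[values.name].to_numpy(dtype=float),
        (~df["quantifiable_long"]).to_numpy(dtype=bool),
        bins[:-1] if math.isinf(bins[-1]) else bins,
    )
    return out.rename(columns={"fraction": "fraction_nonquantifiable"})


def ir_comparison(
    graphs: Iterable[SpliceGraph],
    lsvs_by_gene: dict[str, list[Lsv]],
    min_reads: int = 10,
    read_bins: Sequence[float] = (1,) + READ_BINS[:-1],
    psi_bin_width: float = 0.1,
) -> dict[str, pd.DataFrame]:
    """Retained-intron comparison tables.

    Returns ``counts`` (per-category IR counts), ``lengths`` (per-category
    intron-length five-number summaries with whiskers at 1.5 IQR) and
    ``detection`` (long-read IR events binned by PSI and by long-read count,
    with the short-detected fraction per bin).
    """
    rows = []
    for g in graphs:
        lsvs = lsvs_by_gene.get(g.gene_id, [])
        for e in sorted(g.intron_edges(), key=lambda e: e.key):
            cat = six_category(e)
            if cat is SixCategory.NOT_DETECTED:
                continue
            rows.append(
                {
                    "gene_id": g.gene_id,
                    "start": e.start,
                    "end": e.end,
                    "six_category": cat.value,
                    "length": e.end - e.start + 1,
                    "short_detected": SHORT in e.support,
                    "long_detected": LONG in e.support,
                    "long_count": e.long_count,
                    "psi_long": ir_psi(e.key, lsvs, LONG, min_reads),
                }
            )
    ir = pd.DataFrame(
        rows,
        columns=[
            "gene_id", "start", "end", "six_category", "length",
            "short_detected", "long_detected", "long_count", "psi_long",
        ],
    )

    counts = (
        ir.groupby("six_category").size().rename("count").reset_index()
        if not ir.empty
        else pd.DataFrame(columns=["six_category", "count"])
    )

    length_rows = []
    for cat, sub in ir.groupby("six_category"):
        lengths = sub["length"].to_numpy(dtype=float)
        q1, med, q3 = np.percentile(lengths, [25, 50, 75])
        iqr = q3 - q1
        in_lo = lengths[lengths >= q1 - 1.5 * iqr]
        in_hi = lengths[lengths <= q3 + 1.5 * iqr]
        length_rows.append(
            {
                "six_category": cat,
                "n": len(lengths),
                "median": med,
                "q1": q1,
                "q3": q3,
                "whisker_low": float(in_lo.min()),
                "whisker_high": float(in_hi.max()),
            }
        )
    lengths = pd.DataFrame(
        length_rows,
        columns=["six_category", "n", "median", "q1", "q3", "whisker_low", "whisker_high"],
    )

    long_ir = ir[ir["long_detected"]]
    by_reads = _bin_fractions(
        long_ir["long_count"].to_numpy(dtype=float),
        long_ir["short_detected"].to_numpy(dtype=bool),
        read_bins,
    ).assign(axis="long_reads")
    with_psi = long_ir[long_ir["psi_long"].notna()]
    by_psi = _bin_fractions(
        with_psi["psi_long"].to_numpy(dtype=float),
        with_psi["short_detected"].to_numpy(dtype=bool),
        np.round(np.arange(0.0, 1.0, psi_bin_width), 10),
    ).assign(axis="psi")
    detection = pd.concat([by_psi, by_reads], ignore_index=True)
    return {"counts": counts, "lengths": lengths, "detection": detection, "events": ir}


def read_length_distribution(
    lengths: Sequence[float], thresholds: Sequence[float] = (3000,)
) -> dict[str, pd.DataFrame]:
    """Empirical CDF of read lengths and fraction >= each threshold."""
    arr = np.sort(np.asarray(lengths, dtype=float))
    n = arr.size
    cdf = pd.DataFrame(
        {"length": arr, "cum_fraction": np.arange(1, n + 1) / n if n else []}
    )
    fractions = pd.DataFrame(
        {
            "threshold": list(thresholds),
            "fraction_ge": [
                float((arr >= t).mean()) if n else float("nan") for t in thresholds
            ],
        }
    )
    return {"cdf": cdf, "fractions": fractions}
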