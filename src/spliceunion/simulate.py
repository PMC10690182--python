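"""Synthetic matched annotation / short-read / long-read data with ground truth.

The generator emits exactly the input dialects the readers consume
(annotation GTF, long-read GTF with per-transcript counts plus sidecar TSV,
STAR SJ.out.tab, intron-retention TSV, a read-length list) together with
ground-truth labels for every element, transcript and known LSV.

Emulated phenomena: genes as exon chains with an annotated skipped exon;
per-class novelty injection (novel splice site, novel combination of
annotated sites, new exon, retained intron, putative TSS/TES, small
fuzzy-offset splice sites); log-normal expression; negative-binomial
short-read junction counts scaled by isoform usage; long reads sampled per
isoform and truncated from the 3' end with an exponential spliced-length
tail plus a full-length probability mass, reproducing the 3'-to-5' coverage
bias of polyA-primed long-read protocols.

Ground truth is re-derived from the emitted material by direct brute-force
scans (subset tests over raw junction/transcript sets), independent of the
splice-graph machinery, so label consistency holds by construction.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np
import pandas as pd

from .io import write_gtf, write_tables
from .model import (
    ANNOTATION,
    Interval,
    JUNCTION,
    LONG,
    RETAINED_INTRON,
    SHORT,
    ShortReadEvidence,
    Transcript,
    ValidationError,
    donor_acceptor,
)

_STRAND_CODE = {"+": 1, "-": 2}


@dataclass(frozen=True)
class SimConfig:
    """Generator parameters; defaults define the standard study conditions."""

    n_genes: int = 200
    exons_per_gene: tuple[int, int] = (12, 16)
    exon_length: tuple[int, int] = (120, 320)
    intron_length: tuple[int, int] = (300, 1500)
    new_exon_length: tuple[int, int] = (60, 120)
    intergenic_gap: int = 5000
    # expression and count models
    expression_sigma: float = 0.6          # log-normal spread, mean-1 scaled
    short_read_mean: float = 60.0          # NB mean scale for junction counts
    short_read_dispersion: float = 0.3
    long_read_depth: float = 25.0          # mean long reads per unit abundance
    # 3'-anchored truncation of long reads (spliced nt); None disables.
    # The near-pure exponential with a small full-length mass reproduces an
    # ONT-like length profile (~6% of reads reach 3 kb spliced).
    full_length_prob: float = 0.05
    truncation_scale: Optional[float] = 1200.0
    # per-gene novelty injection rates
    p_novel_ss_long: float = 0.35
    p_novel_comb_long: float = 0.30
    p_new_exon_long: float = 0.25
    p_ir_long: float = 0.60
    p_ptes_long: float = 0.20
    p_fuzzy_offset_long: float = 0.15
    p_novel_ss_short: float = 0.60
    p_novel_comb_short: float = 0.50
    p_ir_short: float = 0.25        # short IR row on the long-IR intron
    p_ir_short_only: float = 0.08   # short-only IR row on another intron
    p_short_drop: float = 0.05      # annotated junction loses its SJ row
    p_long_isoform_drop: float = 0.30  # skip isoform absent from long pool
    p_alt_tes: float = 0.30         # second annotated transcript ending early
    p_minus_strand: float = 0.5
    short_min_reads: int = 2
    seed: int = 0

    def __post_init__(self) -> None:
        for name in (
            "p_novel_ss_long", "p_novel_comb_long", "p_new_exon_long",
            "p_ir_long", "p_ptes_long", "p_fuzzy_offset_long",
            "p_novel_ss_short", "p_novel_comb_short", "p_ir_short",
            "p_ir_short_only", "p_short_drop", "p_long_isoform_drop",
            "p_alt_tes", "p_minus_strand", "full_length_prob",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValidationError(f"{name}={v} outside [0, 1]")
        if self.n_genes < 1:
            raise ValidationError("n_genes must be >= 1")
        if self.exons_per_gene[0] < 4:
            raise ValidationError("genes need at least 4 exons")
        if self.truncation_scale is not None and self.truncation_scale <= 0:
            raise ValidationError("truncation_scale must be positive")
        if self.new_exon_length[1] + 20 > self.intron_length[0]:
            raise ValidationError(
                "introns too short to host new exons (infeasible config)"
            )


@dataclass
class GroundTruth:
    """Brute-force labels for everything the generator emitted."""

    elements: pd.DataFrame     # gene, kind, start, end, six_category, ...
    transcripts: pd.DataFrame  # transcript_id, venn, ptss, ptes
    lsvs: pd.DataFrame         # gene, exon, direction, element, true_psi


@dataclass
class SimResult:
    config: SimConfig
    annotation_transcripts: list[Transcript]
    long_transcripts: list[Transcript]
    short: ShortReadEvidence
    read_lengths: list[int]
    truth: GroundTruth

    def write(self, out_dir: str) -> dict[str, str]:
        """Write every input dialect plus the truth tables; returns paths."""
        os.makedirs(out_dir, exist_ok=True)
        paths = {
            "annotation": os.path.join(out_dir, "annotation.gtf"),
            "long_gtf": os.path.join(out_dir, "long_reads.gtf"),
            "long_counts": os.path.join(out_dir, "long_read_counts.tsv"),
            "sj": os.path.join(out_dir, "SJ.out.tab"),
            "ir": os.path.join(out_dir, "ir_counts.tsv"),
            "read_lengths": os.path.join(out_dir, "read_lengths.txt"),
            "truth_elements": os.path.join(out_dir, "truth_elements.tsv"),
            "truth_transcripts": os.path.join(out_dir, "truth_transcripts.tsv"),
            "truth_lsvs": os.path.join(out_dir, "truth_lsvs.tsv"),
        }
        write_gtf(self.annotation_transcripts, paths["annotation"])
        write_gtf(self.long_transcripts, paths["long_gtf"])
        with open(paths["long_counts"], "w") as fh:
            for t in self.long_transcripts:
                fh.write(f"{t.transcript_id}\t{t.read_count:g}\n")
        with open(paths["sj"], "w") as fh:
            for (chrom, strand, start, end), count in sorted(
                self.short.junctions.items()
            ):
                code = _STRAND_CODE.get(strand, 0)
                annotated = 0
                fh.write(
                    f"{chrom}\t{start}\t{end}\t{code}\t1\t{annotated}\t"
                    f"{count}\t0\t40\n"
                )
        with open(paths["ir"], "w") as fh:
            fh.write("chromosome\tstrand\tintron_start\tintron_end\tsupporting_reads\n")
            for (chrom, strand, start, end), count in sorted(
                self.short.introns.items()
            ):
                fh.write(f"{chrom}\t{strand}\t{start}\t{end}\t{count}\n")
        with open(paths["read_lengths"], "w") as fh:
            for length in self.read_lengths:
                fh.write(f"{length}\n")
        write_tables(self.truth.elements, paths["truth_elements"])
        write_tables(self.truth.transcripts, paths["truth_transcripts"])
        write_tables(self.truth.lsvs, paths["truth_lsvs"])
        return paths


# ---------------------------------------------------------------------------
# per-gene construction
# ---------------------------------------------------------------------------

@dataclass
class _GeneDraw:
    """Everything the generator decided and emitted for one gene."""

    gene_id: str
    chromosome: str
    strand: str
    annotated: list[Transcript] = field(default_factory=list)
    emitted_long: list[Transcript] = field(default_factory=list)
    sj_counts: dict[Interval, int] = field(default_factory=dict)
    ir_counts: dict[Interval, int] = field(default_factory=dict)
    lsv_truth: list[dict] = field(default_factory=list)
    read_lengths: list[int] = field(default_factory=list)


def _nb(rng: np.random.Generator, mean: float, dispersion: float) -> int:
    """Negative binomial draw with mean ``mean`` and dispersion ``dispersion``
    (variance mean + dispersion * mean^2)."""
    if mean <= 0:
        return 0
    n = 1.0 / dispersion
    p = n / (n + mean)
    return int(rng.negative_binomial(n, p))


def _truncate_chain(
    exons: tuple[Interval, ...], strand: str, keep: int
) -> tuple[Interval, ...]:
    """Keep the 3'-most ``keep`` spliced nt of an exon chain."""
    ordered = list(exons[::-1]) if strand == "+" else list(exons)
    kept: list[Interval] = []
    remaining = keep
    for s, e in ordered:
        length = e - s + 1
        if remaining <= 0:
            break
        if length <= remaining:
            kept.append((s, e))
            remaining -= length
        else:
            if strand == "+":
                kept.append((e - remaining + 1, e))
            else:
                kept.append((s, s + remaining - 1))
            remaining = 0
    kept.sort()
    return tuple(kept)


def _spliced_len(exons: tuple[Interval, ...]) -> int:
    return sum(e - s + 1 for s, e in exons)


def _simulate_gene(
    rng: np.random.Generator, cfg: SimConfig, index: int, offset: int
) -> tuple[_GeneDraw, int]:
    gene_id = f"G{index:04d}"
    chrom = "chr1"
    strand = "-" if rng.random() < cfg.p_minus_strand else "+"
    n_exons = int(rng.integers(cfg.exons_per_gene[0], cfg.exons_per_gene[1] + 1))
    exon_lens = rng.integers(cfg.exon_length[0], cfg.exon_length[1] + 1, n_exons)
    intron_lens = rng.integers(
        cfg.intron_length[0], cfg.intron_length[1] + 1, n_exons - 1
    )
    exons: list[Interval] = []
    pos = offset
    for i in range(n_exons):
        exons.append((pos, pos + int(exon_lens[i]) - 1))
        pos = exons[-1][1] + 1
        if i < n_exons - 1:
            pos += int(intron_lens[i])
    introns = [(exons[i][1] + 1, exons[i + 1][0] - 1) for i in range(n_exons - 1)]
    next_offset = exons[-1][1] + cfg.intergenic_gap

    draw = _GeneDraw(gene_id=gene_id, chromosome=chrom, strand=strand)

    # ---- injection slots: disjoint intron indices ----
    used: set[int] = set()
    interior = list(range(1, n_exons - 1))
    rng.shuffle(interior)

    def take_skip() -> Optional[int]:
        for i, ex in enumerate(interior):
            if not {ex - 1, ex} & used:
                interior.pop(i)
                used.update({ex - 1, ex})
                return ex
        return None

    singles = list(range(n_exons - 1))
    rng.shuffle(singles)

    def take_single() -> Optional[int]:
        while singles:
            i = singles.pop()
            if i not in used:
                used.add(i)
                return i
        return None

    k = take_skip()  # annotated skipped exon
    j_nc = take_skip() if rng.random() < cfg.p_novel_comb_long else None
    j_nc_short = take_skip() if rng.random() < cfg.p_novel_comb_short else None
    m_ns = take_single() if rng.random() < cfg.p_novel_ss_long else None
    m_ne = take_single() if rng.random() < cfg.p_new_exon_long else None
    m_ir = take_single() if rng.random() < cfg.p_ir_long else None
    m_fz = take_single() if rng.random() < cfg.p_fuzzy_offset_long else None
    m_ns_short = take_single() if rng.random() < cfg.p_novel_ss_short else None

    def chain_without_exon(ex: int) -> tuple[Interval, ...]:
        return tuple(exons[:ex] + exons[ex + 1:])

    # ---- annotated transcripts ----
    t_full = Transcript(
        f"{gene_id}.T1", gene_id, chrom, strand, tuple(exons), source=ANNOTATION
    )
    draw.annotated.append(t_full)
    t_skip = None
    if k is not None:
        t_skip = Transcript(
            f"{gene_id}.T2", gene_id, chrom, strand, chain_without_exon(k),
            source=ANNOTATION,
        )
        draw.annotated.append(t_skip)
    if rng.random() < cfg.p_alt_tes and n_exons >= 6:
        # early polyadenylation isoform: drop the 2 transcription-terminal exons
        alt = tuple(exons[:-2]) if strand == "+" else tuple(exons[2:])
        draw.annotated.append(
            Transcript(f"{gene_id}.T3", gene_id, chrom, strand, alt, source=ANNOTATION)
        )

    # ---- long-read isoform pool with abundances ----
    psi_lo = rng.beta(0.2, 0.8)
    psi_hi = rng.beta(0.8, 0.2)
    psi = float(np.clip(psi_lo if rng.random() < 0.5 else psi_hi, 0.05, 0.95))
    # the pool defines isoform abundances (drives short counts and true PSI);
    # long_excluded isoforms exist but emit no long reads
    pool: list[tuple[tuple[Interval, ...], float]] = [
        (t_full.exons, psi if t_skip is not None else 1.0)
    ]
    long_excluded: set[tuple[Interval, ...]] = set()
    if t_skip is not None:
        pool.append((t_skip.exons, 1.0 - psi))
        if rng.random() < cfg.p_long_isoform_drop:
            long_excluded.add(t_skip.exons)

    def novel_abundance() -> float:
        return float(rng.uniform(0.1, 0.4))

    def shifted_intron_chain(m: int, delta: int) -> tuple[Interval, ...]:
        # shrink the exon genomically left of intron m: intron start moves left
        new = list(exons)
        s, e = new[m]
        new[m] = (s, e - delta)
        return tuple(new)

    if m_ns is not None:
        d = int(rng.integers(10, 31))
        pool.append((shifted_intron_chain(m_ns, d), novel_abundance()))
    if m_fz is not None:
        d = int(rng.integers(2, 7))
        pool.append((shifted_intron_chain(m_fz, d), novel_abundance()))
    if j_nc is not None:
        pool.append((chain_without_exon(j_nc), novel_abundance()))
    if m_ne is not None:
        ilen = introns[m_ne][1] - introns[m_ne][0] + 1
        ne_len = int(rng.integers(cfg.new_exon_length[0], cfg.new_exon_length[1] + 1))
        ne_start = introns[m_ne][0] + int(
            rng.integers(10, ilen - ne_len - 9)
        )
        ne = (ne_start, ne_start + ne_len - 1)
        chain = list(exons)
        chain.insert(m_ne + 1, ne)
        pool.append((tuple(sorted(chain)), novel_abundance()))
    if m_ir is not None:
        chain = exons[:m_ir] + [(exons[m_ir][0], exons[m_ir + 1][1])] + exons[m_ir + 2:]
        pool.append((tuple(chain), novel_abundance()))
    if rng.random() < cfg.p_ptes_long:
        d = int(rng.integers(20, 61))
        chain = list(exons)
        if strand == "+":
            s, e = chain[-1]
            chain[-1] = (s, e - d)
        else:
            s, e = chain[0]
            chain[0] = (s + d, e)
        pool.append((tuple(chain), novel_abundance()))

    # ---- sample long reads with 3'-anchored truncation, group into models ----
    expr = float(rng.lognormal(-cfg.expression_sigma**2 / 2, cfg.expression_sigma))
    groups: dict[tuple[Interval, ...], int] = {}
    read_lengths = draw.read_lengths
    for chain, abundance in pool:
        if chain in long_excluded:
            continue
        n_reads = 1 + int(rng.poisson(cfg.long_read_depth * abundance * expr))
        total = _spliced_len(chain)
        for _ in range(n_reads):
            if cfg.truncation_scale is None or rng.random() < cfg.full_length_prob:
                kept = chain
                length = total
            else:
                length = min(total, max(1, int(rng.exponential(cfg.truncation_scale))))
                kept = _truncate_chain(chain, strand, length)
            read_lengths.append(length)
            groups[kept] = groups.get(kept, 0) + 1
    for i, (chain, count) in enumerate(sorted(groups.items())):
        draw.emitted_long.append(
            Transcript(
                f"{gene_id}.L{i:03d}", gene_id, chrom, strand, chain,
                read_count=float(count), source="long_reads",
            )
        )

    # ---- short-read junction counts ----
    ann_junctions = {j for t in draw.annotated for j in t.junctions()}
    pool_weight: dict[Interval, float] = {}
    for chain, abundance in pool:
        t = Transcript("tmp", gene_id, chrom, strand, chain, source=ANNOTATION)
        for j in t.junctions():
            pool_weight[j] = pool_weight.get(j, 0.0) + abundance

    # one over-dispersion factor per gene: junctions of a gene share the
    # library/expression noise, so count *ratios* track isoform usage (PSI)
    # while marginal counts stay negative-binomial
    gamma = float(rng.gamma(1.0 / cfg.short_read_dispersion,
                            cfg.short_read_dispersion))

    def sj_count(weight: float) -> int:
        # mean proportional to isoform usage, so count ratios within an LSV
        # track the generating PSI; draws below the support threshold stay
        # in the file (STAR reports them) but do not support the junction
        return int(rng.poisson(cfg.short_read_mean * weight * expr * gamma))

    def add_sj(j: Interval, weight: float) -> None:
        count = sj_count(weight)
        if count >= 1:
            draw.sj_counts[j] = count

    for j in sorted(ann_junctions):
        if rng.random() < cfg.p_short_drop:
            continue
        add_sj(j, pool_weight.get(j, 0.0))
    # novel long junctions occasionally confirmed by short reads
    for chain, _ in pool:
        t = Transcript("tmp", gene_id, chrom, strand, chain, source=ANNOTATION)
        for j in t.junctions():
            if j in ann_junctions or j in draw.sj_counts:
                continue
            if rng.random() < 0.3:
                add_sj(j, pool_weight.get(j, 0.1))
    # short-only novel junctions
    if m_ns_short is not None:
        d = int(rng.integers(10, 31))
        s, e = introns[m_ns_short]
        j = (s, e + d)  # acceptor-side shift into the downstream exon
        if j not in ann_junctions and j not in pool_weight:
            add_sj(j, 0.3)
    if j_nc_short is not None:
        j = (introns[j_nc_short - 1][0], introns[j_nc_short][1])
        if j not in ann_junctions and j not in pool_weight:
            add_sj(j, 0.3)

    # ---- short-read intron retention rows ----
    if m_ir is not None and rng.random() < cfg.p_ir_short:
        draw.ir_counts[introns[m_ir]] = 1 + int(rng.poisson(5))
    if rng.random() < cfg.p_ir_short_only:
        candidates = [i for i in range(n_exons - 1) if i != m_ir]
        pick = int(rng.integers(0, len(candidates)))
        draw.ir_counts[introns[candidates[pick]]] = 1 + int(rng.poisson(5))

    # ---- LSV-level truth for the annotated skip event ----
    if k is not None and t_skip is not None:
        incl = (introns[k - 1][0], introns[k - 1][1])
        skip = (introns[k - 1][0], introns[k][1])
        w_incl = pool_weight.get(incl, 0.0)
        w_skip = pool_weight.get(skip, 0.0)
        if w_incl + w_skip > 0:
            ref_exon = exons[k - 1]
            draw.lsv_truth.append(
                {
                    "gene_id": gene_id,
                    "exon_start": ref_exon[0],
                    "exon_end": ref_exon[1],
                    "direction": "source" if strand == "+" else "target",
                    "element_start": incl[0],
                    "element_end": incl[1],
                    "true_psi": w_incl / (w_incl + w_skip),
                }
            )

    return draw, next_offset


# ---------------------------------------------------------------------------
# brute-force ground-truth derivation from the emitted material
# ---------------------------------------------------------------------------

_CAT = {
    frozenset({"annotation", "short", "long"}): "ALL",
    frozenset({"short", "long"}): "BOTH_DENOVO",
    frozenset({"annotation", "short"}): "SHORT_ANNOT",
    frozenset({"annotation", "long"}): "LONG_ANNOT",
    frozenset({"short"}): "SHORT_ONLY",
    frozenset({"long"}): "LONG_ONLY",
    frozenset({"annotation"}): "NOT_DETECTED",
}

_VENN = {
    frozenset({"nc"}): "I",
    frozenset({"ns"}): "II",
    frozenset({"nc", "ns"}): "III",
    frozenset({"nc", "p"}): "IV",
    frozenset({"ns", "p"}): "V",
    frozenset({"nc", "ns", "p"}): "VI",
    frozenset({"p"}): "VII",
}


def _truth_for_gene(draw: _GeneDraw, cfg: SimConfig) -> tuple[list[dict], list[dict]]:
    strand = draw.strand
    ann_junctions = {j for t in draw.annotated for j in t.junctions()}
    donors = {donor_acceptor(j, strand)[0] for j in ann_junctions}
    acceptors = {donor_acceptor(j, strand)[1] for j in ann_junctions}
    ann_tss = {t.tss for t in draw.annotated}
    ann_tes = {t.tes for t in draw.annotated}

    long_junctions: set[Interval] = set()
    for t in draw.emitted_long:
        long_junctions.update(t.junctions())
    short_junctions = {
        j for j, c in draw.sj_counts.items() if c >= cfg.short_min_reads
    }

    # long-read IR: emitted exon spans an annotated or short-observed intron
    comparison = ann_junctions | short_junctions
    long_ir: set[Interval] = set()
    for t in draw.emitted_long:
        for es, ee in t.exons:
            for s, e in comparison:
                if es < s and e < ee:
                    long_ir.add((s, e))
    short_ir = set(draw.ir_counts)

    def denovo_class(j: Interval) -> str:
        d, a = donor_acceptor(j, strand)
        if d in donors and a in acceptors:
            return "NOVEL_COMBINATION"
        return "NOVEL_SPLICE_SITE"

    def novel_type(j: Interval) -> str:
        d, a = donor_acceptor(j, strand)
        d_novel, a_novel = d not in donors, a not in acceptors
        for t in draw.emitted_long:
            if j not in set(t.junctions()):
                continue
            for exon in t.exons:
                if exon[1] == j[0] - 1 or exon[0] == j[1] + 1:
                    inside = any(
                        s <= exon[0] and exon[1] <= e for s, e in ann_junctions
                    )
                    starts = {s for s, _ in ann_junctions}
                    ends = {e for _, e in ann_junctions}
                    boundaries_novel = (
                        (exon[0] - 1) not in ends and (exon[1] + 1) not in starts
                    )
                    if inside and boundaries_novel:
                        return "NEW_EXON"
        if d_novel and a_novel:
            return "MIXED"
        return "ALT_5SS" if d_novel else "ALT_3SS"

    elements = []
    for j in sorted(ann_junctions | long_junctions | short_junctions):
        support = set()
        if j in ann_junctions:
            support.add("annotation")
        if j in short_junctions:
            support.add("short")
        if j in long_junctions:
            support.add("long")
        cat = _CAT[frozenset(support)]
        denovo = ss_type = None
        if cat != "NOT_DETECTED" and "annotation" not in support:
            denovo = denovo_class(j)
            if "long" in support and denovo == "NOVEL_SPLICE_SITE":
                ss_type = novel_type(j)
        elements.append(
            {
                "gene_id": draw.gene_id,
                "kind": JUNCTION,
                "start": j[0],
                "end": j[1],
                "six_category": cat,
                "denovo_class": denovo,
                "novel_ss_type": ss_type,
            }
        )
    for iv in sorted(short_ir | long_ir):
        support = set()
        if iv in short_ir:
            support.add("short")
        if iv in long_ir:
            support.add("long")
        elements.append(
            {
                "gene_id": draw.gene_id,
                "kind": RETAINED_INTRON,
                "start": iv[0],
                "end": iv[1],
                "six_category": _CAT[frozenset(support)],
                "denovo_class": "NOVEL_SPLICE_SITE",
                "novel_ss_type": "IR" if "long" in support else None,
            }
        )

    transcripts = []
    for t in draw.emitted_long:
        features = set()
        for j in t.junctions():
            if j in ann_junctions:
                continue
            features.add("nc" if denovo_class(j) == "NOVEL_COMBINATION" else "ns")
        ptss = t.tss not in ann_tss
        ptes = t.tes not in ann_tes
        if ptss or ptes:
            features.add("p")
        transcripts.append(
            {
                "gene_id": draw.gene_id,
                "transcript_id": t.transcript_id,
                "venn": _VENN.get(frozenset(features)),
                "ptss": ptss,
                "ptes": ptes,
            }
        )
    return elements, transcripts


# ---------------------------------------------------------------------------
# top level
# ---------------------------------------------------------------------------

def simulate(config: SimConfig, out_dir: Optional[str] = None) -> SimResult:
    """Generate one matched annotation/short/long dataset with ground truth.

    Identical configs (including seed) produce byte-identical outputs.
    """
    rng = np.random.default_rng(config.seed)
    offset = 1000
    draws: list[_GeneDraw] = []
    for i in range(config.n_genes):
        draw, offset = _simulate_gene(rng, config, i, offset)
        draws.append(draw)

    annotation_transcripts = [t for d in draws for t in d.annotated]
    long_transcripts = [t for d in draws for t in d.emitted_long]
    short = ShortReadEvidence(sample="sim")
    for d in draws:
        for (s, e), c in d.sj_counts.items():
            short.junctions[(d.chromosome, d.strand, s, e)] = c
        for (s, e), c in d.ir_counts.items():
            short.introns[(d.chromosome, d.strand, s, e)] = c
    read_lengths = [length for d in draws for length in d.read_lengths]
    element_rows: list[dict] = []
    transcript_rows: list[dict] = []
    lsv_rows: list[dict] = []
    for d in draws:
        el, tr = _truth_for_gene(d, config)
        element_rows.extend(el)
        transcript_rows.extend(tr)
        lsv_rows.extend(d.lsv_truth)

    truth = GroundTruth(
        elements=pd.DataFrame(
            element_rows,
            columns=[
                "gene_id", "kind", "start", "end", "six_category",
                "denovo_class", "novel_ss_type",
            ],
        ),
        transcripts=pd.DataFrame(
            transcript_rows,
            columns=["gene_id", "transcript_id", "venn", "ptss", "ptes"],
        ),
        lsvs=pd.DataFrame(
            lsv_rows,
            columns=[
                "gene_id", "exon_start", "exon_end", "direction",
                "element_start", "element_end", "true_psi",
            ],
        ),
    )
    result = SimResult(
        config=config,
        annotation_transcripts=annotation_transcripts,
        long_transcripts=long_transcripts,
        short=short,
        read_lengths=read_lengths,
        truth=truth,
    )
    if out_dir is not None:
        result.write(out_dir)
    return result


def truth_eval(
    elements: pd.DataFrame,
    transcripts: pd.DataFrame,
    truth: GroundTruth,
) -> dict[str, pd.DataFrame]:
    """Confusion tables pipeline-vs-truth for every taxonomy.

    ``elements``/``transcripts`` are the classification tables produced by
    the pipeline. Raises when the element universes differ. Returns one
    confusion DataFrame per taxonomy plus a ``recovery`` summary
    (trace / total per taxonomy).
    """
    keys = ["gene_id", "kind", "start", "end"]
    merged = truth.elements.merge(
        elements, on=keys, how="outer", suffixes=("_true", "_pred"), indicator=True
    )
    if (merged["_merge"] != "both").any():
        missing = merged[merged["_merge"] != "both"][keys + ["_merge"]]
        raise ValidationError(
            f"element universes differ between pipeline and truth:\n{missing.head()}"
        )
    out: dict[str, pd.DataFrame] = {}
    recovery_rows = []
    for column in ("six_category", "denovo_class", "novel_ss_type"):
        t = merged[f"{column}_true"].fillna("NONE")
        p = merged[f"{column}_pred"].fillna("NONE")
        confusion = (
            pd.crosstab(t, p).rename_axis(index="true", columns="predicted")
        )
        out[column] = confusion
        recovery_rows.append(
            {"taxonomy": column, "n": len(merged), "recovery": float((t == p).mean())}
        )
    tmerged = truth.transcripts.merge(
        transcripts, on=["gene_id", "transcript_id"], how="outer",
        suffixes=("_true", "_pred"), indicator=True,
    )
    if (tmerged["_merge"] != "both").any():
        raise ValidationError("transcript universes differ between pipeline and truth")
    for column in ("venn", "ptss", "ptes"):
        t = tmerged[f"{column}_true"].fillna("NONE").astype(str)
        p = tmerged[f"{column}_pred"].fillna("NONE").astype(str)
        out[column] = pd.crosstab(t, p).rename_axis(index="true", columns="predicted")
        recovery_rows.append(
            {"taxonomy": column, "n": len(tmerged), "recovery": float((t == p).mean())}
        )
    out["recovery"] = pd.DataFrame(recovery_rows)
    return out
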