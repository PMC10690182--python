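# Methods

## Scope and data flow

`spliceunion` compares three sources of transcriptome evidence per gene —
reference annotation, short-read splice-junction counts, long-read
transcript models — and everything downstream reads from one structure, the
unified splice graph. The pipeline is: read inputs → assign long-read
transcripts to genes → build per-gene graphs → classify elements →
enumerate and quantify LSVs → fuzzy splice-site sweep → reporting tables.
Genes are processed independently and all randomness lives in the
synthetic-data generator, so a run is a deterministic function of its
inputs and configuration (reruns are byte-identical).

## Coordinates and graph construction

All intervals are 1-based inclusive (GTF native); STAR's `SJ.out.tab`
intron coordinates are already 1-based, so no conversion happens anywhere.
Junctions and retained introns are keyed by their intron interval.

Edge support rules:

* **annotation** — the junction appears between consecutive exons of an
  annotated transcript;
* **short** — an `SJ.out.tab` row with unique-read count ≥ `short_min_reads`
  (default 2, the minimal reading of "multiple split reads"; the
  multi-mapping column is ignored as unreliable). Undetermined-strand rows
  (STAR code 0) are matched to genes by coordinates; rows matching no gene
  are dropped. A stricter filter requiring reads at multiple *positions*
  across the junction cannot be checked from `SJ.out.tab`, which has no
  per-position detail; this is a deliberate simplification.
* **long** — ≥ 1 transcript model containing the junction after the
  count filter (`min_count` 1.0, the recommended cut for callers that echo
  unexpressed reference transcripts). The edge's long count is the sum of
  read counts of containing transcripts — transcript counts are what
  long-read callers emit, so they are the natural per-junction unit.

Retained-intron edges come from the short-read IR table and from long-read
transcripts with an exon fully spanning an annotated or short-observed
intron (both flanking splice sites strictly inside the exon; partial
overlap is not IR). Annotation transcripts are not scanned for IR, so IR
support is ⊆ {short, long}: annotation is not an IR evidence source here,
matching how IR overlaps are compared across technologies. Annotation-only
junctions stay in the graph for export but are excluded from every detected
statistic.

Long-read transcripts are assigned to the same-strand annotated gene with
maximal exonic overlap, ties to the smaller gene id; this replaces the
caller's own gene assignment deterministically. Merged exons are the union
of all sources' exons; an edge endpoint outside every exon (possible for
short-only junctions with no transcript context) gets a minimal anchoring
exon so the graph invariant — every edge endpoint abuts exonic sequence —
always holds.

## Classification

The six-way category is the support subset. De novo junctions are
NOVEL_COMBINATION iff donor and acceptor (strand-aware) both exist in the
gene's annotated splice-site index but the pair is no annotated junction;
otherwise NOVEL_SPLICE_SITE. Long-read novel-splice-site elements refine
with precedence IR > NEW_EXON > ALT/MIXED: retained-intron edges are IR; a
junction whose novel boundary belongs to a transcript exon lying wholly
inside an annotated intron with both boundaries unannotated is NEW_EXON
(this catches both flanking junctions of a novel exon); otherwise the novel
side decides ALT_5SS / ALT_3SS, or MIXED when both sites are novel. The
precedence order is this package's choice — the outcomes are treated as
disjoint and no published rule orders them. Splice-site novelty is judged
against the gene's own annotated sites, not genome-wide, matching the
per-gene scope of the graph.

pTSS/pTES flags compare a long-read transcript's strand-aware endpoints
against the gene's annotated TSS/TES sets within `boundary_window`
(default 0 = exact; configurable for sensitivity analyses). Novel
transcripts map to the seven non-empty subsets of {novel combination,
novel splice site, pTSS/pTES}; the mapping to Roman numerals I–VII is fixed
in `TranscriptVenn` (VII = pTSS/pTES only, excluded from comparisons since
short-read callers cannot call transcript ends). A fully annotated
transcript is NONE.

## LSV quantification

For each merged exon, the detected edges attached to its 3' side
(strand-aware) form a source LSV when ≥ 2, and its 5' side a target LSV;
adjacent retained-intron edges count as elements. The same beta-binomial
posterior is applied to both sources' counts:

    Psi_j | r ~ Beta(1/J + r_j, 1 - 1/J + sum_{j' != j} r_{j'})

The prior Beta(1/J, 1 − 1/J) generalises the Jeffreys prior to J elements
and favours extreme inclusion. Closed-form consequences asserted in tests:
posterior means sum to exactly 1 (numerically < 1e−9), zero counts return
the prior (mean 1/J), means are strictly monotone in their own count and
converge to r_j/Σr. Applying the same machinery to short-read counts is a
simplification: it replaces the short-read bootstrap/stack machinery of
dedicated short-read tools, which this package does not reimplement.

Quantifiability requires Σ r_j ≥ `lsv_min_reads` (default 10). A junction
in several quantifiable LSVs reports its minimum posterior-mean PSI;
retained introns likewise, with LSVs under 10 reads excluded.

Distance to the 3' end is *spliced* (exonic) nucleotides from the reference
exon's LSV-side boundary to the TES, minimised over annotation transcripts
containing the exon — the conservative choice under multiple 3' ends. Read
length acts in transcript space, hence spliced rather than genomic
distance; annotation transcripts define the 3' ends because long-read 3'
ends are themselves subject to the artifacts being measured. Both choices
are this package's decisions where no convention exists.

Default bin edges: read coverage {[10,20), [20,50), [50,100), [100,∞)} and
3' distance {[0,500), [500,1000), [1000,2500), [2500,∞)} nt; PSI histogram
width 0.05. All configurable.

## Fuzzy splice-site matching

Long-read-only splice sites (per side: junction starts and ends
independently) are matched greedily nearest-first against short-read sites
within ±window, falling back to annotated sites; ties snap to the smaller
genomic coordinate; many long sites may share one target but each long site
snaps at most once. Only long-read sites move — short reads are never
re-matched against the annotation. `fuzzy_match` re-categorises *per
element*: every original edge keeps its identity and edges sharing a
snapped interval pool their support, so the total element count is
conserved at every window and ALL/BOTH_DENOVO counts are non-decreasing
while LONG_ONLY is non-increasing as the window grows. `apply_fuzzy`
produces the physically merged graph (colliding edges union support and sum
counts), on which matching again at the same window is a no-op. Sweeps are
independent per window, not cumulative. Matching per site rather than per
junction pair is the literal reading of matching "in both 5'/3' splice
sites"; a per-junction variant would be strictly more conservative.

## Synthetic data generator

The generator emits exactly the dialects the readers consume (annotation
GTF, long-read GTF + sidecar counts, `SJ.out.tab`, IR TSV, a read-length
list) plus ground-truth labels, and is the package's test bed. Per gene:

* an exon chain (12–16 exons of 120–320 nt, introns 300–1500 nt) with a
  full-length transcript, an annotated skipped-exon isoform and, with
  probability 0.3, an early-polyadenylation isoform (second annotated TES);
* novelty injected into disjoint intron slots, one class each per gene at
  its configured rate: novel splice site (donor shifted 10–30 nt into the
  exon), novel combination (unannotated exon skip over annotated sites),
  new exon (60–120 nt inside an intron, both boundaries novel), retained
  intron (two exons merged), pTES (shortened terminal exon), a small
  2–6 nt splice-site offset to exercise fuzzy matching, and short-read-only
  novel junctions;
* isoform abundances: skip-event PSI from the extreme-favouring mixture
  0.5·Beta(0.2,0.8) + 0.5·Beta(0.8,0.2), clipped to [0.05, 0.95]; novel
  isoforms Uniform(0.1, 0.4);
* short-read counts: per-junction Poisson with mean
  `short_read_mean · weight · expression · gamma`, where weight is the
  summed abundance of isoforms containing the junction, expression is
  log-normal (σ 0.6, mean-1 scaled) and gamma a per-gene Gamma factor
  (dispersion 0.3). Sharing gamma across a gene's junctions makes count
  *ratios* track the generating PSI while marginal counts stay
  negative-binomial; draws of 1 still appear in the file (as STAR would
  report them) but do not reach the 2-read support threshold;
* long reads: per isoform 1 + Poisson(depth · abundance · expression)
  reads (depth 25); each read is full-length with probability 0.05, else
  truncated to an Exp(1200 nt) spliced suffix anchored at the isoform's 3'
  end. Reads grouped by identical exon chains become the emitted transcript
  models with counts — truncation thus yields pTSS models, graded junction
  coverage loss toward 5', and an ONT-like length profile (~6% of reads
  reach 3 kb). An isoform can be excluded from long-read emission without
  leaving the abundance model, decoupling detection gaps from quantification.

Ground truth is re-derived from the emitted material by brute-force subset
scans (set membership over junction/transcript collections) written
independently of the splice-graph machinery, so label consistency holds by
construction and the pipeline's classification can be scored against it;
the noiseless defaults are recovered at 100%.

Depth, expression spread and the truncation profile were chosen together so
that each emulated phenomenon is statistically resolvable at the default
200-gene scale: short reads detect slightly more junctions than long reads,
long reads report roughly twice the IR events, non-quantifiability grows
monotonically across the distance bins, and coverage–distance correlation
is strongly negative. What the generator does **not** emulate: genomic
sequence and alignment artifacts, splice-site motifs, overlapping genes,
multi-mapping, inter-replicate biological variability, and the
transcriptome-wide expression skew that produces the large (40–60%)
short-read junction excess seen at full data scale — on synthetic data the
excess has the right sign but a small magnitude, so passing tests certify
the machinery, not effect sizes on real data.

## Numerical and degenerate-input choices

Posterior arithmetic is plain float64; the normalization identity is exact
in closed form and asserted to 1e−9. Empty annotation files yield empty
sets with a warning; an LSV needs J ≥ 2 by definition; zero-read LSVs
return prior means and are flagged non-quantifiable; empty report bins emit
NaN fractions rather than rows dropping out; tables are written with floats
at 6 significant digits and stable column order. Single-exon transcripts
have no junctions and only participate via exons/TSS/TES.

## Known limitations

Short-read PSI here is not a reimplementation of any short-read caller's
full model (no bootstrapping, no per-position read stacks). One long-read
source is compared at a time; contrasting two long-read technologies means
two runs joined on element keys. IR detection from short reads is taken
from the provided IR table as-is — the package does not re-derive IR from
intronic coverage. The Venn numbering and the MIXED/NEW_EXON precedence are
package conventions; comparisons across tools should join on the underlying
feature sets, not the numerals.
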