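# spliceunion

Unified splice-graph comparison of three views of a transcriptome: a
reference annotation (GTF), short-read splice-junction evidence (STAR
`SJ.out.tab` plus an intron-retention count table), and long-read transcript
models (the GTF-with-counts output of callers such as FLAIR, ESPRESSO,
IsoQuant or Bambu).

Short and long RNA-seq reads disagree systematically: short reads detect
more splice junctions and longer retained introns, while long reads see far
more intron-retention events and lose coverage away from the polyA-proximal
3' end. `spliceunion` is for researchers who want to quantify those gaps for
their own data or benchmark a new long-read caller: it merges all three
sources into per-gene splice graphs, classifies every junction and retained
intron by the subset of sources supporting it, quantifies local splicing
variations from both technologies, and computes the comparison statistics
(detection versus coverage and inclusion, 3'-bias profiles, fuzzy splice-site
matching, intron-retention overlap).

## The model

**Splice graph.** Per gene, exons (merged across sources) are nodes and two
edge kinds connect them: junctions, keyed by their intron interval
`[donor_exon.end + 1, acceptor_exon.start - 1]` (1-based inclusive), and
retained introns. Every edge carries a support set ⊆ {annotation, short,
long} with per-source read counts. A short-read junction needs ≥ 2 unique
reads; long-read support needs ≥ 1 surviving transcript model (transcripts
with < 1 read are filtered); a long-read exon spanning an annotated or
short-observed intron is retained-intron evidence. Detected elements fall in
one of six categories — ALL, BOTH_DENOVO, SHORT_ANNOT, LONG_ANNOT,
SHORT_ONLY, LONG_ONLY — while annotation-only edges are NOT_DETECTED.

**LSVs and PSI.** A local splicing variation (LSV) is a split in the graph:
≥ 2 detected edges leaving a reference exon (source LSV) or entering it
(target LSV), strand-aware. With per-element read counts *r<sub>j</sub>*,
*j = 1…J*, element reads are binomial in the LSV total and inclusion
Ψ<sub>j</sub> gets the prior Beta(1/J, 1 − 1/J), which favours extreme
inclusion; conjugacy gives the posterior

&nbsp;&nbsp;&nbsp;&nbsp;Ψ<sub>j</sub> | r ~ Beta(1/J + r<sub>j</sub>, 1 − 1/J + Σ<sub>j′≠j</sub> r<sub>j′</sub>)

whose means sum to exactly 1. An LSV is *quantifiable* for a source when its
elements accumulate ≥ 10 reads; a junction appearing in several LSVs is
summarised by its lowest posterior-mean PSI.

**Novelty taxonomies.** De novo junctions split into novel-splice-site
versus novel-combination (both sites annotated, pair not); long-read
novel-splice-site elements refine to alternative 5'/3' splice site, mixed,
retained intron or new exon; novel long-read transcripts land in a
seven-class Venn over {novel combination, novel splice site, pTSS/pTES},
where pTSS/pTES marks transcript ends matching no annotated TSS/TES.

## Worked example

`python examples/psi_posteriors.py` quantifies one LSV from its counts:

```
counts=[7, 3]  (J=2)
  element 0: Beta(7.500, 3.500)  E[PSI]=0.6818
  element 1: Beta(3.500, 7.500)  E[PSI]=0.3182
  sum of posterior means = 1.000000000000
```

Seven reads against three gives the first element Beta(1/2 + 7, 1/2 + 3)
with posterior mean 7.5/11 ≈ 0.68; the means always sum to 1.

`python examples/three_prime_bias.py` simulates a matched dataset with
3'-anchored exponential truncation of long reads and measures its effect:

```
fraction of short-quantifiable LSVs not quantifiable by long reads,
by spliced distance to the transcript 3' end:
  [     0,    500) nt  n=266  fraction=0.120
  [   500,   1000) nt  n=252  fraction=0.214
  [  1000,   2500) nt  n=689  fraction=0.570
  [  2500,    inf) nt  n=116  fraction=0.828

Spearman(long coverage, 3' distance): rho=-0.360, p=2.4e-57 (n=1839 junctions)
```

LSVs close to the 3' end are almost always quantifiable by long reads; more
than 2.5 kb away, 83% fall below the 10-read filter, and long-read junction
coverage correlates negatively with 3' distance. The other examples cover
the six-way classification with ground-truth recovery
(`simulate_and_compare.py`) and fuzzy splice-site matching
(`fuzzy_splice_sites.py`).

A command-line layer wraps the same pipeline for shell use:

```bash
spliceunion simulate --out fixture --seed 7 --n-genes 50
spliceunion compare --annotation fixture/annotation.gtf \
    --long-gtf fixture/long_reads.gtf --sj fixture/SJ.out.tab \
    --ir fixture/ir_counts.tsv --out run
spliceunion evaluate --run-dir run --truth-dir fixture --out eval
```

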