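import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from spliceunion.model import (
    AnnotationSet,
    JUNCTION,
    RETAINED_INTRON,
    SpliceGraphEdge,
    Transcript,
    ValidationError,
)
from spliceunion.quantify import (
    Lsv,
    define_lsvs,
    distance_to_3prime,
    ir_psi,
    is_quantifiable,
    junction_min_psi,
    psi_posterior,
    psi_short,
)


def _edge(kind, start, end, support=("short", "long"), short=0, long=0.0):
    return SpliceGraphEdge(kind=kind, start=start, end=end,
                           support=set(support), short_count=short,
                           long_count=long)


def _lsv(counts, source="long", direction="source", kind=JUNCTION):
    elements = []
    for i, c in enumerate(counts):
        start, end = 201 + i, 300 + 100 * i
        e = _edge(kind, start, end)
        if source == "long":
            e.long_count = c
        else:
            e.short_count = c
        elements.append(e)
    return Lsv("G1", (101, 200), direction, elements)


class TestDefineLsvs:
    def test_two_outgoing_junctions_form_source_lsv(self, toy_graph):
        lsvs = define_lsvs(toy_graph)
        by_id = {l.lsv_id: l for l in lsvs}
        src = by_id["G1:s:101-200"]
        assert src.J == 2
        assert {e.interval for e in src.elements} == {(201, 300), (201, 340)}

    def test_adjacent_retained_intron_included_as_element(self, toy_graph):
        lsvs = define_lsvs(toy_graph)
        src = {l.lsv_id: l for l in lsvs}["G1:s:501-600"]
        kinds = {e.kind for e in src.elements}
        assert RETAINED_INTRON in kinds and JUNCTION in kinds

    def test_linear_gene_has_no_lsvs(self):
        ann = AnnotationSet.from_transcripts(
            [Transcript("T", "G", "chr1", "+", ((1, 100), (201, 300), (401, 500)))]
        )
        from spliceunion.graph import build_splice_graph
        from spliceunion.model import ShortReadEvidence

        ev = ShortReadEvidence()
        ev.junctions = {("chr1", "+", 101, 200): 9, ("chr1", "+", 301, 400): 9}
        graph = build_splice_graph("G", ann, ev, [], 2)
        assert define_lsvs(graph) == []


class TestPsiPosterior:
    def test_j2_counts_7_3_gives_beta_7p5_3p5(self):
        post = psi_posterior([7, 3])
        assert post.alpha[0] == 7.5 and post.beta[0] == 3.5
        assert post.means[0] == pytest.approx(7.5 / 11)

    def test_zero_counts_return_the_prior(self):
        post = psi_posterior([0, 0, 0])
        np.testing.assert_allclose(post.alpha, 1 / 3)
        np.testing.assert_allclose(post.beta, 2 / 3)
        np.testing.assert_allclose(post.means, 1 / 3)

    def test_large_count_limit_approaches_one(self):
        post = psi_posterior([1000, 0])
        # oracle: numerical mean of the same Beta distribution
        numerical = stats.beta(post.alpha[0], post.beta[0]).mean()
        assert post.means[0] == pytest.approx(numerical, abs=1e-12)
        assert post.means[0] == pytest.approx(1.0, abs=1e-3)

    def test_short_counts_use_same_machinery(self):
        post = psi_short(_lsv([30, 10], source="short"))
        np.testing.assert_allclose(post.means, [30.5 / 41, 10.5 / 41])
        post0 = psi_short(_lsv([0, 0], source="short"))
        np.testing.assert_allclose(post0.means, [0.5, 0.5])
        post4 = psi_short(_lsv([10, 0, 0, 0], source="short"))
        assert post4.means[0] == pytest.approx(10.25 / 11)

    def test_single_element_rejected(self):
        with pytest.raises(ValidationError):
            psi_posterior([5])

    @settings(max_examples=100, derandomize=True, deadline=None)
    @given(
        st.lists(st.integers(min_value=0, max_value=5000), min_size=2, max_size=8)
    )
    def test_posterior_invariants(self, counts):
        post = psi_posterior(counts)
        J, total = len(counts), sum(counts)
        # conjugate update, exact up to float associativity
        np.testing.assert_allclose(
            post.alpha, 1.0 / J + np.asarray(counts, float), rtol=1e-12
        )
        np.testing.assert_allclose(
            post.beta, 1.0 - 1.0 / J + total - np.asarray(counts, float),
            rtol=1e-12, atol=1e-12,
        )
        # normalization
        assert abs(post.means.sum() - 1.0) < 1e-9
        # monotonicity: one more read strictly raises that element's mean
        bumped = list(counts)
        bumped[0] += 1
        assert psi_posterior(bumped).means[0] > post.means[0]

    def test_consistency_with_empirical_ratio_at_large_depth(self):
        counts = np.array([7000, 2000, 1000])
        post = psi_posterior(counts)
        np.testing.assert_allclose(post.means, counts / counts.sum(), atol=1e-3)


class TestQuantifiability:
    @pytest.mark.parametrize("source", ["short", "long"])
    @pytest.mark.parametrize("total,expected", [(10, True), (9, False)])
    def test_ten_read_boundary(self, source, total, expected):
        lsv = _lsv([total - 3, 3], source=source)
        assert is_quantifiable(lsv, source, 10) is expected

    def test_zero_threshold_always_quantifiable(self):
        assert is_quantifiable(_lsv([0, 0]), "long", 0) is True


class TestJunctionMinPsi:
    def test_lowest_value_across_lsvs(self):
        shared = _edge(JUNCTION, 201, 300, long=4)
        a = Lsv("G1", (101, 200), "source", [shared, _edge(JUNCTION, 201, 400, long=6)])
        b = Lsv("G1", (301, 400), "target", [shared, _edge(JUNCTION, 150, 300, long=36)])
        # psi in a = 4.5/11 ~ 0.409; in b = 4.5/41 ~ 0.11
        got = junction_min_psi(shared.key, [a, b], "long", 10)
        assert got == pytest.approx(4.5 / 41)

    def test_single_lsv_returns_its_value(self):
        a = _lsv([7, 3])
        got = junction_min_psi(a.elements[0].key, [a], "long", 10)
        assert got == pytest.approx(7.5 / 11)

    def test_no_quantifiable_lsv_is_excluded(self):
        a = _lsv([3, 3])
        assert junction_min_psi(a.elements[0].key, [a], "long", 10) is None


class TestIrPsi:
    def test_intron_vs_competing_junction(self):
        ir = _edge(RETAINED_INTRON, 201, 300, long=12)
        j = _edge(JUNCTION, 201, 300, long=4)
        lsv = Lsv("G1", (101, 200), "source", [ir, j])
        assert ir_psi(ir.key, [lsv], "long", 10) == pytest.approx(12.5 / 17)

    def test_below_min_reads_excluded(self):
        ir = _edge(RETAINED_INTRON, 201, 300, long=5)
        j = _edge(JUNCTION, 201, 300, long=3)
        lsv = Lsv("G1", (101, 200), "source", [ir, j])
        assert ir_psi(ir.key, [lsv], "long", 10) is None

    def test_lowest_across_multiple_lsvs(self):
        ir = _edge(RETAINED_INTRON, 201, 300, long=3)
        lsv1 = Lsv("G1", (101, 200), "source", [ir, _edge(JUNCTION, 201, 400, long=7)])
        lsv2 = Lsv("G1", (301, 400), "target", [ir, _edge(JUNCTION, 100, 300, long=27)])
        got = ir_psi(ir.key, [lsv1, lsv2], "long", 10)
        assert got == pytest.approx(3.5 / 31)


def _ann_t(tid, exons, strand="+"):
    return Transcript(tid, "G1", "chr1", strand, tuple(exons))


class TestDistanceTo3Prime:
    def test_two_exon_tail_sums_exonic_lengths(self):
        # tail after reference exon: exons of 120 and 80 nt -> 200
        t = _ann_t("T", [(101, 200), (301, 420), (501, 580)])
        lsv = Lsv("G1", (101, 200), "source",
                  [_edge(JUNCTION, 201, 300), _edge(JUNCTION, 201, 500)])
        assert distance_to_3prime(lsv, [t]) == 200

    def test_terminal_exon_distance_bounded_by_its_length(self):
        t = _ann_t("T", [(101, 200), (301, 400)])
        lsv = Lsv("G1", (301, 400), "target",
                  [_edge(JUNCTION, 201, 300), _edge(JUNCTION, 150, 300)])
        d = distance_to_3prime(lsv, [t])
        assert d is not None and d <= 100

    def test_minimum_over_transcripts_with_multiple_tes(self):
        long_tail = _ann_t("Ta", [(101, 200), (301, 800), (1001, 3100)])
        short_tail = _ann_t("Tb", [(101, 200), (301, 800)])
        lsv = Lsv("G1", (101, 200), "source",
                  [_edge(JUNCTION, 201, 300), _edge(JUNCTION, 201, 1000)])
        assert distance_to_3prime(lsv, [long_tail]) == 500 + 2100
        assert distance_to_3prime(lsv, [long_tail, short_tail]) == 500

    def test_no_containing_transcript_is_undefined(self):
        t = _ann_t("T", [(5001, 6000)])
        lsv = Lsv("G1", (101, 200), "source",
                  [_edge(JUNCTION, 201, 300), _edge(JUNCTION, 201, 400)])
        assert distance_to_3prime(lsv, [t]) is None

    def test_matches_per_base_enumeration_on_random_genes(self):
        """Spliced distance equals brute-force per-base counting."""
        from spliceunion.graph import build_splice_graph
        from spliceunion.model import ShortReadEvidence
        from spliceunion.simulate import SimConfig, simulate

        sim = simulate(SimConfig(n_genes=100, seed=21))
        ann = AnnotationSet.from_transcripts(sim.annotation_transcripts)
        checked = 0
        for gene_id, gene in ann.genes.items():
            ev = ShortReadEvidence()
            for key, c in sim.short.junctions.items():
                ev.junctions[key] = c
            graph = build_splice_graph(gene_id, ann, ev, [], 2)
            for lsv in define_lsvs(graph):
                got = distance_to_3prime(lsv, graph.transcripts)
                exp = _brute_force_distance(lsv, gene.transcripts)
                assert got == exp
                checked += 1
        assert checked >= 100


def _brute_force_distance(lsv, transcripts):
    """Independent oracle: enumerate every exonic base 3' of the boundary."""
    exon = lsv.reference_exon
    best = None
    for t in transcripts:
        if t.source != "annotation":
            continue
        if not any(s <= exon[1] and exon[0] <= e for s, e in t.exons):
            continue
        exonic = [p for s, e in t.exons for p in range(s, e + 1)]
        if t.strand == "+":
            boundary = exon[1] if lsv.direction == "source" else exon[0]
            d = sum(1 for p in exonic if p > boundary)
        else:
            boundary = exon[0] if lsv.direction == "source" else exon[1]
            d = sum(1 for p in exonic if p < boundary)
        best = d if best is None else min(best, d)
    return None if best is None else float(best)
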