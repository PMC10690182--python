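import math

import numpy as np
import pandas as pd
import pytest

from spliceunion.quantify import define_lsvs
from spliceunion.report import (
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


def _junctions(n=100, detected_mask=None, psi=None, counts=None):
    detected_mask = (
        np.ones(n, dtype=bool) if detected_mask is None else detected_mask
    )
    return pd.DataFrame(
        {
            "gene_id": "G",
            "start": np.arange(n) * 10 + 100,
            "end": np.arange(n) * 10 + 200,
            "six_category": "ALL",
            "short_count": counts if counts is not None else np.full(n, 50),
            "long_count": 5.0,
            "short_detected": True,
            "long_detected": detected_mask,
            "psi_short": psi if psi is not None else np.full(n, 0.5),
        }
    )


class TestCategoryCounts:
    def test_single_replicate_has_zero_sem(self, toy_graph):
        table = category_counts([[toy_graph]])
        assert (table["sem"] == 0).all()
        total = table["mean"].sum()
        detected = sum(
            1 for e in toy_graph.junction_edges() if e.support != {"annotation"}
        )
        assert total == detected

    def test_identical_replicates_have_zero_sem(self, toy_graph):
        table = category_counts([[toy_graph], [toy_graph], [toy_graph]])
        assert (table["sem"] == 0).all()
        assert (table["mean"] == table["rep_0"]).all()

    def test_sem_matches_closed_form(self, toy_graph, toy_annotation, toy_short):
        from spliceunion.graph import build_splice_graph

        # replicate without long reads has fewer detected categories
        other = build_splice_graph("G1", toy_annotation, toy_short, [], 2)
        table = category_counts([[toy_graph], [other]])
        row = table.set_index("category").loc["ALL"]
        values = np.array([row["rep_0"], row["rep_1"]], dtype=float)
        assert row["sem"] == pytest.approx(values.std(ddof=1) / math.sqrt(2))


class TestDetectionVsPsi:
    def test_all_detected_gives_zero_missed(self):
        df = _junctions(50)
        assert missed_fraction(df, 0.2) == 0.0
        table = detection_vs_psi(df)
        filled = table[table["n_short"] > 0]
        assert (filled["fraction_long_detected"] == 1.0).all()

    def test_empty_long_set_gives_missed_one(self):
        df = _junctions(50, detected_mask=np.zeros(50, dtype=bool))
        assert missed_fraction(df, 0.2) == 1.0

    def test_configured_dropout_recovered(self):
        rng = np.random.default_rng(5)
        psi = rng.uniform(0.25, 0.95, 2000)
        detected = rng.random(2000) >= 0.10  # hide 10% of high-PSI junctions
        df = _junctions(2000, detected_mask=detected, psi=psi)
        assert missed_fraction(df, 0.2) == pytest.approx(0.10, abs=0.02)

    def test_cdf_is_monotone_and_ends_at_one(self):
        rng = np.random.default_rng(6)
        df = _junctions(500, psi=rng.uniform(0, 1, 500))
        table = detection_vs_psi(df)
        cdf = table["cdf_short"].to_numpy()
        assert (np.diff(cdf) >= 0).all()
        assert cdf[-1] == pytest.approx(1.0)


class TestDetectionVsCoverage:
    def test_identical_sets_give_fraction_one(self):
        table = detection_vs_coverage(_junctions(40))
        filled = table[table["n"] > 0]
        assert (filled["fraction"] == 1.0).all()

    def test_coverage_independent_dropout_is_flat(self):
        rng = np.random.default_rng(7)
        counts = rng.integers(2, 500, 4000)
        detected = rng.random(4000) >= 0.2
        table = detection_vs_coverage(
            _junctions(4000, detected_mask=detected, counts=counts)
        )
        filled = table[table["n"] > 50]
        assert (abs(filled["fraction"] - 0.8) < 0.05).all()

    def test_empty_bin_emitted_as_missing(self):
        table = detection_vs_coverage(_junctions(10, counts=np.full(10, 15)))
        empty = table[table["n"] == 0]
        assert empty["fraction"].isna().all()


class TestNonquantifiableFractions:
    def _lsvs(self, n=50, long_total=None, distance=None):
        return pd.DataFrame(
            {
                "gene_id": "G",
                "lsv_id": [f"L{i}" for i in range(n)],
                "direction": "source",
                "J": 2,
                "short_total": np.full(n, 40.0),
                "long_total": long_total if long_total is not None else np.full(n, 40.0),
                "quantifiable_short": True,
                "quantifiable_long": (
                    (long_total if long_total is not None else np.full(n, 40.0)) >= 10
                ),
                "distance_3p": distance if distance is not None else np.full(n, 100.0),
            }
        )

    def test_long_counts_copied_from_short_gives_zero(self):
        table = nonquantifiable_fractions(self._lsvs(), "coverage")
        filled = table[table["n"] > 0]
        assert (filled["fraction_nonquantifiable"] == 0.0).all()

    def test_long_counts_zeroed_gives_one(self):
        table = nonquantifiable_fractions(
            self._lsvs(long_total=np.zeros(50)), "distance3p"
        )
        filled = table[table["n"] > 0]
        assert (filled["fraction_nonquantifiable"] == 1.0).all()

    def test_truncation_profile_increases_with_distance(self):
        rng = np.random.default_rng(8)
        n = 4000
        distance = rng.uniform(0, 4000, n)
        # exponential 3' truncation: quantifiability decays with distance
        lam = np.exp(-distance / 1500)
        long_total = rng.poisson(25 * lam)
        table = nonquantifiable_fractions(
            self._lsvs(n, long_total=long_total, distance=distance), "distance3p"
        )
        fracs = table["fraction_nonquantifiable"].to_numpy()
        assert (np.diff(fracs) >= 0).all()


class TestIrComparison:
    def test_no_short_ir_leaves_only_long_categories(
        self, toy_annotation, toy_long
    ):
        from spliceunion.graph import build_splice_graph
        from spliceunion.model import Transcript

        ir_iso = Transcript(
            "L9", "G1", "chr1", "+", ((101, 200), (301, 800)),
            read_count=12.0, source="long_reads",
        )
        graph = build_splice_graph("G1", toy_annotation, None, [ir_iso], 2)
        tables = ir_comparison([graph], {"G1": define_lsvs(graph)})
        assert set(tables["counts"]["six_category"]) <= {"LONG_ONLY"}

    def test_single_event_quartiles_collapse_to_its_length(self, toy_graph):
        tables = ir_comparison([toy_graph], {"G1": define_lsvs(toy_graph)})
        lengths = tables["lengths"]
        row = lengths.iloc[0]
        assert row["median"] == row["q1"] == row["q3"] == 100
        assert row["whisker_low"] == row["whisker_high"] == 100

    def test_short_only_ir_longer_than_shared(self):
        rng = np.random.default_rng(9)
        rows = []
        for i in range(200):
            shared = i < 100
            length = int(rng.integers(2000, 5000)) if not shared else int(
                rng.integers(100, 500)
            )
            rows.append(
                {
                    "gene_id": "G",
                    "start": 1000 * i,
                    "end": 1000 * i + length - 1,
                    "six_category": "BOTH_DENOVO" if shared else "SHORT_ONLY",
                    "length": length,
                    "short_detected": True,
                    "long_detected": shared,
                    "long_count": 5.0 if shared else 0.0,
                    "psi_long": None,
                }
            )
        df = pd.DataFrame(rows)
        med = df.groupby("six_category")["length"].median()
        assert med["SHORT_ONLY"] > med["BOTH_DENOVO"]


class TestReadLengths:
    def test_all_short_reads_have_zero_fraction(self):
        out = read_length_distribution([100] * 50)
        assert out["fractions"]["fraction_ge"].iloc[0] == 0.0

    def test_threshold_boundary_inclusive(self):
        out = read_length_distribution([2999, 3000, 3001])
        assert out["fractions"]["fraction_ge"].iloc[0] == pytest.approx(2 / 3)

    def test_exponential_sample_median_fraction_half(self):
        rng = np.random.default_rng(10)
        lengths = rng.exponential(1000, 20000)
        median = 1000 * math.log(2)
        out = read_length_distribution(lengths, thresholds=[median])
        assert out["fractions"]["fraction_ge"].iloc[0] == pytest.approx(0.5, abs=0.02)

    def test_cdf_monotone_ends_at_one(self):
        out = read_length_distribution([5, 1, 3, 2])
        cdf = out["cdf"]["cum_fraction"].to_numpy()
        assert (np.diff(cdf) >= 0).all() and cdf[-1] == 1.0
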