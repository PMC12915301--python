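"""Genome presence, count filtering, TPM and per-capita expression."""

import numpy as np
import pandas as pd
import pytest

from cazymeta.annotation import CazymeAnnotation, EcSource
from cazymeta.io_formats import GenomeQuality
from cazymeta.quant import (
    aggregate_tpm,
    build_expression_table,
    filter_counts,
    filter_genome_quality,
    genome_presence,
    per_capita,
    tpm_normalize,
)


class TestGenomeQualityFilter:
    def test_boundaries_inclusive(self):
        at = GenomeQuality("m1", 50.0, 5.0)
        below = GenomeQuality("m2", 49.9, 1.0)
        assert filter_genome_quality([at, below]) == {"m1"}

    def test_empty(self):
        assert filter_genome_quality([]) == set()


class TestGenomePresence:
    def cov(self, rows):
        return pd.DataFrame(rows, columns=["contig_id", "sample_id", "depth", "breadth", "length"])

    def test_length_weighted_breadth(self):
        cov = self.cov([("c1", "s1", 1.0, 0.2, 10_000), ("c2", "s1", 1.0, 0.05, 90_000)])
        present, breadth = genome_presence(cov, {"c1": "m1", "c2": "m1"})
        assert breadth.loc["m1", "s1"] == pytest.approx(0.065)
        assert not present.loc["m1", "s1"]

    def test_exact_ten_percent_is_present(self):
        cov = self.cov([("c1", "s1", 1.0, 0.10, 10_000)])
        present, _ = genome_presence(cov, {"c1": "m1"})
        assert bool(present.loc["m1", "s1"])

    def test_zero_coverage_absent(self):
        cov = self.cov([("c1", "s1", 0.0, 0.0, 10_000)])
        present, _ = genome_presence(cov, {"c1": "m1"})
        assert not present.loc["m1", "s1"]

    def test_unmapped_contig_is_an_error(self):
        cov = self.cov([("c1", "s1", 1.0, 0.5, 10_000)])
        with pytest.raises(KeyError):
            genome_presence(cov, {})


class TestCountsAndTpm:
    def test_cells_below_five_are_zeroed(self):
        counts = pd.DataFrame({"s1": [4, 5, 0]}, index=["g1", "g2", "g3"])
        out = filter_counts(counts)
        assert list(out["s1"]) == [0, 5, 0]

    def test_non_integer_counts_rejected(self):
        counts = pd.DataFrame({"s1": [4.5]}, index=["g1"])
        with pytest.raises(ValueError):
            filter_counts(counts)

    def test_worked_tpm_example(self):
        counts = pd.DataFrame({"s1": [10, 10]}, index=["g1", "g2"])
        lengths = pd.Series({"g1": 1000, "g2": 2000})
        tpm = tpm_normalize(counts, lengths)
        assert tpm.loc["g1", "s1"] == pytest.approx(666_666.6667, rel=1e-6)
        assert tpm.loc["g2", "s1"] == pytest.approx(333_333.3333, rel=1e-6)

    def test_single_nonzero_gene_takes_the_million(self):
        counts = pd.DataFrame({"s1": [7, 0]}, index=["g1", "g2"])
        tpm = tpm_normalize(counts, pd.Series({"g1": 900, "g2": 1200}))
        assert tpm.loc["g1", "s1"] == pytest.approx(1e6)

    def test_columns_sum_to_a_million(self):
        rng = np.random.default_rng(0)
        counts = pd.DataFrame(
            rng.integers(0, 500, size=(30, 4)),
            index=[f"g{i}" for i in range(30)],
            columns=list("abcd"),
        )
        lengths = pd.Series(rng.integers(300, 3000, size=30), index=counts.index)
        tpm = tpm_normalize(counts, lengths)
        assert np.allclose(tpm.sum(axis=0), 1e6, rtol=1e-9)

    def test_all_zero_column_stays_zero(self):
        counts = pd.DataFrame({"s1": [0, 0]}, index=["g1", "g2"])
        tpm = tpm_normalize(counts, pd.Series({"g1": 900, "g2": 1200}))
        assert (tpm["s1"] == 0).all()

    def test_zero_length_rejected(self):
        counts = pd.DataFrame({"s1": [5]}, index=["g1"])
        with pytest.raises(ValueError):
            tpm_normalize(counts, pd.Series({"g1": 0}))

    def test_filter_before_normalize_is_pinned(self):
        counts = pd.DataFrame({"s1": [4, 100]}, index=["g1", "g2"])
        lengths = pd.Series({"g1": 1000, "g2": 1000})
        pipeline = tpm_normalize(filter_counts(counts), lengths)
        reverse = tpm_normalize(counts, lengths)  # skipping the floor
        assert pipeline.loc["g1", "s1"] == 0.0
        assert reverse.loc["g1", "s1"] > 0.0
        assert pipeline.loc["g2", "s1"] != reverse.loc["g2", "s1"]

    def test_expressed_flag_threshold(self):
        counts = pd.DataFrame({"s1": [4, 5]}, index=["g1", "g2"])
        table = build_expression_table(counts, pd.Series({"g1": 900, "g2": 900}))
        assert not table.expressed.loc["g1", "s1"]
        assert table.expressed.loc["g2", "s1"]


class TestPerCapita:
    def test_ratio_and_missing_on_zero_depth(self):
        tpm = pd.DataFrame({"s1": [100.0], "s2": [50.0]}, index=["m1"])
        depth = pd.DataFrame({"s1": [20.0], "s2": [0.0]}, index=["m1"])
        out = per_capita(tpm, depth)
        assert out.loc["m1", "s1"] == pytest.approx(5.0)
        assert np.isnan(out.loc["m1", "s2"])

    def test_scale_equivariance(self):
        rng = np.random.default_rng(1)
        tpm = pd.DataFrame(rng.uniform(0, 1000, (5, 3)), columns=list("abc"))
        depth = pd.DataFrame(rng.uniform(1, 50, (5, 3)), columns=list("abc"))
        base = per_capita(tpm, depth)
        for c in (0.1, 2.5, 10.0):
            assert np.allclose(per_capita(tpm, depth * c), base / c)
            assert np.allclose(per_capita(tpm * c, depth * c), base)


class TestAggregateTpm:
    def anns(self):
        return {
            "g1": CazymeAnnotation("g1", frozenset({"GH13"}), frozenset({"3.2.1.1"}), EcSource.RULE1),
            "g2": CazymeAnnotation("g2", frozenset({"GH13"}), frozenset({"3.2.1.1"}), EcSource.RULE1),
            "g3": CazymeAnnotation(
                "g3", frozenset({"GH13"}), frozenset({"3.2.1.1", "3.2.1.133"}), EcSource.RULE1
            ),
        }

    def test_sums_within_key_and_genome(self):
        tpm = pd.DataFrame({"s1": [10.0, 5.0, 0.0]}, index=["g1", "g2", "g3"])
        out = aggregate_tpm(tpm, self.anns(), {"g1": "m1", "g2": "m1", "g3": "m1"}, by="ec")
        val = out[(out["ec"] == "3.2.1.1") & (out["sample_id"] == "s1")]["tpm"].iloc[0]
        assert val == pytest.approx(15.0)

    def test_multi_ec_gene_counts_fully_under_each(self):
        tpm = pd.DataFrame({"s1": [10.0]}, index=["g3"]).astype(float)
        out = aggregate_tpm(tpm, self.anns(), {"g3": "m1"}, by="ec")
        by_ec = out.set_index("ec")["tpm"]
        assert by_ec["3.2.1.1"] == pytest.approx(10.0)
        assert by_ec["3.2.1.133"] == pytest.approx(10.0)

    def test_empty_annotations_yield_empty_table(self):
        tpm = pd.DataFrame({"s1": [10.0]}, index=["g9"])
        out = aggregate_tpm(tpm, {}, {"g9": "m1"}, by="ec")
        assert out.empty
        assert out.attrs["n_dropped"] == 1
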