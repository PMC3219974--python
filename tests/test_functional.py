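"""Genic context, selection fractions, conservation means and expression proportions."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from cnvhotspots.core import CnvInterval, GeneModel, GenomeModel, ParameterError
from cnvhotspots.functional import (GeneIndex, ScoreTrack, classify_genic_context,
                                    calibrate_k_threshold, compare_k_distributions,
                                    conservation_compare, expression_proportions,
                                    genic_context_table, genic_enrichment,
                                    positive_selection_fraction)


@pytest.fixture
def gene_plus():
    # + strand gene: span [10_000, 30_000), exons at [10_000,10_500) and [29_000,30_000)
    return GeneModel("gA", "chr1", "+", 10_000, 30_000,
                     exons=[(10_000, 10_500), (29_000, 30_000)])


@pytest.fixture
def gene_minus():
    # - strand gene: TSS at 80_000 (right end), promoter [80_000, 82_000)
    return GeneModel("gB", "chr1", "-", 60_000, 80_000, exons=[(60_000, 61_000)])


class TestGenicContext:
    def test_single_exon_base_is_exonic(self, gene_plus):
        index = GeneIndex([gene_plus])
        assert classify_genic_context(("chr1", 10_499, 10_501), index) == "exonic"

    def test_inside_intron(self, gene_plus):
        index = GeneIndex([gene_plus])
        assert classify_genic_context(("chr1", 15_000, 16_000), index) == "intronic"

    def test_promoter_window_plus_strand(self, gene_plus):
        # TSS = 10_000; promoter = [8_000, 10_000)
        index = GeneIndex([gene_plus])
        assert classify_genic_context(("chr1", 8_500, 9_000), index) == "promoter"
        assert classify_genic_context(("chr1", 6_000, 7_999), index) == "intergenic"

    def test_promoter_window_minus_strand(self, gene_minus):
        index = GeneIndex([gene_minus])
        assert classify_genic_context(("chr1", 80_100, 80_200), index) == "promoter"

    def test_precedence_exonic_over_promoter(self, gene_plus, gene_minus):
        # interval touching gA's exon and gB's promoter at once -> exonic wins
        index = GeneIndex([gene_plus, gene_minus])
        assert classify_genic_context(("chr1", 10_400, 80_500), index) == "exonic"

    def test_every_interval_gets_exactly_one_label(self, gene_plus, gene_minus):
        rng = np.random.default_rng(2)
        cnvs = [CnvInterval(f"c{i}", "chr1", int(s), int(s) + int(l))
                for i, (s, l) in enumerate(zip(rng.integers(0, 100_000, 200),
                                               rng.integers(100, 5_000, 200)))]
        table = genic_context_table(cnvs, [gene_plus, gene_minus])
        assert len(table) == 200
        assert table["context"].isin(
            ["exonic", "intronic", "promoter", "intergenic"]).all()


class TestPositiveSelection:
    def k_table(self, ks):
        return pd.DataFrame({"gene_id": [f"g{i}" for i in range(len(ks))], "K": ks})

    def test_half_selected(self):
        res = positive_selection_fraction(["g0", "g1"], self.k_table([0.01, 0.9]), 0.05)
        assert res["fraction"] == 0.5 and res["n_selected"] == 1

    def test_none_selected(self):
        res = positive_selection_fraction(["g0", "g1"], self.k_table([1.0, 1.0]), 0.05)
        assert res["fraction"] == 0.0

    def test_missing_genes_tallied(self):
        res = positive_selection_fraction(["g0", "missing"], self.k_table([0.01]), 0.5)
        assert res["n_missing"] == 1 and res["n_scored"] == 1

    def test_empty_gene_list(self):
        assert positive_selection_fraction([], self.k_table([0.5]), 0.1)["fraction"] is None

    @given(st.lists(st.floats(0, 1), min_size=5, max_size=40),
           st.floats(0.05, 0.45), st.floats(0.05, 0.45))
    @settings(max_examples=100, deadline=None)
    def test_monotone_in_threshold(self, ks, t1, dt):
        table = self.k_table(ks)
        ids = list(table["gene_id"])
        f1 = positive_selection_fraction(ids, table, t1)["fraction"]
        f2 = positive_selection_fraction(ids, table, min(t1 + dt, 0.99))["fraction"]
        assert f1 <= f2

    def test_calibrated_threshold_reproduces_target(self):
        rng = np.random.default_rng(3)
        table = self.k_table(rng.uniform(0, 1, 500))
        ids = list(table["gene_id"])
        thr = calibrate_k_threshold(ids, table, 0.09)
        got = positive_selection_fraction(ids, table, thr)["fraction"]
        assert got == pytest.approx(0.09, abs=1 / 500)


class TestCompareK:
    def test_identical_sets(self):
        table = pd.DataFrame({"gene_id": ["a", "b", "c"], "K": [0.1, 0.5, 0.9]})
        res = compare_k_distributions(["a", "b", "c"], ["a", "b", "c"], table)
        assert res.value == 0.0 and res.detail["median_difference"] == 0.0

    def test_symmetric_d(self):
        rng = np.random.default_rng(4)
        table = pd.DataFrame({"gene_id": [f"g{i}" for i in range(100)],
                              "K": rng.uniform(0, 1, 100)})
        a = [f"g{i}" for i in range(40)]
        b = [f"g{i}" for i in range(40, 100)]
        assert compare_k_distributions(a, b, table).value == \
            compare_k_distributions(b, a, table).value

    def test_empty_join_raises(self):
        table = pd.DataFrame({"gene_id": ["a"], "K": [0.5]})
        with pytest.raises(ParameterError):
            compare_k_distributions(["missing"], ["a"], table)


class TestScoreTrack:
    def track(self, rows):
        return ScoreTrack(pd.DataFrame(rows, columns=["chrom", "start", "end", "score"]))

    def test_single_record_mean(self):
        t = self.track([("chr1", 0, 1_000, 0.7)])
        assert t.interval_mean("chr1", 100, 200) == pytest.approx(0.7)

    def test_adjacent_records_length_weighted(self):
        t = self.track([("chr1", 0, 100, 0.0), ("chr1", 100, 200, 1.0)])
        assert t.interval_mean("chr1", 50, 150) == pytest.approx(0.5)

    def test_uncovered_zero_policy(self):
        t = self.track([("chr1", 0, 100, 1.0)])
        assert t.interval_mean("chr1", 0, 200) == pytest.approx(0.5)
        assert t.interval_mean("chr2", 0, 100) == 0.0

    def test_uncovered_exclude_policy(self):
        t = self.track([("chr1", 0, 100, 1.0)])
        assert t.interval_mean("chr1", 0, 200, uncovered="exclude") == pytest.approx(1.0)
        assert t.interval_mean("chr1", 500, 600, uncovered="exclude") is None

    def test_overlapping_records_rejected(self):
        with pytest.raises(ParameterError):
            self.track([("chr1", 0, 100, 0.5), ("chr1", 50, 150, 0.6)])

    def test_split_recombine_consistency(self):
        """Mean over [a,c) equals the length-weighted mean of [a,b) and [b,c)."""
        rng = np.random.default_rng(6)
        rows = [("chr1", i * 100, (i + 1) * 100, float(rng.uniform()))
                for i in range(100)]
        t = self.track(rows)
        for _ in range(20):
            a = int(rng.integers(0, 9_000))
            c = int(rng.integers(a + 2, 10_000))
            b = int(rng.integers(a + 1, c))
            whole = t.interval_mean("chr1", a, c)
            left = t.interval_mean("chr1", a, b)
            right = t.interval_mean("chr1", b, c)
            combined = (left * (b - a) + right * (c - b)) / (c - a)
            assert whole == pytest.approx(combined, abs=1e-12)


class TestConservationCompare:
    def test_uniform_track_d_zero(self):
        track = ScoreTrack(pd.DataFrame([("chr1", 0, 100_000, 0.5)],
                                        columns=["chrom", "start", "end", "score"]))
        a = [CnvInterval("a", "chr1", 0, 1_000)]
        b = [CnvInterval("b", "chr1", 50_000, 51_000)]
        res = conservation_compare(a, b, track)
        assert res["test"].value == 0.0
        assert res["mean_a"] == res["mean_b"] == pytest.approx(0.5)

    def test_extreme_separation(self):
        track = ScoreTrack(pd.DataFrame(
            [("chr1", 0, 50_000, 0.0), ("chr1", 50_000, 100_000, 1.0)],
            columns=["chrom", "start", "end", "score"]))
        a = [CnvInterval(f"a{i}", "chr1", i * 1_000, i * 1_000 + 500) for i in range(10)]
        b = [CnvInterval(f"b{i}", "chr1", 50_000 + i * 1_000, 50_500 + i * 1_000)
             for i in range(10)]
        res = conservation_compare(a, b, track)
        assert res["test"].value == 1.0
        assert res["curve_a"]["cumulative_fraction"].iloc[-1] == 1.0


class TestExpression:
    def table(self, cats):
        return pd.DataFrame({"gene_id": [f"g{i}" for i in range(len(cats))],
                             "category": cats})

    def test_identical_sets_chi2_zero(self):
        table = self.table(["stabilizing", "stabilizing", "DE_two_species", "other"])
        ids = [f"g{i}" for i in range(4)]
        res = expression_proportions(ids, ids, table)
        for cat, entry in res["categories"].items():
            assert entry["proportion_hotspot"] == entry["proportion_background"]
            if entry["test"] is not None:
                assert entry["test"].value == 0.0

    def test_proportions_sum_to_one(self):
        rng = np.random.default_rng(7)
        cats = rng.choice(["DE_two_species", "stabilizing", "other"], 60).tolist()
        table = self.table(cats)
        hot = [f"g{i}" for i in range(20)]
        bg = [f"g{i}" for i in range(20, 60)]
        res = expression_proportions(hot, bg, table)
        assert sum(e["proportion_hotspot"] for e in res["categories"].values()) \
            == pytest.approx(1.0)
        assert sum(e["proportion_background"] for e in res["categories"].values()) \
            == pytest.approx(1.0)

    def test_empty_join_raises(self):
        with pytest.raises(ParameterError):
            expression_proportions(["x"], ["y"], self.table(["other"]))


class TestGenicEnrichment:
    def test_empty_annotation_observed_zero(self, small_genome):
        cnvs = [CnvInterval("c", "chr1", 0, 10_000)]
        res = genic_enrichment(cnvs, [], small_genome, n_iter=5, seed=1)
        assert res.observed == 0

    def test_genes_tiling_genome_fold_one(self):
        genome = GenomeModel(chromosomes=[("chr1", 1_000_000)])
        genes = [GeneModel(f"g{i}", "chr1", "+", i * 10_000, (i + 1) * 10_000,
                           exons=[(i * 10_000, (i + 1) * 10_000)])
                 for i in range(100)]
        cnvs = [CnvInterval(f"c{i}", "chr1", i * 50_000, i * 50_000 + 2_000)
                for i in range(10)]
        res = genic_enrichment(cnvs, genes, genome, n_iter=20, seed=2)
        assert res.observed == 10 and res.fold == pytest.approx(1.0)
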