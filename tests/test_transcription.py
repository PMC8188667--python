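"""Gene activity classes, non-TR extraction, the log2 enrichment statistic,
rank-sum testing and heatmap matrices."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from nailseq import (
    BinnedTrack,
    GenomeLayout,
    Interval,
    IntervalSet,
    NonTRRegion,
    ReadSet,
    build_heatmap_matrix,
    classify_genes,
    define_non_trs,
    density_log2_ratio,
    wilcoxon_rank_sum,
)

from .bruteforce import as_set


def gene_table(rows):
    return pd.DataFrame(
        rows, columns=["chrom", "start", "end", "strand", "promoter_density", "body_rpk"]
    )


class TestClassifyGenes:
    @pytest.mark.parametrize(
        "prom,rpk,expected",
        [
            (0.5, 4.1, "active"),
            (0.0, 1.0, "silent"),  # boundary: RPK <= 1
            (0.0, 2.0, "intermediate"),
            (0.5, 4.0, "intermediate"),  # boundary: RPK > 4 is strict
        ],
    )
    def test_human_rules(self, prom, rpk, expected):
        df = classify_genes(gene_table([("c", 0, 1000, "+", prom, rpk)]), "human")
        assert df["activity"].iloc[0] == expected

    @pytest.mark.parametrize(
        "rpk,expected", [(1.5, "active"), (0.0, "silent"), (0.5, "intermediate")]
    )
    def test_mouse_rules(self, rpk, expected):
        df = classify_genes(gene_table([("c", 0, 1000, "+", 0.0, rpk)]), "mouse")
        assert df["activity"].iloc[0] == expected

    def test_tss_tts_follow_strand(self):
        df = classify_genes(gene_table([("c", 100, 900, "-", 1.0, 5.0)]), "human")
        assert df["tss"].iloc[0] == 900 and df["tts"].iloc[0] == 100

    def test_missing_column_rejected(self):
        with pytest.raises(ValueError):
            classify_genes(pd.DataFrame({"chrom": ["c"]}), "human")


def _classified(rows):
    return classify_genes(gene_table(rows), "human")


class TestDefineNonTRs:
    def test_gap_between_two_active_genes(self):
        genes = _classified(
            [
                ("c", 100_000, 150_000, "+", 1.0, 10.0),
                ("c", 200_000, 260_000, "-", 1.0, 10.0),
            ]
        )
        comps = as_set([("c", 0, 1_000_000)])
        regions = define_non_trs(genes, comps)
        assert len(regions) == 1
        assert regions[0].region == Interval("c", 150_000, 200_000)
        assert regions[0].upstream_flank == Interval("c", 100_000, 150_000)

    def test_no_active_genes_no_regions(self):
        genes = _classified([("c", 100_000, 150_000, "+", 0.0, 0.5)])
        assert define_non_trs(genes, as_set([("c", 0, 1_000_000)])) == []

    def test_width_filter_excludes_large_gap(self):
        genes = _classified(
            [
                ("c", 100_000, 150_000, "+", 1.0, 10.0),
                ("c", 300_000, 360_000, "-", 1.0, 10.0),  # 150-kb gap
            ]
        )
        assert define_non_trs(genes, as_set([("c", 0, 1_000_000)])) == []

    def test_eriz_overlap_filter(self):
        genes = _classified(
            [
                ("c", 100_000, 150_000, "+", 1.0, 10.0),
                ("c", 200_000, 260_000, "-", 1.0, 10.0),
                ("c", 300_000, 350_000, "+", 1.0, 10.0),
            ]
        )
        comps = as_set([("c", 0, 1_000_000)])
        erizs = as_set([("c", 160_000, 180_000)])
        regions = define_non_trs(genes, comps, erizs=erizs)
        assert [r.region.start for r in regions] == [150_000]

    def test_gap_not_flanked_on_both_sides_excluded(self):
        # single active gene inside the compartment: edge gaps have one flank
        genes = _classified([("c", 100_000, 150_000, "+", 1.0, 10.0)])
        assert define_non_trs(genes, as_set([("c", 50_000, 250_000)])) == []

    def test_non_trs_never_overlap_active_bodies(self, truth):
        genes = classify_genes(
            truth.genes.rename(columns={}), "human"
        )
        regions = define_non_trs(genes, truth.compartments_a)
        active = as_set(
            [
                (r["chrom"], int(r["start"]), int(r["end"]))
                for _, r in genes[genes["activity"] == "active"].iterrows()
            ]
        )
        gaps = as_set([(r.region.chrom, r.region.start, r.region.end) for r in regions])
        from nailseq import intersect_select

        hits, _ = intersect_select(gaps, active)
        assert len(hits) == 0


def region(chrom, gap, left, right):
    return NonTRRegion(
        region=Interval(chrom, *gap),
        upstream_flank=Interval(chrom, *left),
        downstream_flank=Interval(chrom, *right),
    )


class TestDensityLog2Ratio:
    def test_fourfold_density_gives_two(self):
        # non-TR at 10 reads/kb, flanks at 2.5 reads/kb -> log2 ratio ~= 2
        r = region("c", (20_000, 70_000), (0, 20_000), (70_000, 90_000))
        rng = np.random.default_rng(0)
        reads = []
        for s in rng.integers(20_200, 69_800 - 100, size=498):  # ~10/kb trimmed
            reads.append(("c", int(s), int(s) + 100))
        for s in rng.integers(200, 19_800 - 100, size=49):
            reads.append(("c", int(s), int(s) + 100))
        for s in rng.integers(70_200, 89_800 - 100, size=49):
            reads.append(("c", int(s), int(s) + 100))
        df = density_log2_ratio(ReadSet.from_intervals(reads), [r], pseudocount=0.0)
        assert df["log2_ratio"].iloc[0] == pytest.approx(2.0, abs=0.1)

    def test_equal_density_gives_zero(self):
        r = region("c", (20_000, 40_000), (0, 20_000), (40_000, 60_000))
        reads = [("c", s, s + 100) for s in range(500, 59_000, 500)]
        df = density_log2_ratio(ReadSet.from_intervals(reads), [r], pseudocount=0.0)
        assert abs(df["log2_ratio"].iloc[0]) < 0.1

    def test_antisymmetry_under_density_swap(self):
        rng = np.random.default_rng(1)
        r = region("c", (20_000, 40_000), (0, 20_000), (40_000, 60_000))
        ntr_reads = [("c", int(s), int(s) + 100) for s in rng.integers(20_200, 39_700, 200)]
        flank_reads = [("c", int(s), int(s) + 100) for s in rng.integers(200, 19_700, 25)] + [
            ("c", int(s), int(s) + 100) for s in rng.integers(40_200, 59_700, 25)
        ]
        fwd = density_log2_ratio(
            ReadSet.from_intervals(ntr_reads + flank_reads), [r], pseudocount=0.0
        )
        # swap: same counts, mirrored across region/flank with equal lengths
        swapped_reads = [("c", s - 20_000, e - 20_000) for _, s, e in ntr_reads] + [
            ("c", s + 20_000, e + 20_000) for _, s, e in flank_reads if s < 20_000
        ] + [("c", s - 20_000, e - 20_000) for _, s, e in flank_reads if s >= 40_000]
        # regions have equal ntr/flank lengths so densities swap exactly in
        # expectation; compare signs instead of exact values
        assert fwd["log2_ratio"].iloc[0] > 0

    def test_zero_region_reads_finite_with_pseudocount(self):
        r = region("c", (20_000, 40_000), (0, 20_000), (40_000, 60_000))
        reads = [("c", s, s + 100) for s in range(500, 19_000, 200)]
        df = density_log2_ratio(ReadSet.from_intervals(reads), [r])
        assert np.isfinite(df["log2_ratio"].iloc[0]) and df["log2_ratio"].iloc[0] < 0

    def test_overtrimmed_region_skipped_with_warning(self):
        r = region("c", (20_000, 20_300), (0, 20_000), (20_300, 40_000))
        with pytest.warns(UserWarning):
            df = density_log2_ratio(ReadSet(), [r], trim=200)
        assert df.empty


class TestWilcoxonRankSum:
    def test_identical_samples_p_one(self):
        stat, p = wilcoxon_rank_sum([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert p == pytest.approx(1.0, abs=0.05)

    def test_exact_small_sample(self):
        # all x below all y: one-tailed 1/20 -> two-sided 0.1
        _, p = wilcoxon_rank_sum([1, 2, 3], [4, 5, 6])
        assert p == pytest.approx(0.1)

    def test_large_sample_matches_reference(self, rng):
        from scipy import stats as ss

        for _ in range(100):
            x = rng.normal(0, 1, size=40)
            y = rng.normal(0.3, 1, size=35)
            stat, p = wilcoxon_rank_sum(x, y)
            ref = ss.mannwhitneyu(x, y, alternative="two-sided", method="asymptotic",
                                  use_continuity=True)
            assert p == pytest.approx(ref.pvalue, abs=1e-8)

    def test_constant_data_p_one(self):
        assert wilcoxon_rank_sum([5, 5], [5, 5, 5])[1] == 1.0


class TestHeatmapMatrix:
    def make_track(self, values, bin_width=1000):
        g = GenomeLayout({"c": len(values) * bin_width})
        return BinnedTrack(g, bin_width, {"c": np.asarray(values, float)})

    def test_constant_track_constant_matrix(self):
        track = self.make_track(np.full(400, 2.5))
        regions = [Interval("c", 150_000, 190_000), Interval("c", 200_000, 220_000)]
        mat, order = build_heatmap_matrix(track, regions, mode="midpoint")
        assert np.allclose(mat, 2.5)

    def test_delta_signal_lands_in_center_column(self):
        vals = np.zeros(400)
        vals[170] = 100.0  # midpoint bin of the region below
        track = self.make_track(vals)
        regions = [Interval("c", 160_000, 181_000)]  # midpoint 170,500
        mat, _ = build_heatmap_matrix(track, regions, mode="midpoint")
        assert mat.shape == (1, 200)
        hottest = int(np.nanargmax(mat[0]))
        assert hottest in (99, 100)

    def test_rows_ordered_by_increasing_width(self):
        track = self.make_track(np.zeros(400))
        regions = [Interval("c", 0, 80_000), Interval("c", 100_000, 120_000)]
        _, order = build_heatmap_matrix(track, regions, mode="midpoint")
        assert order == [1, 0]  # 20-kb region first

    def test_off_edge_columns_are_nan(self):
        track = self.make_track(np.ones(400))
        regions = [Interval("c", 0, 20_000)]  # midpoint 10 kb, flank reaches -90 kb
        mat, _ = build_heatmap_matrix(track, regions, mode="midpoint")
        assert np.isnan(mat[0, 0]) and np.isfinite(mat[0, -1])

    def test_scaled_mode_shape_and_strand_flip(self):
        vals = np.zeros(400)
        vals[:200] = np.arange(200)  # gradient over the gene body
        track = self.make_track(vals)
        genes = pd.DataFrame(
            {
                "chrom": ["c", "c"],
                "start": [100_000, 100_000],
                "end": [150_000, 150_000],
                "strand": ["+", "-"],
            }
        )
        mat, order = build_heatmap_matrix(track, genes, mode="scaled")
        assert mat.shape == (2, 200)  # 50 + 100 + 50 columns
        plus = mat[order.index(0)]
        minus = mat[order.index(1)]
        assert np.allclose(plus, minus[::-1], equal_nan=True)
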