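"""Peak callers: island chaining, dEB seed/extend traces, Poisson scan rules,
replicate support, and the ERIZ partition."""

from __future__ import annotations

import numpy as np
import pytest

from nailseq import (
    BinnedTrack,
    EBParams,
    GenomeLayout,
    IntervalSet,
    IslandParams,
    PoissonScanParams,
    ReadSet,
    call_eb_peaks,
    call_islands,
    call_poisson_peaks,
    define_erizs,
    overlap_fractions,
    reproducible_peaks,
)

from .bruteforce import as_set, set_to_list


def uniform_reads(rng, chrom, length, rate_per_bp, extra_regions=()):
    """Poisson background plus optional (start, end, rate) enrichments."""
    n = rng.poisson(rate_per_bp * length)
    starts = rng.integers(0, length - 100, size=n).tolist()
    for s, e, rate in extra_regions:
        m = rng.poisson(rate * (e - s))
        starts += rng.integers(s, e - 100, size=m).tolist()
    return ReadSet.from_intervals([(chrom, int(s), int(s) + 100) for s in starts])


class TestCallIslands:
    def test_single_hot_window_becomes_island(self):
        g = GenomeLayout({"c": 100_000})
        rng = np.random.default_rng(0)
        reads = uniform_reads(rng, "c", 100_000, 20 / 5000,
                              extra_regions=[(50_000, 55_000, 1000 / 5000)])
        islands = call_islands(reads, g, IslandParams())
        assert any(iv.start <= 50_000 and iv.end >= 55_000 for iv in islands)

    @pytest.mark.parametrize("sep_windows,expected_islands", [(3, 1), (4, 2)])
    def test_gap_chaining(self, sep_windows, expected_islands):
        # two hot 5-kb windows separated by `sep_windows` cold windows
        g = GenomeLayout({"c": 200_000})
        rng = np.random.default_rng(1)
        w2 = 5000 * (1 + sep_windows)
        reads = uniform_reads(
            rng, "c", 200_000, 2 / 5000,
            extra_regions=[(0, 5000, 500 / 5000), (w2, w2 + 5000, 500 / 5000)],
        )
        islands = call_islands(reads, g, IslandParams(gap=3))
        assert len(islands) == expected_islands

    def test_eligible_fraction_bounded_under_uniform_background(self):
        g = GenomeLayout({"c": 10_000_000})
        fracs = []
        for seed in range(5):
            rng = np.random.default_rng(seed)
            reads = uniform_reads(rng, "c", 10_000_000, 50 / 5000)
            islands = call_islands(reads, g, IslandParams(significance=1e-2, gap=0))
            fracs.append(sum(iv.width for iv in islands) / 10_000_000)
        assert np.mean(fracs) <= 1e-2

    def test_zero_reads_rejected(self):
        with pytest.raises(ValueError):
            call_islands(ReadSet(), GenomeLayout({"c": 10_000}), IslandParams())


def delta_track(deltas, bin_width=5000):
    g = GenomeLayout({"c": len(deltas) * bin_width})
    return BinnedTrack(g, bin_width, {"c": np.asarray(deltas, float)}, units="delta_rpm")


def whole_chrom_island(track):
    return as_set([("c", 0, track.genome.length("c"))])


class TestCallEBPeaks:
    def test_no_seeds_no_peaks(self):
        track = delta_track([0.1, 0.2, 0.3, 0.25, 0.1, 0.0, -0.1, 0.2])
        assert len(call_eb_peaks(track, whole_chrom_island(track))) == 0

    def test_hand_traced_seed_extend(self):
        # seeds at bins 3 and 5 (1-based 3,5); extension spans bins 2-7
        track = delta_track([-0.1, 0.1, 0.4, 0.2, 0.5, 0.1, 0.05, -0.2])
        peaks = call_eb_peaks(track, whole_chrom_island(track))
        assert set_to_list(peaks) == [("c", 5000, 35000)]  # 30 kb > 20 kb

    def test_isolated_seed_bin_dropped_by_length(self):
        track = delta_track([-0.1, 0.0, 0.6, -0.3, 0.0, -0.1, 0.0, 0.0])
        assert len(call_eb_peaks(track, whole_chrom_island(track))) == 0

    def test_island_containment_required(self):
        track = delta_track([-0.1, 0.1, 0.4, 0.2, 0.5, 0.1, 0.05, -0.2])
        # island covers only one bin of the 30-kb region -> below 50 %
        small_island = as_set([("c", 5000, 10000)])
        assert len(call_eb_peaks(track, small_island)) == 0

    def test_peaks_are_maximal_positive_runs_with_a_seed(self, rng):
        deltas = rng.normal(0.05, 0.3, size=200)
        track = delta_track(deltas)
        peaks = call_eb_peaks(
            track, whole_chrom_island(track), EBParams(min_length=5000)
        )
        for iv in peaks:
            bins = slice(iv.start // 5000, iv.end // 5000)
            assert np.all(deltas[bins] > 0)
            assert np.any(deltas[bins] > 0.3)
            if iv.start > 0:
                assert deltas[iv.start // 5000 - 1] <= 0
            if iv.end < track.genome.length("c"):
                assert deltas[iv.end // 5000] <= 0


class TestReproduciblePeaks:
    def test_identical_replicates_pass_through(self):
        s = as_set([("c", 0, 30_000), ("c", 100_000, 140_000)])
        assert set_to_list(reproducible_peaks([s, s])) == set_to_list(s)

    def test_replicate_specific_peak_excluded(self):
        r1 = as_set([("c", 0, 30_000), ("c", 500_000, 530_000)])
        r2 = as_set([("c", 10_000, 40_000)])
        out = reproducible_peaks([r1, r2])
        assert all(iv.start < 100_000 for iv in out)

    def test_supported_peaks_union_extent(self):
        r1 = as_set([("c", 0, 30_000)])
        r2 = as_set([("c", 25_000, 60_000)])
        assert set_to_list(reproducible_peaks([r1, r2])) == [("c", 0, 60_000)]

    def test_too_few_replicates_rejected(self):
        with pytest.raises(ValueError):
            reproducible_peaks([as_set([("c", 0, 10)])], min_support=2)


class TestCallPoissonPeaks:
    def test_planted_region_recovered_and_background_clean(self):
        g = GenomeLayout({"c": 20_000_000})
        rng = np.random.default_rng(3)
        reads = uniform_reads(
            rng, "c", 20_000_000, 0.2 / 1000,
            extra_regions=[(10_000_000, 10_060_000, 100 / 1000)],
        )
        peaks = call_poisson_peaks(reads, g, PoissonScanParams())
        assert len(peaks) == 1
        iv = next(iter(peaks))
        inter = min(iv.end, 10_060_000) - max(iv.start, 10_000_000)
        union = max(iv.end, 10_060_000) - min(iv.start, 10_000_000)
        assert inter / union >= 0.9

    def test_low_fold_plant_filtered_out(self):
        # 100x background fails the 400-fold rule even though the scan finds it
        g = GenomeLayout({"c": 20_000_000})
        rng = np.random.default_rng(4)
        reads = uniform_reads(
            rng, "c", 20_000_000, 0.2 / 1000,
            extra_regions=[(5_000_000, 5_060_000, 20 / 1000)],
        )
        assert len(call_poisson_peaks(reads, g, PoissonScanParams())) == 0

    def test_merge_then_size_filter(self):
        # passing candidate bins 9.5 kb apart merge (<10 kb); an isolated 8-kb
        # region dies by the min-size rule
        g = GenomeLayout({"c": 10_000_000})
        rng = np.random.default_rng(5)
        reads = uniform_reads(
            rng, "c", 10_000_000, 0.1 / 1000,
            extra_regions=[
                (1_000_000, 1_020_000, 200 / 1000),
                (1_029_500, 1_049_500, 200 / 1000),
                (3_000_000, 3_008_000, 200 / 1000),
            ],
        )
        peaks = call_poisson_peaks(reads, g, PoissonScanParams())
        assert len(peaks) == 1
        iv = next(iter(peaks))
        assert iv.start < 1_020_000 and iv.end > 1_029_500

    def test_blacklist_and_chrom_exclusion(self):
        g = GenomeLayout({"c": 5_000_000, "chrY": 5_000_000})
        rng = np.random.default_rng(6)
        hot = [(1_000_000, 1_050_000, 200 / 1000)]
        reads_c = uniform_reads(rng, "c", 5_000_000, 0.1 / 1000, hot)
        reads_y = uniform_reads(rng, "chrY", 5_000_000, 0.1 / 1000, hot)
        merged = ReadSet(
            {"c": reads_c.arrays("c"), "chrY": reads_y.arrays("chrY")}
        )
        peaks = call_poisson_peaks(merged, g, PoissonScanParams())
        assert [iv.chrom for iv in peaks] == ["c"]
        bl = as_set([("c", 1_040_000, 1_060_000)])
        peaks_bl = call_poisson_peaks(merged, g, PoissonScanParams(blacklist=bl))
        assert len(peaks_bl) == 0

    def test_zero_reads_rejected(self):
        with pytest.raises(ValueError):
            call_poisson_peaks(ReadSet(), GenomeLayout({"c": 10_000}))


class TestDefineErizs:
    def test_partition_is_exact(self):
        eduhu = as_set([("c", 0, 50_000), ("c", 100_000, 160_000), ("c", 300_000, 350_000)])
        eb = as_set([("c", 40_000, 70_000)])
        res = define_erizs(eduhu, eb)
        assert set_to_list(res.erizs) == [("c", 0, 50_000)]
        assert sorted(set_to_list(res.erizs) + set_to_list(res.non_erizs)) == set_to_list(eduhu)

    def test_empty_eb_all_non_eriz(self):
        eduhu = as_set([("c", 0, 50_000)])
        res = define_erizs(eduhu, IntervalSet())
        assert res.n_eriz == 0 and res.n_non_eriz == 1

    def test_constant_timing_labels_early(self):
        g = GenomeLayout({"c": 200_000})
        timing = BinnedTrack(g, 5000, {"c": np.full(40, 0.6)}, units="timing")
        res = define_erizs(as_set([("c", 0, 50_000)]), as_set([("c", 0, 10_000)]), timing)
        assert (res.table["timing_label"] == "early").all()
        assert res.table["timing"].iloc[0] == pytest.approx(0.6)


class TestOverlapFractions:
    def test_identical_sets(self):
        s = as_set([("c", 0, 10), ("c", 20, 30)])
        assert overlap_fractions(s, s) == (1.0, 1.0)

    def test_asymmetric_counts(self):
        a = as_set([("c", 0, 10), ("c", 20, 30)])
        b = as_set([("c", 0, 10)])
        assert overlap_fractions(a, b) == (0.5, 1.0)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            overlap_fractions(IntervalSet(), as_set([("c", 0, 10)]))
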