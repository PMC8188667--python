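"""Replication-initiation peak callers and the ERIZ definition.

Three callers cooperate:

* :func:`call_islands` — broad EdU-enriched territory from a window/gap
  chaining scan (eligible 5-kb windows with Poisson-significant counts,
  chained across short ineligible gaps).
* :func:`call_eb_peaks` — dual-label initiation peaks from the per-bin
  difference dEB = E − B of RPM-normalized first-label (EdU) and
  second-label (BrdU) coverage: bins with dEB above a seed threshold are
  extended through neighbouring dEB > 0 bins, and regions longer than a
  minimum size that fall inside EdU islands are kept.
* :func:`call_poisson_peaks` — sharply localized peaks from EdU/HU
  (hydroxyurea-stalled) coverage: a fixed-bin scan against a global
  Poisson rate, followed by a strong fold-enrichment filter, gap merging,
  a size filter and blacklist/chromosome exclusions.

An early replication initiation zone (ERIZ) is an EdU/HU peak that
overlaps a dual-label E−B peak; :func:`define_erizs` performs the
partition and attaches replication-timing labels.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .genome import GenomeLayout
from .intervals import IntervalSet, _coverage_in, intersect_select, merge_within
from .tracks import BinnedTrack, ReadSet, bin_reads, mean_over

__all__ = [
    "IslandParams",
    "EBParams",
    "PoissonScanParams",
    "ERIZResult",
    "call_islands",
    "eb_delta",
    "call_eb_peaks",
    "reproducible_peaks",
    "call_poisson_peaks",
    "define_erizs",
    "overlap_fractions",
]


@dataclass
class IslandParams:
    """Window/gap island scan settings (SICER-style -w 5000 -g 3)."""

    window: int = 5000
    gap: int = 3  # ineligible windows tolerated between eligible ones
    significance: float = 1e-5  # Poisson upper-tail level for eligibility

    def __post_init__(self) -> None:
        if self.window <= 0:
            raise ValueError("window must be positive")
        if self.gap < 0:
            raise ValueError("gap must be >= 0")
        if not 0 < self.significance < 1:
            raise ValueError("significance must be in (0, 1)")


@dataclass
class EBParams:
    """Dual-label caller settings (all dEB values in RPM units)."""

    bin_width: int = 5000
    seed_threshold: float = 0.3  # dEB above this seeds a peak
    extend_threshold: float = 0.0  # extension continues while dEB > this
    min_length: int = 20000  # regions must be strictly longer
    min_island_coverage: float = 0.5  # fraction of region inside islands
    min_replicates: int = 2

    def __post_init__(self) -> None:
        if self.seed_threshold <= self.extend_threshold:
            raise ValueError("seed_threshold must exceed extend_threshold")
        if self.min_length <= 0:
            raise ValueError("min_length must be positive")
        if not 0 <= self.min_island_coverage <= 1:
            raise ValueError("min_island_coverage must be in [0, 1]")


@dataclass
class PoissonScanParams:
    """EdU/HU scan settings (MACS14 -p 1e-5 --nolambda surrogate + filters)."""

    scan_bin_width: int = 1000
    p_threshold: float = 1e-5
    min_fold: float = 400.0
    merge_gap: int = 10000  # 10 kb (K562 convention); 20 kb for GM12878
    min_size: int = 10000  # merged peaks strictly below this are discarded
    excluded_chroms: tuple[str, ...] = ("chrY", "chrM")
    blacklist: IntervalSet | None = None

    def __post_init__(self) -> None:
        if not 0 < self.p_threshold < 1:
            raise ValueError("p_threshold must be in (0, 1)")
        if self.min_fold <= 0:
            raise ValueError("min_fold must be positive")


@dataclass
class ERIZResult:
    """EdU/HU peaks partitioned into ERIZs / non-ERIZs with timing labels."""

    erizs: IntervalSet
    non_erizs: IntervalSet
    table: pd.DataFrame = field(repr=False)

    @property
    def n_eriz(self) -> int:
        return len(self.erizs)

    @property
    def n_non_eriz(self) -> int:
        return len(self.non_erizs)


def _runs(mask: np.ndarray) -> list[tuple[int, int]]:
    """Maximal runs of True as (first, last) index pairs."""
    if not mask.any():
        return []
    idx = np.flatnonzero(mask)
    breaks = np.flatnonzero(np.diff(idx) > 1)
    starts = np.concatenate([[idx[0]], idx[breaks + 1]])
    ends = np.concatenate([idx[breaks], [idx[-1]]])
    return list(zip(starts.tolist(), ends.tolist()))


def call_islands(
    edu_reads: ReadSet, genome: GenomeLayout, params: IslandParams | None = None
) -> IntervalSet:
    """Chain Poisson-significant windows into broad enriched islands.

    A window is eligible when its read count is significant against the
    genome-wide mean rate (upper-tail Poisson p below
    ``params.significance``). Eligible windows separated by at most
    ``params.gap`` ineligible windows join one island; the island spans
    from its first to its last eligible window.
    """
    params = params or IslandParams()
    track = bin_reads(edu_reads, genome, params.window)
    total = track.total_reads or 0
    if total == 0:
        raise ValueError("cannot call islands with zero reads")
    n_bins = sum(track.n_bins(c) for c in genome)
    lam = total / n_bins
    out: dict[str, list[tuple[int, int]]] = {}
    for chrom in genome:
        counts = track.values[chrom]
        # P(X >= c) = sf(c - 1)
        eligible = stats.poisson.sf(counts - 1, lam) < params.significance
        idx = np.flatnonzero(eligible)
        if idx.size == 0:
            continue
        breaks = np.flatnonzero(np.diff(idx) > params.gap + 1)
        firsts = np.concatenate([[idx[0]], idx[breaks + 1]])
        lasts = np.concatenate([idx[breaks], [idx[-1]]])
        chrom_len = genome.length(chrom)
        out[chrom] = [
            (int(f) * params.window, min((int(l) + 1) * params.window, chrom_len))
            for f, l in zip(firsts, lasts)
        ]
    return IntervalSet.from_intervals(
        (c, s, e) for c, ivs in out.items() for s, e in ivs
    )


def eb_delta(e_rpm: BinnedTrack, b_rpm: BinnedTrack) -> BinnedTrack:
    """Per-bin difference dEB = E − B of two RPM tracks on a shared grid."""
    if not e_rpm.same_grid(b_rpm):
        raise ValueError("E and B tracks must share the bin grid")
    values = {c: e_rpm.values[c] - b_rpm.values[c] for c in e_rpm.genome}
    return BinnedTrack(e_rpm.genome, e_rpm.bin_width, values, units="delta_rpm")


def call_eb_peaks(
    delta: BinnedTrack,
    islands: IntervalSet,
    params: EBParams | None = None,
) -> IntervalSet:
    """Seed-and-extend caller on the dEB track.

    Bins with dEB above ``seed_threshold`` seed regions; each seed extends
    left and right through contiguous bins with dEB above
    ``extend_threshold`` (strict). Overlapping extensions merge. Regions
    strictly longer than ``min_length`` whose island coverage reaches
    ``min_island_coverage`` are returned.
    """
    params = params or EBParams()
    if delta.bin_width != params.bin_width:
        raise ValueError(
            f"delta track bin width {delta.bin_width} != params.bin_width "
            f"{params.bin_width}"
        )
    genome = delta.genome
    islands_union = islands.union()
    kept: list[tuple[str, int, int]] = []
    for chrom in genome:
        vals = delta.values[chrom]
        positive = vals > params.extend_threshold
        chrom_len = genome.length(chrom)
        for first, last in _runs(positive):
            if not np.any(vals[first : last + 1] > params.seed_threshold):
                continue
            start = first * params.bin_width
            end = min((last + 1) * params.bin_width, chrom_len)
            if end - start <= params.min_length:
                continue
            cov = _coverage_in(islands_union.arrays(chrom), start, end)
            if cov / (end - start) >= params.min_island_coverage:
                kept.append((chrom, start, end))
    return IntervalSet.from_intervals(kept)


def reproducible_peaks(
    replicate_peak_sets: list[IntervalSet], min_support: int = 2
) -> IntervalSet:
    """Union of peaks supported by at least ``min_support`` replicates.

    A peak counts as supported when it overlaps (>= 1 bp) a peak in at
    least ``min_support − 1`` other replicates; supported peaks from all
    replicates are merged into one coverage set.
    """
    if min_support < 1:
        raise ValueError("min_support must be >= 1")
    if len(replicate_peak_sets) < min_support:
        raise ValueError(
            f"need at least {min_support} replicate sets, got {len(replicate_peak_sets)}"
        )
    supported: list[IntervalSet] = []
    for i, peaks in enumerate(replicate_peak_sets):
        if len(peaks) == 0:
            continue
        others = [s for j, s in enumerate(replicate_peak_sets) if j != i]
        hit_counts = np.zeros(len(peaks), dtype=int)
        for other in others:
            hits, _ = intersect_select(peaks, other)
            # count per-element support via membership in hits
            hit_set = {iv for iv in hits}
            for k, iv in enumerate(peaks):
                if iv in hit_set:
                    hit_counts[k] += 1
        keep = [iv for k, iv in enumerate(peaks) if hit_counts[k] >= min_support - 1]
        supported.append(IntervalSet.from_intervals(keep))
    if not supported:
        return IntervalSet()
    merged = IntervalSet.from_intervals(
        iv for s in supported for iv in s
    ).union()
    return merged


def call_poisson_peaks(
    reads: ReadSet,
    genome: GenomeLayout,
    params: PoissonScanParams | None = None,
) -> IntervalSet:
    """Fixed-bin Poisson scan with a strong fold-enrichment filter.

    Scan bins whose counts are upper-tail significant against the global
    Poisson rate become candidates; adjacent candidates fuse into
    candidate peaks. Each candidate peak's fold enrichment is its read
    density over the background density (mean density of non-candidate
    bins, so that massive peaks do not inflate their own background).
    Peaks with fold >= ``min_fold`` are gap-merged, size-filtered, and
    purged of excluded chromosomes and blacklist overlaps.
    """
    params = params or PoissonScanParams()
    bw = params.scan_bin_width
    track = bin_reads(reads, genome, bw)
    total = track.total_reads or 0
    if total == 0:
        raise ValueError("cannot call peaks with zero reads (rate undefined)")
    n_bins = sum(track.n_bins(c) for c in genome)
    lam = total / n_bins

    candidate_peaks: list[tuple[str, int, int, float]] = []  # chrom, start, end, count
    bg_reads = 0.0
    bg_bins = 0
    for chrom in genome:
        counts = track.values[chrom]
        candidate = stats.poisson.sf(counts - 1, lam) < params.p_threshold
        bg_reads += counts[~candidate].sum()
        bg_bins += int((~candidate).sum())
        chrom_len = genome.length(chrom)
        for first, last in _runs(candidate):
            start = first * bw
            end = min((last + 1) * bw, chrom_len)
            candidate_peaks.append(
                (chrom, start, end, float(counts[first : last + 1].sum()))
            )
    if bg_bins == 0:
        raise ValueError("no background bins left to estimate the Poisson rate")
    bg_density = bg_reads / (bg_bins * bw)  # reads per bp outside candidates
    if bg_density == 0:
        raise ValueError("zero background density (rate undefined)")

    passing = [
        (chrom, s, e)
        for chrom, s, e, c in candidate_peaks
        if (c / (e - s)) / bg_density >= params.min_fold
    ]
    peaks = merge_within(IntervalSet.from_intervals(passing), params.merge_gap)
    peaks = IntervalSet.from_intervals(
        iv
        for iv in peaks
        if iv.width >= params.min_size and iv.chrom not in params.excluded_chroms
    )
    if params.blacklist is not None and len(params.blacklist):
        _, peaks = intersect_select(peaks, params.blacklist)
    return peaks


def define_erizs(
    eduhu_peaks: IntervalSet,
    eb_peaks: IntervalSet,
    timing: BinnedTrack | None = None,
    early_cut: float = 0.5,
) -> ERIZResult:
    """Partition EdU/HU peaks into ERIZs (overlapping E−B peaks) and non-ERIZs.

    When a replication-timing track is provided, each peak is annotated
    with its length-weighted mean timing value and labelled ``early`` when
    the mean is strictly above ``early_cut``, ``late`` otherwise
    (``unknown`` without a timing value).
    """
    erizs, non_erizs = intersect_select(eduhu_peaks, eb_peaks)
    rows = []
    for is_eriz, group in ((True, erizs), (False, non_erizs)):
        for iv in group:
            if timing is not None:
                t = mean_over(timing, iv)
                label = "unknown" if np.isnan(t) else ("early" if t > early_cut else "late")
            else:
                t, label = np.nan, "unknown"
            rows.append((iv.chrom, iv.start, iv.end, is_eriz, t, label))
    table = pd.DataFrame(
        rows, columns=["chrom", "start", "end", "is_eriz", "timing", "timing_label"]
    )
    return ERIZResult(erizs=erizs, non_erizs=non_erizs, table=table)


def overlap_fractions(a: IntervalSet, b: IntervalSet) -> tuple[float, float]:
    """Fraction of a's elements overlapping b, and vice versa."""
    if len(a) == 0 or len(b) == 0:
        raise ValueError("overlap_fractions requires two non-empty sets")
    hits_a, _ = intersect_select(a, b)
    hits_b, _ = intersect_select(b, a)
    return len(hits_a) / len(a), len(hits_b) / len(b)
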