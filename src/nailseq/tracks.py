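"""Binned coverage tracks and the pipeline's normalizations.

A :class:`BinnedTrack` holds one value per fixed-width bin per chromosome
(the last bin of each chromosome may be short). Reads are assigned to bins
by their fragment midpoint, which conserves the total read count and is
insensitive to fragment length at the bin scales used here (1–5 kb).

Units supported: raw ``count``, ``RPM`` (reads per million), ``RPK``
(reads per kilobase, optionally library-scaled), ``RPKM``, ``fold_change``
and ``zscore``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import numpy as np

from .genome import GenomeLayout
from .intervals import Interval, IntervalSet

__all__ = [
    "ReadSet",
    "BinnedTrack",
    "bin_reads",
    "normalize",
    "fold_change",
    "zscore",
    "mean_over",
    "read_bedgraph",
]

#: chromosomes excluded from genome-wide statistics, mirroring the
#: peak-calling exclusions (sex chromosome Y and the mitochondrial genome)
DEFAULT_EXCLUDED_CHROMS = ("chrY", "chrM")


class ReadSet:
    """Aligned read/fragment positions as per-chromosome (start, end) arrays."""

    def __init__(self, by_chrom: dict[str, np.ndarray] | None = None):
        self._by_chrom: dict[str, np.ndarray] = {}
        if by_chrom:
            for chrom, arr in by_chrom.items():
                arr = np.asarray(arr, dtype=np.int64).reshape(-1, 2)
                if arr.size:
                    self._by_chrom[chrom] = arr

    @classmethod
    def from_intervals(cls, reads: Iterable[tuple[str, int, int]]) -> "ReadSet":
        by_chrom: dict[str, list] = {}
        for chrom, start, end in reads:
            by_chrom.setdefault(chrom, []).append((start, end))
        return cls({c: np.asarray(v, dtype=np.int64) for c, v in by_chrom.items()})

    @classmethod
    def read_bed(cls, path: str | Path) -> "ReadSet":
        by_chrom: dict[str, list] = {}
        with open(path) as fh:
            for line in fh:
                if not line.strip() or line.startswith(("#", "track", "browser")):
                    continue
                fields = line.split("\t")
                by_chrom.setdefault(fields[0], []).append(
                    (int(fields[1]), int(fields[2]))
                )
        return cls({c: np.asarray(v, dtype=np.int64) for c, v in by_chrom.items()})

    def write_bed(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for chrom in sorted(self._by_chrom):
                for s, e in self._by_chrom[chrom]:
                    fh.write(f"{chrom}\t{s}\t{e}\n")

    @property
    def chroms(self) -> list[str]:
        return list(self._by_chrom)

    def arrays(self, chrom: str) -> np.ndarray:
        return self._by_chrom.get(chrom, np.empty((0, 2), dtype=np.int64))

    def midpoints(self, chrom: str) -> np.ndarray:
        arr = self.arrays(chrom)
        return (arr[:, 0] + arr[:, 1]) // 2

    def __len__(self) -> int:
        return sum(arr.shape[0] for arr in self._by_chrom.values())

    def count_in(self, chrom: str, start: int, end: int) -> int:
        """Reads whose midpoint falls in [start, end)."""
        mids = self.midpoints(chrom)
        return int(np.count_nonzero((mids >= start) & (mids < end)))

    def subset(self, regions: IntervalSet) -> int:
        """Total reads whose midpoint falls inside ``regions`` (union)."""
        total = 0
        u = regions.union()
        for chrom in u.chroms:
            mids = np.sort(self.midpoints(chrom))
            for s, e in u.arrays(chrom):
                lo = np.searchsorted(mids, s, side="left")
                hi = np.searchsorted(mids, e, side="left")
                total += hi - lo
        return total


@dataclass
class BinnedTrack:
    """Fixed-width per-chromosome bin values."""

    genome: GenomeLayout
    bin_width: int
    values: dict[str, np.ndarray]
    units: str = "count"
    total_reads: int | None = field(default=None)

    def __post_init__(self) -> None:
        if self.bin_width <= 0:
            raise ValueError("bin_width must be positive")
        for chrom in self.genome:
            n = self.n_bins(chrom)
            if chrom not in self.values:
                self.values[chrom] = np.zeros(n)
            elif len(self.values[chrom]) != n:
                raise ValueError(
                    f"{chrom}: expected {n} bins, got {len(self.values[chrom])}"
                )

    def n_bins(self, chrom: str) -> int:
        return -(-self.genome.length(chrom) // self.bin_width)

    def same_grid(self, other: "BinnedTrack") -> bool:
        return (
            self.bin_width == other.bin_width
            and self.genome.lengths == other.genome.lengths
        )

    def flat(self, exclude_chroms: tuple[str, ...] = ()) -> np.ndarray:
        return np.concatenate(
            [self.values[c] for c in self.genome if c not in exclude_chroms]
        )

    def bin_interval(self, chrom: str, i: int) -> Interval:
        start = i * self.bin_width
        end = min(start + self.bin_width, self.genome.length(chrom))
        return Interval(chrom, start, end)

    # ---- bedGraph I/O --------------------------------------------------

    def write_bedgraph(self, path: str | Path, skip_zero: bool = False) -> None:
        with open(path, "w") as fh:
            for chrom in self.genome:
                vals = self.values[chrom]
                length = self.genome.length(chrom)
                for i, v in enumerate(vals):
                    if skip_zero and v == 0:
                        continue
                    start = i * self.bin_width
                    end = min(start + self.bin_width, length)
                    fh.write(f"{chrom}\t{start}\t{end}\t{float(v)!r}\n")


def read_bedgraph(
    path: str | Path, genome: GenomeLayout, bin_width: int, units: str = "count"
) -> BinnedTrack:
    """Read a bedGraph whose records align to the given bin grid.

    Records may cover several bins (constant value spread over them);
    uncovered bins are zero.
    """
    values = {c: np.zeros(-(-genome.length(c) // bin_width)) for c in genome}
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            chrom, s, e, v = line.split("\t")[:4]
            if chrom not in genome:
                raise ValueError(f"bedGraph chromosome {chrom!r} not in genome")
            s, e = int(s), int(e)
            if s % bin_width != 0:
                raise ValueError(f"record start {s} not aligned to {bin_width}-bp grid")
            values[chrom][s // bin_width : -(-e // bin_width)] = float(v)
    return BinnedTrack(genome, bin_width, values, units=units)


def bin_reads(reads: ReadSet, genome: GenomeLayout, bin_width: int) -> BinnedTrack:
    """Count reads per bin, assigning each read by its fragment midpoint."""
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    values: dict[str, np.ndarray] = {}
    total = 0
    for chrom in genome:
        n = -(-genome.length(chrom) // bin_width)
        mids = reads.midpoints(chrom)
        if np.any((mids < 0) | (mids >= genome.length(chrom))):
            raise ValueError(f"read midpoint outside chromosome {chrom!r}")
        counts = np.bincount(mids // bin_width, minlength=n).astype(float)
        values[chrom] = counts
        total += int(counts.sum())
    unknown = set(reads.chroms) - set(genome.chrom_names)
    if unknown:
        raise ValueError(f"reads on chromosomes absent from genome: {sorted(unknown)}")
    return BinnedTrack(genome, bin_width, values, units="count", total_reads=total)


def normalize(
    track: BinnedTrack,
    mode: str = "rpm",
    library_scale: float | None = None,
) -> BinnedTrack:
    """Normalize a count track.

    mode="rpm"
        RPM_i = c_i * 1e6 / T with T the total read count.
    mode="rpk"
        RPK_i = c_i * 1e3 / bin_bp, optionally multiplied by
        ``library_scale / T`` (e.g. ``library_scale=1e7`` for densities
        normalized to 10 million reads).
    mode="rpkm"
        RPKM_i = c_i * 1e9 / (T * bin_bp).
    """
    if track.units != "count":
        raise ValueError("normalize expects a count track")
    total = track.total_reads
    if total is None:
        total = int(sum(v.sum() for v in track.values.values()))
    if total <= 0 and (mode in ("rpm", "rpkm") or library_scale is not None):
        raise ValueError("cannot normalize a track with zero total reads")

    values: dict[str, np.ndarray] = {}
    for chrom in track.genome:
        counts = track.values[chrom]
        n = len(counts)
        bin_bp = np.full(n, track.bin_width, dtype=float)
        bin_bp[-1] = track.genome.length(chrom) - (n - 1) * track.bin_width
        if mode == "rpm":
            values[chrom] = counts * 1e6 / total
        elif mode == "rpk":
            v = counts * 1e3 / bin_bp
            if library_scale is not None:
                v = v * (library_scale / total)
            values[chrom] = v
        elif mode == "rpkm":
            values[chrom] = counts * 1e9 / (total * bin_bp)
        else:
            raise ValueError(f"unknown normalization mode {mode!r}")
    return BinnedTrack(
        track.genome, track.bin_width, values, units=mode, total_reads=total
    )


def fold_change(
    treat: BinnedTrack, control: BinnedTrack, pseudocount: float = 1.0
) -> BinnedTrack:
    """Per-bin ratio (t_i + eps) / (c_i + eps) of two same-grid tracks."""
    if not treat.same_grid(control):
        raise ValueError("fold_change requires tracks on the same bin grid")
    if pseudocount < 0:
        raise ValueError("pseudocount must be >= 0")
    values = {}
    for chrom in treat.genome:
        denom = control.values[chrom] + pseudocount
        if pseudocount == 0 and np.any(denom == 0):
            raise ValueError("zero control bin with zero pseudocount")
        values[chrom] = (treat.values[chrom] + pseudocount) / denom
    return BinnedTrack(treat.genome, treat.bin_width, values, units="fold_change")


def zscore(
    track: BinnedTrack,
    exclude_chroms: tuple[str, ...] = DEFAULT_EXCLUDED_CHROMS,
    ddof: int = 0,
) -> BinnedTrack:
    """Genome-wide z-score transform (population sd by default).

    The mean and sd are computed jointly over all bins of the included
    chromosomes; excluded chromosomes are transformed with the same
    parameters so grids stay aligned.
    """
    flat = track.flat(exclude_chroms=tuple(c for c in exclude_chroms if c in track.genome))
    if len(flat) < 2:
        raise ValueError("zscore needs at least two bins")
    mu = float(np.mean(flat))
    sd = float(np.std(flat, ddof=ddof))
    if sd == 0:
        raise ValueError("zscore undefined for a constant track")
    values = {c: (track.values[c] - mu) / sd for c in track.genome}
    return BinnedTrack(track.genome, track.bin_width, values, units="zscore")


def mean_over(track: BinnedTrack, region: Interval) -> float:
    """Length-weighted mean of bin values over the bases of ``region``."""
    chrom_len = track.genome.length(region.chrom)
    if not (0 <= region.start < region.end <= chrom_len):
        raise ValueError(f"region {region} outside chromosome bounds")
    bw = track.bin_width
    vals = track.values[region.chrom]
    first = region.start // bw
    last = (region.end - 1) // bw
    idx = np.arange(first, last + 1)
    bin_starts = idx * bw
    bin_ends = np.minimum(bin_starts + bw, chrom_len)
    weights = np.minimum(bin_ends, region.end) - np.maximum(bin_starts, region.start)
    return float(np.average(vals[idx], weights=weights))
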