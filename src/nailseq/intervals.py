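"""Strandless genomic intervals (BED semantics) and exact set operations.

This is the workhorse data model of the package: peaks, initiation zones,
compartments and gene footprints are all :class:`IntervalSet` objects.
Coordinates are 0-based, half-open throughout; two intervals overlap iff
they share at least one base.
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable, Iterator, NamedTuple, Sequence

import numpy as np
import pandas as pd

from .genome import GenomeLayout

__all__ = [
    "Interval",
    "IntervalSet",
    "merge_within",
    "intersect_select",
    "subtract",
    "proximity_match",
    "shuffle_within_chrom",
    "fraction_width_in",
    "read_bed",
]


class Interval(NamedTuple):
    """A half-open genomic interval [start, end) on one chromosome."""

    chrom: str
    start: int
    end: int

    @property
    def width(self) -> int:
        return self.end - self.start

    @property
    def midpoint(self) -> int:
        return (self.start + self.end) // 2


def _as_array(pairs: Sequence[tuple[int, int]]) -> np.ndarray:
    arr = np.asarray(pairs, dtype=np.int64).reshape(-1, 2)
    return arr


class IntervalSet:
    """An ordered collection of intervals, sorted by (chrom, start).

    Elements are kept distinct (no implicit merging): a set of called peaks
    retains one element per peak even if peaks touch. Operations that need
    base-pair (coverage) semantics union their inputs internally.
    """

    def __init__(self, by_chrom: dict[str, np.ndarray] | None = None):
        self._by_chrom: dict[str, np.ndarray] = {}
        if by_chrom:
            for chrom in sorted(by_chrom):
                arr = _as_array(by_chrom[chrom])
                if arr.size:
                    if np.any(arr[:, 0] >= arr[:, 1]):
                        bad = arr[arr[:, 0] >= arr[:, 1]][0]
                        raise ValueError(
                            f"empty or inverted interval {chrom}:{bad[0]}-{bad[1]}"
                        )
                    if np.any(arr[:, 0] < 0):
                        raise ValueError(f"negative coordinate on {chrom}")
                    order = np.lexsort((arr[:, 1], arr[:, 0]))
                    self._by_chrom[chrom] = arr[order]

    # ---- construction -------------------------------------------------

    @classmethod
    def from_intervals(cls, intervals: Iterable[tuple[str, int, int]]) -> "IntervalSet":
        by_chrom: dict[str, list[tuple[int, int]]] = {}
        for chrom, start, end in intervals:
            by_chrom.setdefault(chrom, []).append((int(start), int(end)))
        return cls({c: _as_array(v) for c, v in by_chrom.items()})

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame) -> "IntervalSet":
        return cls.from_intervals(
            zip(df["chrom"], df["start"].astype(int), df["end"].astype(int))
        )

    # ---- basic protocol ------------------------------------------------

    def __len__(self) -> int:
        return sum(arr.shape[0] for arr in self._by_chrom.values())

    def __iter__(self) -> Iterator[Interval]:
        for chrom, arr in self._by_chrom.items():
            for start, end in arr:
                yield Interval(chrom, int(start), int(end))

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, IntervalSet):
            return NotImplemented
        if set(self._by_chrom) != set(other._by_chrom):
            return False
        return all(
            np.array_equal(self._by_chrom[c], other._by_chrom[c])
            for c in self._by_chrom
        )

    def __repr__(self) -> str:
        return f"IntervalSet({len(self)} intervals on {len(self._by_chrom)} chromosomes)"

    @property
    def chroms(self) -> list[str]:
        return list(self._by_chrom)

    def arrays(self, chrom: str) -> np.ndarray:
        """(n, 2) start/end array for one chromosome (empty if absent)."""
        return self._by_chrom.get(chrom, np.empty((0, 2), dtype=np.int64))

    def widths(self) -> np.ndarray:
        if not self._by_chrom:
            return np.empty(0, dtype=np.int64)
        return np.concatenate(
            [arr[:, 1] - arr[:, 0] for arr in self._by_chrom.values()]
        )

    def total_width(self) -> int:
        """Total base pairs covered (union semantics)."""
        merged = self.union()
        return int(merged.widths().sum())

    def union(self) -> "IntervalSet":
        """Coverage blocks: overlapping or touching elements fused."""
        out = {}
        for chrom, arr in self._by_chrom.items():
            out[chrom] = _fuse(arr, max_gap=0, inclusive=True)
        return IntervalSet(out)

    def to_dataframe(self) -> pd.DataFrame:
        rows = [(iv.chrom, iv.start, iv.end) for iv in self]
        return pd.DataFrame(rows, columns=["chrom", "start", "end"])

    # ---- I/O ----------------------------------------------------------

    def write_bed(
        self,
        path: str | Path,
        names: Sequence[str] | None = None,
        scores: Sequence[float] | None = None,
    ) -> None:
        """Write BED3 (or BED5 when names/scores are given)."""
        n = len(self)
        if names is not None and len(names) != n:
            raise ValueError("names length mismatch")
        if scores is not None and len(scores) != n:
            raise ValueError("scores length mismatch")
        with open(path, "w") as fh:
            for i, iv in enumerate(self):
                fields = [iv.chrom, str(iv.start), str(iv.end)]
                if names is not None or scores is not None:
                    fields.append(names[i] if names is not None else f"region_{i}")
                    fields.append(f"{scores[i]:g}" if scores is not None else "0")
                fh.write("\t".join(fields) + "\n")


def read_bed(path: str | Path) -> IntervalSet:
    """Read the first three columns of a BED file (comments/track lines skipped)."""
    intervals = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            intervals.append((fields[0], int(fields[1]), int(fields[2])))
    return IntervalSet.from_intervals(intervals)


# ---- primitive sweeps ---------------------------------------------------


def _fuse(arr: np.ndarray, max_gap: int, inclusive: bool) -> np.ndarray:
    """Fuse sorted intervals whose gap is < max_gap (or <= when inclusive)."""
    if arr.shape[0] == 0:
        return arr
    out = []
    cur_s, cur_e = int(arr[0, 0]), int(arr[0, 1])
    for s, e in arr[1:]:
        gap = int(s) - cur_e
        join = gap <= max_gap if inclusive else gap < max_gap
        if join:
            cur_e = max(cur_e, int(e))
        else:
            out.append((cur_s, cur_e))
            cur_s, cur_e = int(s), int(e)
    out.append((cur_s, cur_e))
    return _as_array(out)


def _overlap_mask(a_arr: np.ndarray, b_blocks: np.ndarray) -> np.ndarray:
    """Per element of a_arr: does it share >=1 bp with the disjoint b_blocks?"""
    if a_arr.shape[0] == 0:
        return np.zeros(0, dtype=bool)
    if b_blocks.shape[0] == 0:
        return np.zeros(a_arr.shape[0], dtype=bool)
    starts, ends = b_blocks[:, 0], b_blocks[:, 1]
    # last block starting before a.end
    idx = np.searchsorted(starts, a_arr[:, 1], side="left") - 1
    mask = idx >= 0
    hit = np.zeros(a_arr.shape[0], dtype=bool)
    hit[mask] = ends[idx[mask]] > a_arr[mask, 0]
    return hit


def _coverage_in(b_blocks: np.ndarray, start: int, end: int) -> int:
    """Base pairs of [start, end) covered by disjoint sorted b_blocks."""
    if b_blocks.shape[0] == 0:
        return 0
    lo = np.maximum(b_blocks[:, 0], start)
    hi = np.minimum(b_blocks[:, 1], end)
    return int(np.clip(hi - lo, 0, None).sum())


# ---- public operations ---------------------------------------------------


def merge_within(intervals: IntervalSet, max_gap: int) -> IntervalSet:
    """Merge neighbouring intervals separated by a gap strictly below ``max_gap``.

    Overlapping intervals always merge (negative gap); a gap exactly equal
    to ``max_gap`` does not. Merging is transitive along each chromosome.
    """
    if max_gap < 0:
        raise ValueError("max_gap must be >= 0")
    out = {}
    for chrom in intervals.chroms:
        out[chrom] = _fuse(intervals.arrays(chrom), max_gap, inclusive=False)
    return IntervalSet(out)


def intersect_select(
    a: IntervalSet, b: IntervalSet
) -> tuple[IntervalSet, IntervalSet]:
    """Partition the elements of ``a`` by whether they overlap ``b``.

    Returns ``(hits, misses)``: whole elements of ``a`` are selected, never
    clipped, so ``hits`` and ``misses`` together restore ``a`` exactly.
    """
    b_union = b.union()
    hits: dict[str, np.ndarray] = {}
    misses: dict[str, np.ndarray] = {}
    for chrom in a.chroms:
        arr = a.arrays(chrom)
        mask = _overlap_mask(arr, b_union.arrays(chrom))
        if mask.any():
            hits[chrom] = arr[mask]
        if (~mask).any():
            misses[chrom] = arr[~mask]
    return IntervalSet(hits), IntervalSet(misses)


def subtract(a: IntervalSet, b: IntervalSet) -> IntervalSet:
    """Base-pair complement of ``b`` within ``a`` (both taken as coverage)."""
    a_union = a.union()
    b_union = b.union()
    out: dict[str, list[tuple[int, int]]] = {}
    for chrom in a_union.chroms:
        pieces = []
        b_arr = b_union.arrays(chrom)
        for s, e in a_union.arrays(chrom):
            cursor = int(s)
            lo = np.searchsorted(b_arr[:, 1], s, side="right") if b_arr.size else 0
            for bs, be in b_arr[lo:]:
                if bs >= e:
                    break
                if bs > cursor:
                    pieces.append((cursor, int(bs)))
                cursor = max(cursor, int(be))
            if cursor < e:
                pieces.append((cursor, int(e)))
        if pieces:
            out[chrom] = _as_array(pieces)
    return IntervalSet(out)


def proximity_match(a: IntervalSet, b: IntervalSet, max_dist: int) -> IntervalSet:
    """Elements of ``a`` within ``max_dist`` bp (edge-to-edge) of any element of ``b``.

    Overlap counts as distance 0; a gap exactly equal to ``max_dist`` matches.
    """
    if max_dist < 0:
        raise ValueError("max_dist must be >= 0")
    b_union = b.union()
    out: dict[str, np.ndarray] = {}
    for chrom in a.chroms:
        arr = a.arrays(chrom)
        blocks = b_union.arrays(chrom)
        if blocks.shape[0] == 0:
            continue
        starts, ends = blocks[:, 0], blocks[:, 1]
        dist = np.full(arr.shape[0], np.iinfo(np.int64).max, dtype=np.int64)
        # gap to the nearest block on the right
        nxt = np.searchsorted(starts, arr[:, 1], side="left")
        m = nxt < blocks.shape[0]
        dist[m] = starts[nxt[m]] - arr[m, 1]
        # gap to the nearest block on the left (or overlap)
        prv = np.searchsorted(starts, arr[:, 1], side="left") - 1
        m = prv >= 0
        left_gap = np.maximum(arr[m, 0] - ends[prv[m]], 0)
        dist[m] = np.minimum(dist[m], left_gap)
        mask = dist <= max_dist
        if mask.any():
            out[chrom] = arr[mask]
    return IntervalSet(out)


def shuffle_within_chrom(
    intervals: IntervalSet,
    genome: GenomeLayout,
    rng: np.random.Generator | int,
) -> IntervalSet:
    """Randomly relocate each interval within its own chromosome.

    Lengths and chromosome assignment are preserved; start positions are
    uniform over the valid range. Shuffled intervals may overlap each other.
    """
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    out: dict[str, np.ndarray] = {}
    for chrom in intervals.chroms:
        arr = intervals.arrays(chrom)
        chrom_len = genome.length(chrom)
        lengths = arr[:, 1] - arr[:, 0]
        if np.any(lengths > chrom_len):
            raise ValueError(f"interval longer than chromosome {chrom!r}")
        starts = rng.integers(0, chrom_len - lengths + 1)
        out[chrom] = np.column_stack([starts, starts + lengths])
    return IntervalSet(out)


def fraction_width_in(a: IntervalSet, b: IntervalSet) -> float:
    """Fraction of the base pairs of ``a`` that lie inside ``b``."""
    a_union = a.union()
    total = a_union.widths().sum()
    if total == 0:
        raise ValueError("fraction_width_in: set a is empty")
    covered = 0
    b_union = b.union()
    for chrom in a_union.chroms:
        b_arr = b_union.arrays(chrom)
        for s, e in a_union.arrays(chrom):
            covered += _coverage_in(b_arr, int(s), int(e))
    return covered / int(total)
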