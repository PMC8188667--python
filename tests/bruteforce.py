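"""Per-base brute-force oracles for the interval engine.

Deliberately naive: intervals become boolean base arrays (or are compared
pairwise), so these implementations share no code path with the package's
sweep-based operations.
"""

from __future__ import annotations

import numpy as np

from nailseq import Interval, IntervalSet


def base_set(intervals: list[tuple[str, int, int]], chrom: str, length: int) -> np.ndarray:
    mask = np.zeros(length, dtype=bool)
    for c, s, e in intervals:
        if c == chrom:
            mask[s:e] = True
    return mask


def runs_to_intervals(mask: np.ndarray, chrom: str) -> list[tuple[str, int, int]]:
    out = []
    in_run = False
    for i, v in enumerate(mask):
        if v and not in_run:
            start, in_run = i, True
        elif not v and in_run:
            out.append((chrom, start, i))
            in_run = False
    if in_run:
        out.append((chrom, start, len(mask)))
    return out


def brute_merge_within(ivs: list[tuple[str, int, int]], max_gap: int):
    """Repeated pairwise hulls until no two intervals have gap < max_gap."""
    ivs = [list(iv) for iv in ivs]
    changed = True
    while changed:
        changed = False
        for i in range(len(ivs)):
            for j in range(i + 1, len(ivs)):
                a, b = ivs[i], ivs[j]
                if a[0] != b[0]:
                    continue
                gap = max(a[1], b[1]) - min(a[2], b[2])
                if gap < max_gap:
                    ivs[i] = [a[0], min(a[1], b[1]), max(a[2], b[2])]
                    del ivs[j]
                    changed = True
                    break
            if changed:
                break
    return sorted(tuple(iv) for iv in ivs)


def brute_overlaps(a: tuple[str, int, int], bs: list[tuple[str, int, int]]) -> bool:
    for c, s, e in bs:
        if c == a[0] and len(set(range(a[1], a[2])) & set(range(s, e))) > 0:
            return True
    return False


def brute_subtract(a_ivs, b_ivs, genome: dict[str, int]):
    out = []
    for chrom, length in genome.items():
        mask = base_set(a_ivs, chrom, length) & ~base_set(b_ivs, chrom, length)
        out.extend(runs_to_intervals(mask, chrom))
    return sorted(out)


def brute_distance(a: tuple[str, int, int], b: tuple[str, int, int]) -> int:
    if a[0] != b[0]:
        return 10**12
    if a[1] < b[2] and b[1] < a[2]:
        return 0
    return max(b[1] - a[2], a[1] - b[2])


def brute_fraction_width_in(a_ivs, b_ivs, genome: dict[str, int]) -> float:
    total = covered = 0
    for chrom, length in genome.items():
        a_mask = base_set(a_ivs, chrom, length)
        b_mask = base_set(b_ivs, chrom, length)
        total += int(a_mask.sum())
        covered += int((a_mask & b_mask).sum())
    return covered / total


def random_interval_sets(rng: np.random.Generator, genome: dict[str, int], max_n=12):
    def one():
        ivs = []
        for chrom, length in genome.items():
            for _ in range(rng.integers(0, max_n + 1)):
                s = int(rng.integers(0, length - 1))
                e = int(rng.integers(s + 1, min(s + length // 4 + 2, length) + 1))
                ivs.append((chrom, s, min(e, length)))
        return ivs

    return one(), one()


def as_set(ivs) -> IntervalSet:
    return IntervalSet.from_intervals(ivs)


def set_to_list(s: IntervalSet) -> list[tuple[str, int, int]]:
    return sorted((iv.chrom, iv.start, iv.end) for iv in s)
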