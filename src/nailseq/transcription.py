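"""Transcription context: gene activity classes, non-transcribed regions,
and the non-TR vs TR enrichment statistic.

The spatial question this module serves: early replication initiation
zones sit in the gaps *between* active genes inside A compartments. A
"non-TR" is such a gap — flanked on both sides by active-gene footprints —
and the log2 ratio of read density inside the gap versus in its flanking
gene bodies quantifies how strongly a signal avoids (or, after
transcription perturbation, invades) transcribed chromatin.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .intervals import Interval, IntervalSet, intersect_select
from .tracks import BinnedTrack, ReadSet, mean_over

__all__ = [
    "classify_genes",
    "NonTRRegion",
    "define_non_trs",
    "density_log2_ratio",
    "wilcoxon_rank_sum",
    "build_heatmap_matrix",
]

GENE_COLUMNS = ["chrom", "start", "end", "strand", "promoter_density", "body_rpk"]


def classify_genes(genes: pd.DataFrame, species: str = "human") -> pd.DataFrame:
    """Label genes active / silent / intermediate from nascent-RNA densities.

    Human rules: active = promoter read density > 0 and gene-body RPK > 4;
    silent = zero promoter density and body RPK <= 1. Mouse rules: active =
    body RPK > 1; silent = zero body RPK. Everything else is intermediate.

    The input table needs columns ``chrom, start, end, strand, body_rpk``
    plus ``promoter_density`` for the human rules; TSS/TTS columns are
    derived from strand. A copy with ``activity``, ``tss`` and ``tts``
    columns is returned.
    """
    required = {"chrom", "start", "end", "strand", "body_rpk"}
    if species == "human":
        required.add("promoter_density")
    missing = required - set(genes.columns)
    if missing:
        raise ValueError(f"gene table missing columns: {sorted(missing)}")
    out = genes.copy()
    minus = out["strand"] == "-"
    out["tss"] = np.where(minus, out["end"], out["start"])
    out["tts"] = np.where(minus, out["start"], out["end"])
    rpk = out["body_rpk"].to_numpy(dtype=float)
    if species == "human":
        prom = out["promoter_density"].to_numpy(dtype=float)
        active = (prom > 0) & (rpk > 4)
        silent = (prom == 0) & (rpk <= 1)
    elif species == "mouse":
        active = rpk > 1
        silent = rpk == 0
    else:
        raise ValueError(f"unknown species rule {species!r}")
    out["activity"] = np.select([active, silent], ["active", "silent"], "intermediate")
    return out


@dataclass(frozen=True)
class NonTRRegion:
    """A gene-free gap between two active-gene footprints in an A compartment."""

    region: Interval
    upstream_flank: Interval  # active footprint block left of the gap
    downstream_flank: Interval  # active footprint block right of the gap

    @property
    def midpoint(self) -> int:
        return self.region.midpoint

    @property
    def width(self) -> int:
        return self.region.width


def define_non_trs(
    genes: pd.DataFrame,
    compartments_a: IntervalSet,
    width_range: tuple[int, int] = (20000, 100000),
    erizs: IntervalSet | None = None,
) -> list[NonTRRegion]:
    """Extract non-transcribed regions between active genes in A compartments.

    Active-gene footprints (overlapping genes merged) are intersected with
    each A compartment; the gaps strictly between two footprint blocks are
    candidate non-TRs. Gaps touching a compartment edge have only one
    gene flank and are dropped. Width filtering is inclusive on both ends
    of ``width_range``; when ``erizs`` is given, only gaps overlapping an
    ERIZ by >= 1 bp are kept.
    """
    if "activity" not in genes.columns:
        raise ValueError("gene table must carry an 'activity' column (classify first)")
    active = genes[genes["activity"] == "active"]
    footprint = IntervalSet.from_intervals(
        zip(active["chrom"], active["start"].astype(int), active["end"].astype(int))
    ).union()
    lo, hi = width_range
    out: list[NonTRRegion] = []
    for comp in compartments_a.union():
        blocks = footprint.arrays(comp.chrom)
        # footprint blocks clipped to this compartment
        sel = (blocks[:, 1] > comp.start) & (blocks[:, 0] < comp.end)
        clipped = blocks[sel].copy()
        if clipped.shape[0] < 2:
            continue
        clipped[:, 0] = np.maximum(clipped[:, 0], comp.start)
        clipped[:, 1] = np.minimum(clipped[:, 1], comp.end)
        for left, right in zip(clipped[:-1], clipped[1:]):
            gap = Interval(comp.chrom, int(left[1]), int(right[0]))
            if gap.width <= 0 or not (lo <= gap.width <= hi):
                continue
            region = NonTRRegion(
                region=gap,
                upstream_flank=Interval(comp.chrom, int(left[0]), int(left[1])),
                downstream_flank=Interval(comp.chrom, int(right[0]), int(right[1])),
            )
            out.append(region)
    if erizs is not None:
        gaps = IntervalSet.from_intervals(
            (r.region.chrom, r.region.start, r.region.end) for r in out
        )
        hits, _ = intersect_select(gaps, erizs)
        hit_set = set(hits)
        out = [r for r in out if Interval(*r.region) in hit_set]
    return out


def _trimmed(iv: Interval, trim: int) -> Interval | None:
    s, e = iv.start + trim, iv.end - trim
    if e <= s:
        return None
    return Interval(iv.chrom, s, e)


def density_log2_ratio(
    reads: ReadSet,
    regions: list[NonTRRegion],
    trim: int = 200,
    pseudocount: float | None = None,
) -> pd.DataFrame:
    """Per-region log2 ratio of non-TR read density to flanking-TR density.

    The non-TR is trimmed by ``trim`` bp at each end (excluding TSS/TTS
    neighbourhoods); each flanking gene body is trimmed the same way.
    Flank read counts are summed and divided by the summed flank length.
    The default pseudocount is half a read over the combined assessed
    length, keeping ratios finite on sparse data; ratios use
    log2((d_ntr + eps) / (d_tr + eps)).
    """
    rows = []
    for r in regions:
        ntr = _trimmed(r.region, trim)
        up = _trimmed(r.upstream_flank, trim)
        down = _trimmed(r.downstream_flank, trim)
        if ntr is None or up is None or down is None:
            warnings.warn(
                f"region {r.region} skipped: trimming left an empty interval",
                stacklevel=2,
            )
            continue
        n_ntr = reads.count_in(ntr.chrom, ntr.start, ntr.end)
        n_tr = reads.count_in(up.chrom, up.start, up.end) + reads.count_in(
            down.chrom, down.start, down.end
        )
        len_tr = up.width + down.width
        d_ntr = n_ntr / ntr.width
        d_tr = n_tr / len_tr
        eps = pseudocount if pseudocount is not None else 0.5 / (ntr.width + len_tr)
        ratio = float(np.log2((d_ntr + eps) / (d_tr + eps)))
        rows.append(
            (r.region.chrom, r.region.start, r.region.end, d_ntr, d_tr, ratio)
        )
    return pd.DataFrame(
        rows, columns=["chrom", "start", "end", "density_ntr", "density_tr", "log2_ratio"]
    )


def wilcoxon_rank_sum(x, y) -> tuple[float, float]:
    """Two-sided Wilcoxon rank-sum (Mann–Whitney) test.

    Exact enumeration for small untied samples (both n <= 25), otherwise
    the tie-corrected normal approximation with continuity correction.
    Returns (U statistic for x, two-sided p).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 1 or len(y) < 1:
        raise ValueError("both samples must be non-empty")
    combined = np.concatenate([x, y])
    if np.all(combined == combined[0]):
        return float(len(x) * len(y) / 2), 1.0
    has_ties = len(np.unique(combined)) < len(combined)
    method = "exact" if (len(x) <= 25 and len(y) <= 25 and not has_ties) else "asymptotic"
    res = stats.mannwhitneyu(
        x, y, alternative="two-sided", method=method, use_continuity=True
    )
    return float(res.statistic), float(res.pvalue)


def _column_mean(track: BinnedTrack, chrom: str, start: int, end: int) -> float:
    chrom_len = track.genome.length(chrom)
    s = max(start, 0)
    e = min(end, chrom_len)
    if e <= s:
        return np.nan
    return mean_over(track, Interval(chrom, s, e))


def build_heatmap_matrix(
    track: BinnedTrack,
    regions,
    mode: str = "midpoint",
    bin_width: int = 1000,
    flank: int = 100000,
    body_columns: int = 100,
    scaled_flank: int = 50000,
) -> tuple[np.ndarray, list[int]]:
    """Region × position signal matrix for heatmap display.

    mode="midpoint"
        ``regions`` is an iterable of intervals; each row covers
        midpoint ± ``flank`` in ``bin_width`` columns, rows ordered by
        increasing region width. Columns falling off a chromosome edge
        are NaN.
    mode="scaled"
        ``regions`` is a DataFrame with chrom/start/end/strand; gene
        bodies are rescaled to ``body_columns`` columns with
        ``scaled_flank`` bp of real-scale flank on each side, rows ordered
        by increasing gene width (smallest on top); minus-strand rows are
        flipped so transcription runs left to right.

    Returns (matrix, row_order) where ``row_order`` gives the original
    region indices in display order.
    """
    if mode == "midpoint":
        ivs = [Interval(r.chrom, r.start, r.end) for r in regions]
        if not ivs:
            raise ValueError("no regions given")
        order = sorted(range(len(ivs)), key=lambda i: ivs[i].width)
        n_cols = 2 * flank // bin_width
        mat = np.full((len(ivs), n_cols), np.nan)
        for row, i in enumerate(order):
            center = ivs[i].midpoint
            left = center - flank
            for j in range(n_cols):
                mat[row, j] = _column_mean(
                    track, ivs[i].chrom, left + j * bin_width, left + (j + 1) * bin_width
                )
        return mat, order
    if mode == "scaled":
        df = regions.reset_index(drop=True)
        if len(df) == 0:
            raise ValueError("no regions given")
        widths = (df["end"] - df["start"]).to_numpy()
        order = np.argsort(widths, kind="stable").tolist()
        flank_cols = scaled_flank // bin_width
        n_cols = 2 * flank_cols + body_columns
        mat = np.full((len(df), n_cols), np.nan)
        for row, i in enumerate(order):
            chrom = df.at[i, "chrom"]
            start, end = int(df.at[i, "start"]), int(df.at[i, "end"])
            cols = []
            for j in range(flank_cols):  # upstream flank, real scale
                cols.append((start - scaled_flank + j * bin_width,
                             start - scaled_flank + (j + 1) * bin_width))
            length = end - start
            edges = start + np.round(np.linspace(0, length, body_columns + 1)).astype(int)
            for j in range(body_columns):  # body, proportional scale
                lo, hi = int(edges[j]), int(edges[j + 1])
                cols.append((lo, max(hi, lo + 1)))
            for j in range(flank_cols):  # downstream flank
                cols.append((end + j * bin_width, end + (j + 1) * bin_width))
            vals = [_column_mean(track, chrom, lo, hi) for lo, hi in cols]
            if str(df.at[i, "strand"]) == "-":
                vals = vals[::-1]
            mat[row] = vals
        return mat, order
    raise ValueError(f"unknown heatmap mode {mode!r}")
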