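"""Synthetic genomes and read sets with the signal structure the pipeline assumes.

The generator plants a known truth — A/B compartments, active/silent genes
inside A compartments, and early-initiation zones confined to the
non-transcribed gaps between active genes — and then simulates each assay
around it:

* dual-label reads: first-label (EdU) enrichment over the zones, second-label
  (BrdU) enrichment displaced outward onto the zone flanks (elongation having
  moved on by the time of the second pulse), over a uniform Poisson background;
* HU-stalled (EdU/HU) reads: sharply concentrated on the zones over a sparse
  background, exercising both sides of the 400-fold filter;
* marker peak sets positively co-located with zones or negatively co-located
  (inside active gene bodies), a nascent-transcription (GRO) gene table, and a
  replication-timing track high over A and low over B;
* replicate read sets for a dCas9 barrier locus with an optional upstream
  pile-up.

Everything is deterministic under (config, seed).
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .barrier import BarrierConfig
from .genome import GenomeLayout
from .intervals import Interval, IntervalSet, proximity_match
from .tracks import BinnedTrack, ReadSet

__all__ = [
    "SimConfig",
    "SyntheticTruth",
    "generate_truth",
    "simulate_dual_label",
    "simulate_eduhu",
    "simulate_markers",
    "simulate_barrier",
    "write_truth",
]

READ_LEN = 150  # fragment length; midpoint binning makes the exact value immaterial


@dataclass
class SimConfig:
    """Study conditions for the synthetic genome (all rates per replicate).

    The genome is a scaled-down stand-in (2 × 20 Mb); enrichment folds and
    the zone-width scale follow the assays' signal structure: zones of
    median width ~70 kb, ~10× dual-label enrichment with the second label
    displaced ~25 kb outward, and ~1000× EdU/HU concentration over a
    sparse background.
    """

    chrom_lengths: dict = field(
        default_factory=lambda: {"chr1": 25_000_000, "chr2": 25_000_000}
    )
    # compartments: alternating A/B segments
    compartment_len_range: tuple = (1_500_000, 2_500_000)
    # gene layout inside A compartments
    gene_len_range: tuple = (30_000, 80_000)
    # wide enough that the realized zone widths follow their distribution
    # (median ~70 kb) rather than being truncated by their host gap
    gap_len_range: tuple = (60_000, 140_000)
    first_gap_range: tuple = (10_000, 30_000)
    active_fraction: float = 0.7
    silent_fraction: float = 0.25  # remainder is intermediate
    # planted zones
    n_zones: int = 50
    zone_width_median: float = 70_000.0
    zone_width_sigma: float = 0.25  # lognormal sigma
    zone_width_bounds: tuple = (30_000, 110_000)
    zone_margin: int = 2_000  # gene-free cushion each side of a zone
    perturbed_fraction: float = 0.0  # fraction of zones relocated into gene bodies
    # dual-label assay
    replicates: int = 2
    edu_bg_per_kb: float = 4.0
    dual_zone_fold: float = 10.0
    brdu_flank_offset: int = 25_000
    # EdU/HU assay
    eduhu_bg_per_kb: float = 0.1
    eduhu_zone_fold: float = 1000.0
    # markers / timing / transcription table
    marker_bg_per_mb: float = 1.0
    marker_width: int = 2_000
    p_positive: float = 0.8
    p_negative: float = 0.8
    # active genes closer than this to a planted zone host no negative-marker
    # peaks: the negative marker emulates elongation chromatin depleted around
    # initiation-adjacent gaps, one 50-kb window away
    neg_zone_exclusion: int = 50_000
    timing_a: float = 0.75
    timing_b: float = 0.25
    timing_noise_sd: float = 0.05
    timing_bin: int = 5_000
    # barrier locus
    barrier_bg_per_kb: float = 5.0
    barrier_fold: float = 5.0
    barrier_replicates: int = 3
    barrier_window: int = 2_000

    def genome(self) -> GenomeLayout:
        return GenomeLayout(self.chrom_lengths)


@dataclass
class SyntheticTruth:
    """Planted structures against which recovery is scored."""

    genome: GenomeLayout
    compartments_a: IntervalSet
    compartments_b: IntervalSet
    genes: pd.DataFrame  # chrom,start,end,strand,promoter_density,body_rpk,activity
    zones: IntervalSet

    @property
    def active_genes(self) -> pd.DataFrame:
        return self.genes[self.genes["activity"] == "active"]


def _sub_rng(seed: int, stream: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([int(seed), int(stream)]))


def generate_truth(cfg: SimConfig, seed: int = 0) -> SyntheticTruth:
    """Lay out compartments, genes and planted zones, deterministically."""
    rng = _sub_rng(seed, 0)
    genome = cfg.genome()

    # alternating A/B compartments
    comp_a, comp_b = [], []
    for chrom in genome:
        pos, is_a = 0, True
        length = genome.length(chrom)
        while pos < length:
            seg = int(rng.integers(*cfg.compartment_len_range))
            end = min(pos + seg, length)
            (comp_a if is_a else comp_b).append((chrom, pos, end))
            pos, is_a = end, not is_a
    compartments_a = IntervalSet.from_intervals(comp_a)
    compartments_b = IntervalSet.from_intervals(comp_b)

    # genes tile A compartments with gene-free gaps between them
    gene_rows = []
    gaps = []  # (chrom, gap_start, gap_end, left_gene_idx, right_gene_idx)
    for chrom, cs, ce in comp_a:
        pos = cs + int(rng.integers(*cfg.first_gap_range))
        prev_idx = None
        prev_end = None
        while True:
            glen = int(rng.integers(*cfg.gene_len_range))
            if pos + glen > ce:
                break
            u = rng.random()
            if u < cfg.active_fraction:
                activity = "active"
                body_rpk = 4.0 + float(rng.exponential(8.0))
                promoter = float(rng.uniform(0.5, 5.0))
            elif u < cfg.active_fraction + cfg.silent_fraction:
                activity = "silent"
                body_rpk = float(rng.uniform(0.0, 1.0))
                promoter = 0.0
            else:
                activity = "intermediate"
                body_rpk = float(rng.uniform(1.5, 4.0))
                promoter = 0.0
            idx = len(gene_rows)
            gene_rows.append(
                (
                    chrom,
                    pos,
                    pos + glen,
                    "+" if rng.random() < 0.5 else "-",
                    promoter,
                    body_rpk,
                    activity,
                )
            )
            if prev_idx is not None:
                gaps.append((chrom, prev_end, pos, prev_idx, idx))
            prev_idx, prev_end = idx, pos + glen
            pos = prev_end + int(rng.integers(*cfg.gap_len_range))
    genes = pd.DataFrame(
        gene_rows,
        columns=[
            "chrom",
            "start",
            "end",
            "strand",
            "promoter_density",
            "body_rpk",
            "activity",
        ],
    )

    # zones go into gaps flanked by two active genes, with a margin
    min_zone = cfg.zone_width_bounds[0]
    eligible = [
        g
        for g in gaps
        if genes.at[g[3], "activity"] == "active"
        and genes.at[g[4], "activity"] == "active"
        and (g[2] - g[1]) >= min_zone + 2 * cfg.zone_margin
    ]
    if len(eligible) < cfg.n_zones:
        raise ValueError(
            f"infeasible placement: {cfg.n_zones} zones requested but only "
            f"{len(eligible)} eligible gaps available"
        )
    chosen = rng.choice(len(eligible), size=cfg.n_zones, replace=False)
    zone_rows = []
    for i in sorted(chosen):
        chrom, gs, ge, _, _ = eligible[i]
        avail = ge - gs - 2 * cfg.zone_margin
        width = float(
            np.exp(rng.normal(np.log(cfg.zone_width_median), cfg.zone_width_sigma))
        )
        width = int(np.clip(width, cfg.zone_width_bounds[0], cfg.zone_width_bounds[1]))
        width = min(width, avail)
        slack = avail - width
        start = gs + cfg.zone_margin + int(rng.integers(0, slack + 1))
        zone_rows.append((chrom, start, start + width))

    # optional perturbation: relocate a fraction of zones into active gene bodies
    n_move = int(round(cfg.perturbed_fraction * len(zone_rows)))
    if n_move > 0:
        active = genes[genes["activity"] == "active"].reset_index(drop=True)
        move_idx = rng.choice(len(zone_rows), size=n_move, replace=False)
        for i in move_idx:
            chrom, s, e = zone_rows[i]
            width = e - s
            g = active.iloc[int(rng.integers(0, len(active)))]
            gw = int(g["end"] - g["start"])
            w = min(width, gw)
            off = int(rng.integers(0, gw - w + 1))
            zone_rows[i] = (g["chrom"], int(g["start"]) + off, int(g["start"]) + off + w)

    zones = IntervalSet.from_intervals(zone_rows)
    return SyntheticTruth(
        genome=genome,
        compartments_a=compartments_a,
        compartments_b=compartments_b,
        genes=genes,
        zones=zones,
    )


def _uniform_reads(
    rng: np.random.Generator, genome: GenomeLayout, rate_per_bp: float
) -> dict[str, np.ndarray]:
    out = {}
    for chrom in genome:
        length = genome.length(chrom)
        n = rng.poisson(rate_per_bp * length)
        starts = rng.integers(0, max(length - READ_LEN, 1), size=n)
        out[chrom] = starts
    return out


def _region_reads(
    rng: np.random.Generator,
    genome: GenomeLayout,
    regions: list[tuple[str, int, int]],
    extra_rate_per_bp: float,
) -> dict[str, list[np.ndarray]]:
    out: dict[str, list[np.ndarray]] = {}
    for chrom, s, e in regions:
        n = rng.poisson(extra_rate_per_bp * (e - s))
        lo = max(s - READ_LEN // 2, 0)
        hi = min(e - READ_LEN // 2, genome.length(chrom) - READ_LEN)
        if hi <= lo:
            continue
        starts = rng.integers(lo, hi, size=n)
        out.setdefault(chrom, []).append(starts)
    return out


def _assemble(genome: GenomeLayout, *parts) -> ReadSet:
    by_chrom: dict[str, list[np.ndarray]] = {}
    for part in parts:
        for chrom, val in part.items():
            arrs = val if isinstance(val, list) else [val]
            by_chrom.setdefault(chrom, []).extend(arrs)
    final = {}
    for chrom, arrs in by_chrom.items():
        starts = np.sort(np.concatenate(arrs)) if arrs else np.empty(0, dtype=np.int64)
        final[chrom] = np.column_stack([starts, starts + READ_LEN])
    return ReadSet(final)


def simulate_dual_label(
    truth: SyntheticTruth, cfg: SimConfig, replicate_seed: int = 0
) -> tuple[ReadSet, ReadSet]:
    """EdU (first-label) and BrdU (second-label) read sets for one replicate.

    EdU piles up on the zones themselves; BrdU piles up on two flanks
    displaced outward by ``cfg.brdu_flank_offset`` (forks have moved on),
    both over the same uniform background.
    """
    rng = _sub_rng(replicate_seed, 1)
    genome = truth.genome
    bg = cfg.edu_bg_per_kb / 1e3
    extra = (cfg.dual_zone_fold - 1.0) * bg
    zone_list = [(iv.chrom, iv.start, iv.end) for iv in truth.zones]
    edu = _assemble(
        genome,
        _uniform_reads(rng, genome, bg),
        _region_reads(rng, genome, zone_list, extra),
    )
    flanks = []
    for chrom, s, e in zone_list:
        flanks.append((chrom, max(s - cfg.brdu_flank_offset, 0), s))
        flanks.append((chrom, e, min(e + cfg.brdu_flank_offset, genome.length(chrom))))
    brdu = _assemble(
        genome,
        _uniform_reads(rng, genome, bg),
        _region_reads(rng, genome, flanks, extra),
    )
    return edu, brdu


def simulate_eduhu(
    truth: SyntheticTruth, cfg: SimConfig, replicate_seed: int = 0
) -> ReadSet:
    """HU-stalled EdU reads: zones at ``eduhu_zone_fold`` × a sparse background."""
    rng = _sub_rng(replicate_seed, 2)
    bg = cfg.eduhu_bg_per_kb / 1e3
    extra = (cfg.eduhu_zone_fold - 1.0) * bg
    zone_list = [(iv.chrom, iv.start, iv.end) for iv in truth.zones]
    return _assemble(
        truth.genome,
        _uniform_reads(rng, truth.genome, bg),
        _region_reads(rng, truth.genome, zone_list, extra),
    )


def simulate_markers(
    truth: SyntheticTruth, cfg: SimConfig, seed: int = 0
) -> tuple[dict[str, IntervalSet], pd.DataFrame, BinnedTrack]:
    """Marker peak sets, the nascent-transcription gene table, and a timing track.

    The positive marker drops a peak inside each planted zone with
    probability ``p_positive``; the negative marker inside each active
    gene body with probability ``p_negative``; both get uniform background
    peaks at ``marker_bg_per_mb``.
    """
    rng = _sub_rng(seed, 3)
    genome = truth.genome

    def bg_peaks() -> list[tuple[str, int, int]]:
        peaks = []
        for chrom in genome:
            length = genome.length(chrom)
            n = rng.poisson(cfg.marker_bg_per_mb * length / 1e6)
            for s in rng.integers(0, length - cfg.marker_width, size=n):
                peaks.append((chrom, int(s), int(s) + cfg.marker_width))
        return peaks

    pos_peaks = bg_peaks()
    for iv in truth.zones:
        if rng.random() < cfg.p_positive and iv.width > cfg.marker_width:
            s = iv.start + int(rng.integers(0, iv.width - cfg.marker_width))
            pos_peaks.append((iv.chrom, s, s + cfg.marker_width))
    neg_peaks = bg_peaks()
    active_ivs = IntervalSet.from_intervals(
        zip(
            truth.active_genes["chrom"],
            truth.active_genes["start"].astype(int),
            truth.active_genes["end"].astype(int),
        )
    )
    near_zone = set(proximity_match(active_ivs, truth.zones, cfg.neg_zone_exclusion))
    for _, g in truth.active_genes.iterrows():
        gw = int(g["end"] - g["start"])
        if Interval(g["chrom"], int(g["start"]), int(g["end"])) in near_zone:
            continue
        if rng.random() < cfg.p_negative and gw > cfg.marker_width:
            s = int(g["start"]) + int(rng.integers(0, gw - cfg.marker_width))
            neg_peaks.append((g["chrom"], s, s + cfg.marker_width))
    markers = {
        "marker_pos": IntervalSet.from_intervals(pos_peaks),
        "marker_neg": IntervalSet.from_intervals(neg_peaks),
    }

    # replication timing: high over A compartments, low over B, plus noise
    values = {}
    a_union = truth.compartments_a.union()
    for chrom in genome:
        n = -(-genome.length(chrom) // cfg.timing_bin)
        v = np.full(n, cfg.timing_b)
        for s, e in a_union.arrays(chrom):
            v[s // cfg.timing_bin : -(-e // cfg.timing_bin)] = cfg.timing_a
        v = v + rng.normal(0.0, cfg.timing_noise_sd, size=n)
        values[chrom] = np.clip(v, 0.0, 1.0)
    timing = BinnedTrack(genome, cfg.timing_bin, values, units="timing")

    gro_table = truth.genes[
        ["chrom", "start", "end", "strand", "promoter_density", "body_rpk"]
    ].copy()
    return markers, gro_table, timing


def simulate_barrier(
    truth: SyntheticTruth,
    cfg: SimConfig,
    seed: int = 0,
    blocked: bool = True,
) -> tuple[list[ReadSet], BarrierConfig]:
    """Replicate EdU/HU read sets around a dCas9 barrier in an active gene.

    In ``blocked`` mode a pile-up at ``barrier_fold`` × background covers
    the 2-kb window immediately upstream (in the transcription direction)
    of the site; scrambled-guide mode omits it. Reads are generated on the
    barrier chromosome only.
    """
    rng = _sub_rng(seed, 4)
    active = truth.active_genes
    wide = active[(active["end"] - active["start"]) >= 20_000]
    if wide.empty:
        raise ValueError("no active gene wide enough to host a barrier")
    g = wide.iloc[0]
    center = int((g["start"] + g["end"]) // 2)
    bcfg = BarrierConfig(
        chrom=str(g["chrom"]), center=center, orientation=str(g["strand"])
    )
    if bcfg.orientation == "+":
        up = (center - cfg.barrier_window, center)
    else:
        up = (center, center + cfg.barrier_window)
    chrom_only = GenomeLayout({bcfg.chrom: truth.genome.length(bcfg.chrom)})
    bg = cfg.barrier_bg_per_kb / 1e3
    reps = []
    for _ in range(cfg.barrier_replicates):
        parts = [_uniform_reads(rng, chrom_only, bg)]
        if blocked:
            parts.append(
                _region_reads(
                    rng,
                    chrom_only,
                    [(bcfg.chrom, up[0], up[1])],
                    (cfg.barrier_fold - 1.0) * bg,
                )
            )
        reps.append(_assemble(chrom_only, *parts))
    return reps, bcfg


def write_truth(
    truth: SyntheticTruth, cfg: SimConfig, outdir: str | Path, seed: int
) -> None:
    """Emit truth files (BED/TSV/bedGraph) plus a manifest JSON."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    truth.genome.to_chrom_sizes(outdir / "genome.chrom.sizes")
    truth.zones.write_bed(outdir / "zones.bed")
    truth.compartments_a.write_bed(outdir / "compartments_A.bed")
    truth.compartments_b.write_bed(outdir / "compartments_B.bed")
    truth.genes.to_csv(outdir / "genes.tsv", sep="\t", index=False)
    manifest = {"seed": seed, "config": asdict(cfg)}
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)
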