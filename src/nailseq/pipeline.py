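"""End-to-end convenience wrappers and recovery scoring.

These glue the per-stage callers into the full chain
(reads → E−B peaks per replicate → reproducible E−B peaks; reads → EdU/HU
peaks; intersection → ERIZs) and score called intervals against a planted
truth.
"""

from __future__ import annotations

import numpy as np

from .genome import GenomeLayout
from .intervals import IntervalSet
from .peaks import (
    EBParams,
    ERIZResult,
    IslandParams,
    PoissonScanParams,
    call_eb_peaks,
    call_islands,
    call_poisson_peaks,
    define_erizs,
    eb_delta,
    reproducible_peaks,
)
from .simulate import SimConfig, SyntheticTruth, simulate_dual_label, simulate_eduhu
from .tracks import BinnedTrack, ReadSet, bin_reads, normalize

__all__ = [
    "call_eb_from_reads",
    "run_eriz_pipeline",
    "recovery_metrics",
]


def call_eb_from_reads(
    edu_reads: ReadSet,
    brdu_reads: ReadSet,
    genome: GenomeLayout,
    eb_params: EBParams | None = None,
    island_params: IslandParams | None = None,
) -> IntervalSet:
    """E−B peaks for one replicate, straight from the two read sets."""
    eb_params = eb_params or EBParams()
    e_rpm = normalize(bin_reads(edu_reads, genome, eb_params.bin_width), "rpm")
    b_rpm = normalize(bin_reads(brdu_reads, genome, eb_params.bin_width), "rpm")
    islands = call_islands(edu_reads, genome, island_params)
    return call_eb_peaks(eb_delta(e_rpm, b_rpm), islands, eb_params)


def run_eriz_pipeline(
    truth: SyntheticTruth,
    cfg: SimConfig,
    seed: int,
    timing: BinnedTrack | None = None,
    eb_params: EBParams | None = None,
    island_params: IslandParams | None = None,
    scan_params: PoissonScanParams | None = None,
) -> ERIZResult:
    """Simulate reads for a truth and run the full ERIZ-calling chain.

    Dual-label replicates are drawn with replicate seeds derived from
    ``seed``; E−B peaks must reproduce in at least
    ``eb_params.min_replicates`` replicates before intersection with the
    EdU/HU peaks.
    """
    eb_params = eb_params or EBParams()
    replicate_sets = []
    for r in range(cfg.replicates):
        edu, brdu = simulate_dual_label(truth, cfg, replicate_seed=seed * 1000 + r)
        replicate_sets.append(
            call_eb_from_reads(edu, brdu, truth.genome, eb_params, island_params)
        )
    eb = reproducible_peaks(replicate_sets, min_support=eb_params.min_replicates)
    eduhu = simulate_eduhu(truth, cfg, replicate_seed=seed * 1000)
    eduhu_peaks = call_poisson_peaks(eduhu, truth.genome, scan_params)
    return define_erizs(eduhu_peaks, eb, timing=timing)


def _jaccard(a: tuple[int, int], b: tuple[int, int]) -> float:
    inter = max(0, min(a[1], b[1]) - max(a[0], b[0]))
    union = (a[1] - a[0]) + (b[1] - b[0]) - inter
    return inter / union if union else 0.0


def recovery_metrics(truth_zones: IntervalSet, called: IntervalSet) -> dict:
    """Score called intervals against planted zones.

    recall
        fraction of zones overlapped (>= 1 bp) by a called interval;
    precision
        fraction of called intervals overlapping a zone;
    jaccards
        per recovered zone, the best single-interval Jaccard index;
    median_jaccard / min_jaccard
        summaries of the above (NaN when nothing is recovered).
    """
    n_zones = len(truth_zones)
    n_called = len(called)
    jaccards = []
    hit_zones = 0
    for zone in truth_zones:
        best = 0.0
        hit = False
        for s, e in called.arrays(zone.chrom):
            if s < zone.end and e > zone.start:
                hit = True
                best = max(best, _jaccard((zone.start, zone.end), (int(s), int(e))))
        if hit:
            hit_zones += 1
            jaccards.append(best)
    called_hits = 0
    zone_union = truth_zones.union()
    for iv in called:
        arr = zone_union.arrays(iv.chrom)
        if np.any((arr[:, 0] < iv.end) & (arr[:, 1] > iv.start)):
            called_hits += 1
    return {
        "n_zones": n_zones,
        "n_called": n_called,
        "recall": hit_zones / n_zones if n_zones else float("nan"),
        "precision": called_hits / n_called if n_called else float("nan"),
        "jaccards": jaccards,
        "median_jaccard": float(np.median(jaccards)) if jaccards else float("nan"),
        "min_jaccard": float(np.min(jaccards)) if jaccards else float("nan"),
    }
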