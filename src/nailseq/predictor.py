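"""Predicting initiation zones from epigenetic features.

A-compartment territory is tiled into 50-kb windows labelled by ERIZ
overlap. Each chromatin marker contributes one feature per window: the
log-odds enrichment of observed marker-peak occupancy (fraction of the
window's 1-kb bins touching a peak) over the occupancy expected from the
same peaks shuffled within their chromosome. A class-balanced logistic
regression then ranks markers by coefficient: positive coefficients mark
chromatin that co-locates with initiation zones, negative ones chromatin
that excludes them.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genome import GenomeLayout
from .intervals import Interval, IntervalSet, _overlap_mask, shuffle_within_chrom

__all__ = [
    "WindowSet",
    "binarize_windows",
    "enrichment_scores",
    "balance_subsample",
    "LogisticModel",
    "fit_logistic",
    "evaluate_contributions",
]


@dataclass
class WindowSet:
    """Fixed windows tiling A compartments with binary ERIZ labels."""

    windows: list[Interval]
    labels: np.ndarray

    def __len__(self) -> int:
        return len(self.windows)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            [(w.chrom, w.start, w.end, int(l)) for w, l in zip(self.windows, self.labels)],
            columns=["chrom", "start", "end", "label"],
        )


def binarize_windows(
    erizs: IntervalSet,
    compartments_a: IntervalSet,
    genome: GenomeLayout,
    window: int = 50000,
) -> WindowSet:
    """Tile A compartments into 50-kb windows and label ERIZ overlap.

    Each compartment is tiled from its start; the final partial window is
    kept when it spans at least half the window width. A window is
    labelled 1 iff it shares >= 1 bp with any ERIZ.
    """
    comp = compartments_a.union()
    if len(comp) == 0:
        raise ValueError("no A compartments given")
    windows: list[Interval] = []
    for iv in comp:
        pos = iv.start
        while pos < iv.end:
            end = min(pos + window, iv.end)
            if end - pos >= window // 2:
                windows.append(Interval(iv.chrom, pos, end))
            pos += window
    eriz_union = erizs.union()
    labels = np.zeros(len(windows), dtype=int)
    by_chrom: dict[str, list[int]] = {}
    for i, w in enumerate(windows):
        by_chrom.setdefault(w.chrom, []).append(i)
    for chrom, idx in by_chrom.items():
        arr = np.array([[windows[i].start, windows[i].end] for i in idx])
        mask = _overlap_mask(arr, eriz_union.arrays(chrom))
        labels[np.array(idx)[mask]] = 1
    return WindowSet(windows=windows, labels=labels)


def _window_bins(windows: list[Interval], sub_bin: int) -> tuple[dict, dict]:
    """Per-chromosome 1-kb sub-bin arrays and the owning window index."""
    bins: dict[str, np.ndarray] = {}
    owner: dict[str, np.ndarray] = {}
    for chrom in sorted({w.chrom for w in windows}):
        rows, own = [], []
        for i, w in enumerate(windows):
            if w.chrom != chrom:
                continue
            starts = np.arange(w.start, w.end, sub_bin)
            ends = np.minimum(starts + sub_bin, w.end)
            rows.append(np.column_stack([starts, ends]))
            own.append(np.full(len(starts), i))
        bins[chrom] = np.concatenate(rows)
        owner[chrom] = np.concatenate(own)
    return bins, owner


def _logit(p: np.ndarray | float, eps: float) -> np.ndarray | float:
    return np.log((p + eps) / (1 - p + eps))


def enrichment_scores(
    windows: WindowSet | list[Interval],
    marker_peaks: IntervalSet,
    genome: GenomeLayout,
    n_shuffle: int = 10,
    rng: np.random.Generator | int = 0,
    eps: float = 0.01,
    sub_bin: int = 1000,
) -> np.ndarray:
    """Log-odds enrichment of observed vs expected marker occupancy per window.

    p_obs is the fraction of a window's 1-kb bins overlapping >= 1 marker
    peak. The expected occupancy is chromosome-level, from ``n_shuffle``
    within-chromosome shuffles of the marker peaks, and is accumulated on
    the log-odds scale: logit(occupancy) is computed per shuffled window
    and averaged over the chromosome's windows and shuffles. Taking the
    logit before averaging matches the sampling noise (and hence the
    concavity bias) of the observed side, so the score
    logit(p_obs) − E[logit(p_shuffled)] is centred at zero for randomly
    placed peaks. ``eps`` is a pseudo-probability guarding the {0, 1}
    endpoints (natural log).
    """
    wlist = windows.windows if isinstance(windows, WindowSet) else list(windows)
    if any(w.width < sub_bin for w in wlist):
        raise ValueError(f"windows must be at least {sub_bin} bp")
    if len(marker_peaks) == 0:
        raise ValueError("marker peak set is empty")
    if n_shuffle < 1:
        raise ValueError("n_shuffle must be >= 1")
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    bins, owner = _window_bins(wlist, sub_bin)
    n_win = len(wlist)

    def occupied(peaks: IntervalSet, chrom: str) -> np.ndarray:
        return _overlap_mask(bins[chrom], peaks.union().arrays(chrom))

    p_obs = np.zeros(n_win)
    counts = np.zeros(n_win)
    for chrom in bins:
        mask = occupied(marker_peaks, chrom)
        np.add.at(p_obs, owner[chrom], mask.astype(float))
        np.add.at(counts, owner[chrom], 1.0)
    p_obs /= counts

    expected_logodds: dict[str, float] = {c: 0.0 for c in bins}
    for _ in range(n_shuffle):
        shuffled = shuffle_within_chrom(marker_peaks, genome, rng)
        for chrom in bins:
            mask = occupied(shuffled, chrom).astype(float)
            win_p = np.zeros(n_win)
            np.add.at(win_p, owner[chrom], mask)
            present = np.unique(owner[chrom])
            win_frac = win_p[present] / counts[present]
            expected_logodds[chrom] += float(np.mean(_logit(win_frac, eps)))
    for chrom in expected_logodds:
        expected_logodds[chrom] /= n_shuffle

    scores = np.empty(n_win)
    for i, w in enumerate(wlist):
        scores[i] = _logit(p_obs[i], eps) - expected_logodds[w.chrom]
    return scores


def balance_subsample(
    labels: np.ndarray, rng: np.random.Generator | int = 0, n_repeats: int = 1
):
    """Row indices keeping all positive rows and an equal-size draw of negatives.

    Negatives are sampled uniformly without replacement; index arrays are
    sorted and deterministic under a fixed seed. With ``n_repeats > 1`` a
    list of independent draws is returned (for coefficient averaging).
    """
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    labels = np.asarray(labels)
    ones = np.flatnonzero(labels == 1)
    zeros = np.flatnonzero(labels == 0)
    if len(ones) == 0 or len(zeros) == 0:
        raise ValueError("both classes must be non-empty")

    def one_draw() -> np.ndarray:
        if len(zeros) <= len(ones):
            return np.sort(np.concatenate([ones, zeros]))
        picked = rng.choice(zeros, size=len(ones), replace=False)
        return np.sort(np.concatenate([ones, picked]))

    if n_repeats == 1:
        return one_draw()
    return [one_draw() for _ in range(n_repeats)]


@dataclass
class LogisticModel:
    """Maximum-likelihood logit fit (IRLS) with Wald standard errors."""

    intercept: float
    coef: np.ndarray
    se: np.ndarray  # intercept SE first, then per-feature
    converged: bool
    n_iter: int
    loglik_path: np.ndarray = field(repr=False)
    separable: bool = False

    @property
    def zscores(self) -> np.ndarray:
        return np.concatenate([[self.intercept], self.coef]) / self.se


def _log_likelihood(eta: np.ndarray, y: np.ndarray) -> float:
    # log L = sum y*eta - log(1 + exp(eta)), computed stably
    return float(np.sum(y * eta - np.logaddexp(0.0, eta)))


def fit_logistic(
    X: np.ndarray, y: np.ndarray, max_iter: int = 100, tol: float = 1e-8
) -> LogisticModel:
    """Fit logit(P(y=1)) = b0 + X @ b by iteratively reweighted least squares.

    Standard errors come from the inverse observed information at the
    optimum. Quasi-separation is flagged (coefficients still reported)
    when fitted probabilities saturate; the log-likelihood is guaranteed
    non-decreasing by step-halving.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if X.ndim != 2 or len(X) != len(y):
        raise ValueError("X must be 2-D with one row per label")
    n, p = X.shape
    if n <= p + 1:
        raise ValueError("need more rows than parameters")
    if np.any(np.ptp(X, axis=0) == 0):
        raise ValueError("constant (zero-variance) feature column")
    Xd = np.column_stack([np.ones(n), X])
    beta = np.zeros(p + 1)
    eta = Xd @ beta
    ll = _log_likelihood(eta, y)
    path = [ll]
    converged = False
    n_iter = 0
    for n_iter in range(1, max_iter + 1):
        mu = 1.0 / (1.0 + np.exp(-eta))
        w = np.clip(mu * (1.0 - mu), 1e-10, None)
        z = eta + (y - mu) / w
        XtW = Xd.T * w
        try:
            step_beta = np.linalg.solve(XtW @ Xd, XtW @ z)
        except np.linalg.LinAlgError:
            break
        # step-halving keeps the log-likelihood monotone
        direction = step_beta - beta
        factor = 1.0
        for _ in range(30):
            cand = beta + factor * direction
            cand_ll = _log_likelihood(Xd @ cand, y)
            if cand_ll >= ll - 1e-12:
                break
            factor /= 2.0
        beta = beta + factor * direction
        eta = Xd @ beta
        new_ll = _log_likelihood(eta, y)
        path.append(new_ll)
        if abs(new_ll - ll) < tol * (abs(ll) + tol):
            converged = True
            ll = new_ll
            break
        ll = new_ll
    mu = 1.0 / (1.0 + np.exp(-eta))
    separable = bool(np.all((mu > 0.999) == (y == 1)) and np.all((mu < 0.001) == (y == 0)))
    if separable:
        warnings.warn(
            "possible perfect separation: coefficients are unstable", stacklevel=2
        )
    w = np.clip(mu * (1.0 - mu), 1e-10, None)
    info = (Xd.T * w) @ Xd
    try:
        cov = np.linalg.inv(info)
        se = np.sqrt(np.diag(cov))
    except np.linalg.LinAlgError:
        se = np.full(p + 1, np.nan)
    return LogisticModel(
        intercept=float(beta[0]),
        coef=beta[1:].copy(),
        se=se,
        converged=converged,
        n_iter=n_iter,
        loglik_path=np.asarray(path),
        separable=separable,
    )


def evaluate_contributions(
    model: LogisticModel, marker_names: list[str]
) -> pd.DataFrame:
    """Rank markers by fitted coefficient (most positive first)."""
    if model is None or model.coef is None:
        raise ValueError("model is not fitted")
    if len(marker_names) != len(model.coef):
        raise ValueError("one name per coefficient required")
    df = pd.DataFrame(
        {
            "marker": marker_names,
            "coefficient": model.coef,
            "se": model.se[1:],
            "z": model.coef / model.se[1:],
        }
    )
    df["sign"] = np.where(df["coefficient"] > 0, "positive", "negative")
    return df.sort_values("coefficient", ascending=False).reset_index(drop=True)
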