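"""Summary statistics of branched fluorescence trajectories.

Amplitude is the raw series height at a detected peak; period is the
interval between consecutive peaks along a branch.  Peaks are detected on
a lightly smoothed copy of each root-to-leaf branch and de-duplicated
across branches that share their early history, so each oscillation is
counted once.  Sister-cell similarity is quantified by the Pearson
correlation of fluorescence between the two daughters of each division,
as a function of the time elapsed since that division.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from scipy.signal import find_peaks as _scipy_find_peaks
from scipy.stats import ks_2samp, pearsonr

from .lineage import LineageTree
from .trajectory import FRAME_INTERVAL_MIN, Trajectory

__all__ = [
    "PeakSet",
    "CorrelationFunction",
    "SummaryStats",
    "find_peaks",
    "tree_peaks",
    "amplitude_and_period_cv",
    "sister_correlation",
    "summarize",
    "cv_distance",
    "corr_distance",
    "ks_compare",
]

DEFAULT_PROMINENCE_FRAC = 0.2
DEFAULT_SMOOTH_WINDOW = 3  # frames; detection only, amplitudes stay raw
DEFAULT_TRANSIENT_MIN = 30.0


@dataclass
class PeakSet:
    """Pooled oscillation peaks: heights (AU) and peak-to-peak intervals (min)."""

    peak_times: np.ndarray
    heights: np.ndarray
    intervals: np.ndarray


@dataclass
class CorrelationFunction:
    """Sister-cell Pearson correlation per lag after division."""

    lags: np.ndarray  # min
    rho: np.ndarray  # NaN where fewer than 2 pairs
    n_pairs: np.ndarray

    def on(self, lags: np.ndarray) -> np.ndarray:
        """Values restricted to the given lags (must be a subset)."""
        idx = {l: i for i, l in enumerate(self.lags)}
        return np.array([self.rho[idx[l]] if l in idx else np.nan for l in lags])


@dataclass
class SummaryStats:
    amplitude_cv: float
    period_cv: float
    mean_period: float
    mean_amplitude: float
    corr: CorrelationFunction
    n_peaks: int = 0
    n_intervals: int = 0

    def to_dict(self) -> dict:
        return {
            "amplitude_cv": self.amplitude_cv,
            "period_cv": self.period_cv,
            "mean_period": self.mean_period,
            "mean_amplitude": self.mean_amplitude,
            "n_peaks": self.n_peaks,
            "n_intervals": self.n_intervals,
            "correlation": {
                "lags": self.corr.lags.tolist(),
                "rho": self.corr.rho.tolist(),
                "n_pairs": self.corr.n_pairs.tolist(),
            },
        }


def _smooth(x: np.ndarray, window: int) -> np.ndarray:
    if window <= 1 or x.size < window:
        return x
    kernel = np.ones(window) / window
    pad = window // 2
    xp = np.pad(x, pad, mode="edge")
    return np.convolve(xp, kernel, mode="valid")[: x.size]


def find_peaks(
    traj: Trajectory,
    min_prominence_frac: float = DEFAULT_PROMINENCE_FRAC,
    smooth_window: int = DEFAULT_SMOOTH_WINDOW,
) -> PeakSet:
    """Detect oscillation peaks in a single uniformly sampled series.

    Detection runs on a ``smooth_window``-frame moving average with a
    prominence threshold relative to the series range; reported amplitudes
    are the raw values at the detected peak times.
    """
    x = traj.values
    rng_x = float(x.max() - x.min()) if x.size else 0.0
    if rng_x <= 0 or x.size < 3:
        empty = np.empty(0)
        return PeakSet(empty, empty, empty)
    xs = _smooth(x, smooth_window)
    idx, _ = _scipy_find_peaks(xs, prominence=min_prominence_frac * rng_x)
    times = traj.times[idx]
    heights = x[idx]
    intervals = np.diff(times)
    return PeakSet(times, heights, intervals)


def tree_peaks(
    tree: LineageTree,
    min_prominence_frac: float = DEFAULT_PROMINENCE_FRAC,
    smooth_window: int = DEFAULT_SMOOTH_WINDOW,
    transient_min: float = DEFAULT_TRANSIENT_MIN,
) -> PeakSet:
    """Pooled peaks of a lineage tree, counted once per oscillation.

    Peaks are detected along every root-to-leaf branch (so each peak sees
    its surrounding troughs even across divisions) and de-duplicated by the
    cell and frame at which they occur; intervals are de-duplicated by
    their peak pair.  Peaks earlier than ``transient_min`` are discarded.
    """
    seen_peaks: set[tuple[int, float]] = set()
    seen_intervals: set[tuple[int, float, int, float]] = set()
    pt, ph, iv = [], [], []
    for path in tree.paths():
        t, x, owner = tree.branch_series(path)
        if t.size < 3:
            continue
        rng_x = x.max() - x.min()
        if rng_x <= 0:
            continue
        xs = _smooth(x, smooth_window)
        idx, _ = _scipy_find_peaks(xs, prominence=min_prominence_frac * rng_x)
        kept = []
        for i in idx:
            if t[i] < transient_min:
                continue
            kept.append(i)
            key = (int(owner[i]), float(t[i]))
            if key not in seen_peaks:
                seen_peaks.add(key)
                pt.append(t[i])
                ph.append(x[i])
        for i0, i1 in zip(kept[:-1], kept[1:]):
            key = (int(owner[i0]), float(t[i0]), int(owner[i1]), float(t[i1]))
            if key not in seen_intervals:
                seen_intervals.add(key)
                iv.append(t[i1] - t[i0])
    return PeakSet(np.asarray(pt), np.asarray(ph), np.asarray(iv))


def pool_peaks(peaksets: Iterable[PeakSet]) -> PeakSet:
    peaksets = list(peaksets)
    return PeakSet(
        np.concatenate([p.peak_times for p in peaksets]) if peaksets else np.empty(0),
        np.concatenate([p.heights for p in peaksets]) if peaksets else np.empty(0),
        np.concatenate([p.intervals for p in peaksets]) if peaksets else np.empty(0),
    )


#: intervals beyond this multiple of the median are treated as missed-beat
#: detector artifacts (a skipped peak doubles the apparent period) and are
#: censored from period statistics
MISSED_BEAT_FACTOR = 1.6


def amplitude_and_period_cv(peaks: PeakSet) -> tuple[float, float]:
    """Sample CV (n-1 SD over mean) of pooled peak heights and intervals.

    Peak-to-peak intervals larger than ``MISSED_BEAT_FACTOR`` times the
    median interval are excluded: they arise when the detector misses a
    low peak, which would otherwise count a double period.
    """
    if peaks.heights.size < 2 or peaks.intervals.size < 2:
        raise ValueError("need at least two peaks and two intervals")
    iv = _censor_missed_beats(peaks.intervals)
    mean_h = peaks.heights.mean()
    mean_i = iv.mean()
    if mean_h == 0 or mean_i == 0:
        raise ValueError("zero mean; CV undefined")
    return (
        float(peaks.heights.std(ddof=1) / mean_h),
        float(iv.std(ddof=1) / mean_i),
    )


def _censor_missed_beats(intervals: np.ndarray) -> np.ndarray:
    med = np.median(intervals)
    kept = intervals[intervals <= MISSED_BEAT_FACTOR * med]
    return kept if kept.size >= 2 else intervals


def _pair_values_at(tree: LineageTree, cid: int, t: float) -> float | None:
    node = tree.nodes[cid]
    # a sister contributes only until its own next division
    if t < node.birth_time - 1e-9 or t > node.division_time + 1e-9:
        return None
    i = int(round((t - node.frame_times[0]) / tree.frame_interval)) if node.frame_times.size else -1
    if i < 0 or i >= node.frame_times.size:
        return None
    if abs(node.frame_times[i] - t) > 1e-6:
        return None
    return float(node.fluorescence[i])


def sister_correlation(
    trees: LineageTree | Sequence[LineageTree],
    max_lag: float = 30.0,
    frame_interval: float = FRAME_INTERVAL_MIN,
) -> CorrelationFunction:
    """Pearson correlation of sister-cell fluorescence vs time since division.

    For each division and each lag t on the frame grid the pair
    (X1(t_div + t), X2(t_div + t)) is collected while both sisters are
    still tracked (neither has divided again); the correlation is computed
    per lineage over its pairs and averaged across lineages.
    """
    if isinstance(trees, LineageTree):
        trees = [trees]
    lags = np.arange(frame_interval, max_lag + 0.5 * frame_interval, frame_interval)
    per_lineage = []
    n_pairs_tot = np.zeros(lags.size, dtype=int)
    for tree in trees:
        rho_l = np.full(lags.size, np.nan)
        for li, lag in enumerate(lags):
            x1s, x2s = [], []
            for t_div, c1, c2 in tree.sister_pairs():
                t = math.ceil((t_div) / frame_interval - 1e-9) * frame_interval
                # first frame at or after division, then offset by lag - interval
                t_query = t + (lag - frame_interval)
                v1 = _pair_values_at(tree, c1, t_query)
                v2 = _pair_values_at(tree, c2, t_query)
                if v1 is not None and v2 is not None:
                    x1s.append(v1)
                    x2s.append(v2)
            if len(x1s) >= 2 and np.std(x1s) > 0 and np.std(x2s) > 0:
                rho_l[li] = pearsonr(x1s, x2s)[0]
                n_pairs_tot[li] += len(x1s)
        per_lineage.append(rho_l)
    stacked = np.vstack(per_lineage) if per_lineage else np.full((1, lags.size), np.nan)
    valid = ~np.isnan(stacked)
    n_valid = valid.sum(axis=0)
    sums = np.where(valid, stacked, 0.0).sum(axis=0)
    rho = np.where(n_valid > 0, sums / np.maximum(n_valid, 1), np.nan)
    return CorrelationFunction(lags, rho, n_pairs_tot)


def summarize(
    trees: LineageTree | Sequence[LineageTree],
    max_lag: float = 30.0,
    min_prominence_frac: float = DEFAULT_PROMINENCE_FRAC,
    smooth_window: int = DEFAULT_SMOOTH_WINDOW,
    transient_min: float = DEFAULT_TRANSIENT_MIN,
) -> SummaryStats:
    """Pooled amplitude/period CVs and the sister-correlation function."""
    if isinstance(trees, LineageTree):
        trees = [trees]
    pooled = pool_peaks(
        tree_peaks(t, min_prominence_frac, smooth_window, transient_min)
        for t in trees
    )
    amp_cv, per_cv = amplitude_and_period_cv(pooled)
    corr = sister_correlation(trees, max_lag=max_lag)
    return SummaryStats(
        amplitude_cv=amp_cv,
        period_cv=per_cv,
        mean_period=float(_censor_missed_beats(pooled.intervals).mean()),
        mean_amplitude=float(pooled.heights.mean()),
        corr=corr,
        n_peaks=int(pooled.heights.size),
        n_intervals=int(pooled.intervals.size),
    )


def cv_distance(cv_sim: float, cv_exp: float) -> float:
    """Absolute difference of coefficients of variation."""
    return abs(cv_sim - cv_exp)


def corr_distance(c_sim: CorrelationFunction, c_exp: CorrelationFunction) -> float:
    """L2 norm of the pointwise correlation difference over shared lags."""
    shared = np.intersect1d(c_sim.lags, c_exp.lags)
    if shared.size == 0:
        raise ValueError("correlation functions share no lags")
    a = c_sim.on(shared)
    b = c_exp.on(shared)
    keep = ~(np.isnan(a) | np.isnan(b))
    if not np.any(keep):
        raise ValueError("correlation functions share no defined lags")
    return float(np.sqrt(np.sum((a[keep] - b[keep]) ** 2)))


def ks_compare(amps_a: np.ndarray, amps_b: np.ndarray) -> tuple[float, float]:
    """Two-sample KS test on mean-rescaled amplitude distributions."""
    a = np.asarray(amps_a, dtype=float)
    b = np.asarray(amps_b, dtype=float)
    if a.size < 10 or b.size < 10:
        raise ValueError("need at least 10 amplitudes per sample")
    res = ks_2samp(a / a.mean(), b / b.mean())
    return float(res.statistic), float(res.pvalue)
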