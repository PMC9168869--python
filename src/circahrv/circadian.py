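"""Wake-anchored standardized day, polynomial trend, window medians.

Each recorded day is mapped onto a standardized coordinate in [0, 1):
the wake phase occupies [0, 0.5) (0 = wake onset) and the sleep phase
[0.5, 1) (0.5 = sleep onset), each linearly rescaled to its half
regardless of actual durations.  All days of a subject are pooled
(superimposed) and a single least-squares polynomial (default degree 10)
is fitted per metric; to avoid spurious boundary behavior, points within
a margin of each end are replicated across the periodic boundary before
fitting.  The fitted trend is then summarized by the medians of ten
0.1-wide windows (five wake, five sleep).
"""
from __future__ import annotations

import itertools
import logging
import math
from typing import Dict, Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.utils.validation import check_is_fitted

from .types import CircadianTrend, SleepWakeLabels

logger = logging.getLogger(__name__)

DEFAULT_DEGREE = 10
DEFAULT_MARGIN = 0.15
POINTS_PER_BIN = 1000


def standardize_positions(times: np.ndarray, labels: SleepWakeLabels) -> np.ndarray:
    """Standardized-day position of each absolute time (seconds since
    recording start); NaN for times outside any labeled interval."""
    labels.validate()
    times = np.asarray(times, dtype=float)
    pos = np.full(times.shape, np.nan)
    w = labels.wake_onset
    s = labels.sleep_onset
    day = np.searchsorted(w, times, side="right") - 1
    ok = (day >= 0) & (day < labels.n_days)
    d = day[ok]
    t = times[ok]
    in_wake = t < s[d]
    p = np.empty(t.shape)
    p[in_wake] = 0.5 * (t[in_wake] - w[d[in_wake]]) / (s[d[in_wake]] - w[d[in_wake]])
    sl = ~in_wake
    p[sl] = 0.5 + 0.5 * (t[sl] - s[d[sl]]) / (w[d[sl] + 1] - s[d[sl]])
    pos[ok] = np.clip(p, 0.0, np.nextafter(1.0, 0.0))
    return pos


def auto_label_sleep_wake(
    activity_t: np.ndarray,
    activity_mag: np.ndarray,
    beat_t: Optional[np.ndarray] = None,
    ibi: Optional[np.ndarray] = None,
    subject_id: str = "",
    epoch_s: float = 300.0,
    smooth_epochs: int = 12,
) -> SleepWakeLabels:
    """Convenience heuristic sleep/wake labeler.

    Scores each 5-min epoch by standardized movement (minus standardized
    mean IBI when beats are given — sleep is still and slow), smooths
    with a rolling median, thresholds at the midpoint between the
    typical wake and sleep score, and keeps the longest sleep block per
    24 h. This is a rough stand-in for manual labeling of accelerometer
    and heart-rate traces, intended for exploration only; analyses
    should prefer curated labels.
    """
    activity_t = np.asarray(activity_t, dtype=float)
    n_ep = int(activity_t[-1] // epoch_s)
    if n_ep < 12:
        raise ValueError("need at least an hour of activity data")
    edges = epoch_s * np.arange(n_ep + 1)
    idx = np.searchsorted(activity_t, edges)
    act = np.array([
        np.mean(activity_mag[idx[k]:idx[k + 1]]) if idx[k + 1] > idx[k] else np.nan
        for k in range(n_ep)
    ])
    score = (act - np.nanmean(act)) / (np.nanstd(act) + 1e-12)
    if beat_t is not None and ibi is not None:
        bidx = np.searchsorted(np.asarray(beat_t, dtype=float), edges)
        mibi = np.array([
            np.mean(ibi[bidx[k]:bidx[k + 1]]) if bidx[k + 1] > bidx[k] else np.nan
            for k in range(n_ep)
        ])
        score = score - (mibi - np.nanmean(mibi)) / (np.nanstd(mibi) + 1e-12)
    score = pd.Series(score).rolling(smooth_epochs, center=True, min_periods=1).median().to_numpy()
    lo, hi = np.nanquantile(score, [0.15, 0.85])
    asleep = score < 0.5 * (lo + hi)
    day_of_ep = (edges[:-1] // 86400.0).astype(int)
    wake_onsets, sleep_onsets = [], []
    for d in range(day_of_ep.max() + 1):
        in_day = day_of_ep == d
        runs = _label_runs(asleep & in_day)
        if not runs:
            continue
        start, stop = max(runs, key=lambda r: r[1] - r[0])
        sleep_onsets.append(edges[start])
        wake_onsets.append(edges[stop] if stop < n_ep else edges[-1])
    if not sleep_onsets:
        raise ValueError("no sleep period detected")
    wake = np.concatenate([[0.0], np.asarray(wake_onsets)])
    sleep = np.asarray(sleep_onsets)
    keep = np.ones(sleep.size, dtype=bool)  # enforce wake < sleep < next wake
    for d in range(sleep.size):
        if not (wake[d] < sleep[d] < wake[d + 1]):
            keep[d] = False
    if not keep.all():
        logger.info("auto-labeler dropped %d malformed day(s)", int((~keep).sum()))
        sleep = sleep[keep]
        wake = np.concatenate([wake[:1], wake[1:][keep]])
    return SleepWakeLabels(subject_id, wake, sleep)


def _label_runs(mask: np.ndarray):
    d = np.diff(mask.astype(np.int8))
    starts = list(np.where(d == 1)[0] + 1)
    stops = list(np.where(d == -1)[0] + 1)
    if mask[0]:
        starts.insert(0, 0)
    if mask[-1]:
        stops.append(mask.size)
    return list(zip(starts, stops))


def standardize_time(segments, labels: SleepWakeLabels) -> pd.DataFrame:
    """Positions of segment midpoints; segments outside labeled intervals
    are dropped (logged)."""
    mids = np.asarray([s.midpoint for s in segments], dtype=float)
    pos = standardize_positions(mids, labels)
    keep = np.isfinite(pos)
    if (~keep).any():
        logger.info("dropping %d segments outside labeled sleep/wake intervals", int((~keep).sum()))
    return pd.DataFrame({"segment_index": np.where(keep)[0], "position": pos[keep]})


def replicate_margins(pos: np.ndarray, val: np.ndarray, margin_fraction: float):
    """Copy end-of-sleep points before 0 and start-of-wake points after 1
    (periodic continuation) for boundary-stable fitting."""
    if margin_fraction <= 0:
        return pos, val
    left = pos >= 1.0 - margin_fraction   # end of sleep -> before wake onset
    right = pos < margin_fraction         # start of wake -> after the night
    pos_ext = np.concatenate([pos[left] - 1.0, pos, pos[right] + 1.0])
    val_ext = np.concatenate([val[left], val, val[right]])
    return pos_ext, val_ext


class CircadianTrendRegressor(BaseEstimator, RegressorMixin):
    """Least-squares polynomial trend over the standardized day.

    The polynomial is represented in a Chebyshev basis over the
    margin-extended domain (a degree-10 monomial fit on [0, 1] is badly
    conditioned; the fitted function is basis-independent).

    Parameters
    ----------
    degree : polynomial degree (default 10). Automatically reduced to
        n_points - 2 when there are too few points (logged).
    margin_fraction : fraction of the day replicated across each
        periodic boundary before fitting (0 disables replication).

    Attributes
    ----------
    chebyshev_ : fitted ``numpy.polynomial.Chebyshev``.
    degree_ : degree actually used.
    window_medians_ : ten medians of the fitted trend over the 0.1-wide
        standardized-day bins (dense-grid medians).
    n_points_ : raw points per bin.
    """

    def __init__(self, degree: int = DEFAULT_DEGREE, margin_fraction: float = DEFAULT_MARGIN):
        self.degree = degree
        self.margin_fraction = margin_fraction

    @staticmethod
    def _positions(X) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if X.ndim == 2:
            if X.shape[1] != 1:
                raise ValueError("expected a single position feature")
            X = X[:, 0]
        return X

    def fit(self, X, y):
        pos = self._positions(X)
        y = np.asarray(y, dtype=float)
        if pos.shape != y.shape:
            raise ValueError("X and y length mismatch")
        ok = np.isfinite(pos) & np.isfinite(y)
        pos, y = pos[ok], y[ok]
        if pos.size < 4:
            raise ValueError("need at least 4 points to fit a trend")
        degree = self.degree
        if pos.size <= degree + 1:
            degree = pos.size - 2
            logger.warning("too few points for degree %d; reduced to %d", self.degree, degree)
        pos_ext, y_ext = replicate_margins(pos, y, self.margin_fraction)
        domain = [0.0 - self.margin_fraction, 1.0 + self.margin_fraction]
        self.chebyshev_ = np.polynomial.Chebyshev.fit(pos_ext, y_ext, deg=degree, domain=domain, window=[-1, 1])
        self.degree_ = degree
        grid = self.chebyshev_(_dense_grid())
        self.window_medians_ = np.median(grid.reshape(10, POINTS_PER_BIN), axis=1)
        self.n_points_ = np.bincount(np.minimum((pos * 10).astype(int), 9), minlength=10)
        self.n_features_in_ = 1
        return self

    def predict(self, X):
        check_is_fitted(self, "chebyshev_")
        return self.chebyshev_(self._positions(X))


def _dense_grid() -> np.ndarray:
    return np.linspace(0.0, 1.0, 10 * POINTS_PER_BIN, endpoint=False)


def fit_trend(
    positions: np.ndarray,
    values: np.ndarray,
    degree: int = DEFAULT_DEGREE,
    margin_fraction: float = DEFAULT_MARGIN,
    metric: str = "",
) -> CircadianTrend:
    """Fit one metric's circadian trend; thin wrapper over
    :class:`CircadianTrendRegressor`."""
    reg = CircadianTrendRegressor(degree=degree, margin_fraction=margin_fraction).fit(positions, values)
    return CircadianTrend(
        metric=metric,
        chebyshev=reg.chebyshev_,
        window_medians=reg.window_medians_,
        n_points=reg.n_points_,
        degree=reg.degree_,
        margin_fraction=margin_fraction,
    )


def window_medians(trend: CircadianTrend, points_per_bin: int = POINTS_PER_BIN) -> np.ndarray:
    """Ten medians of the fitted trend, each over a 1000-point uniform
    grid inside its 0.1-wide standardized-day bin."""
    pos = np.linspace(0.0, 1.0, 10 * points_per_bin, endpoint=False)
    return np.median(trend(pos).reshape(10, points_per_bin), axis=1)


def stability_analysis(
    points: pd.DataFrame,
    subset_sizes: Sequence[int],
    max_combinations: int = 5000,
    seed: int = 0,
    value_columns: Optional[Iterable[str]] = None,
    degree: int = DEFAULT_DEGREE,
    margin_fraction: float = DEFAULT_MARGIN,
) -> pd.DataFrame:
    """Trend stability over day subsets.

    ``points`` must have columns ``day``, ``position`` and one or more
    value columns.  For each subset size k, the trend is refitted on
    every combination of k recorded days (all combinations when there
    are at most ``max_combinations``, otherwise a seeded random sample
    without replacement) and the ten-window-median vector is Pearson-
    correlated with the full-data vector.  Returns tidy rows
    (metric, k, combo, r).
    """
    if value_columns is None:
        value_columns = [c for c in points.columns if c not in ("day", "position")]
    days = np.sort(points["day"].unique())
    if days.size < 2:
        raise ValueError("stability analysis needs >= 2 recorded days")
    rng = np.random.default_rng(seed)
    pos_all = points["position"].to_numpy()
    full = {
        m: fit_trend(pos_all, points[m].to_numpy(), degree, margin_fraction, m).window_medians
        for m in value_columns
    }
    rows = []
    for k in subset_sizes:
        if k > days.size:
            logger.info("subset size %d exceeds available days (%d); skipped", k, days.size)
            continue
        n_combo = math.comb(days.size, k)
        if n_combo <= max_combinations:
            combos = list(itertools.combinations(days, k))
        else:
            combos = []
            seen = set()
            while len(combos) < max_combinations:
                pick = tuple(sorted(rng.choice(days, size=k, replace=False)))
                if pick not in seen:
                    seen.add(pick)
                    combos.append(pick)
        for ci, combo in enumerate(combos):
            mask = points["day"].isin(combo).to_numpy()
            sub = points[mask]
            for m in value_columns:
                try:
                    med = fit_trend(sub["position"].to_numpy(), sub[m].to_numpy(),
                                    degree, margin_fraction, m).window_medians
                except ValueError:
                    continue
                r = float(np.corrcoef(med, full[m])[0, 1])
                rows.append({"metric": m, "k": k, "combo": ci, "r": r})
    return pd.DataFrame(rows)
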