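"""Raw IBI stream -> validity-filtered 5-minute segments.

The stages mirror standard wearable HRV practice: a robust local-outlier
screen for beat-detection artifacts, removal plus time-conserving linear
interpolation of the flagged runs, division into non-overlapping 5-min
segments, and exclusion of segments that are unreliable (long interpolated
runs) or contaminated by movement.
"""
from __future__ import annotations

import logging
from typing import List, Optional

import numpy as np
import pandas as pd

from ._fast import flag_outliers
from .types import (
    ARTIFACT,
    CLEAN,
    EXCLUSION_ACTIVITY,
    EXCLUSION_INTERPOLATION,
    EXCLUSION_NONE,
    EXCLUSION_TOO_FEW,
    INTERPOLATED,
    SEGMENT_SECONDS,
    ActivitySeries,
    IbiSeries,
    Segment,
)

logger = logging.getLogger(__name__)

#: Quartile deviation of a Gaussian is 0.6745 sigma; dividing by it turns
#: the local QD into a robust SD estimate, so DEFAULT_COEF is a z-score.
QD_TO_SD = 0.6745

DEFAULT_WINDOW_BEATS = 41
DEFAULT_COEF = 3.32
DEFAULT_FLOOR_MS = 50.0
DEFAULT_MIN_BEATS = 100
MAX_INTERPOLATED_RUN = 4  # "more than four in a row" is discarded


def detect_artifacts(
    series: IbiSeries,
    window_beats: int = DEFAULT_WINDOW_BEATS,
    coef: float = DEFAULT_COEF,
    floor_ms: float = DEFAULT_FLOOR_MS,
) -> IbiSeries:
    """Flag beats deviating from their local rhythm as artifacts.

    Beat i is flagged iff ``|ibi_i - median_i| > max(coef * QD_i / 0.6745,
    floor_ms)`` where median and quartile deviation are taken over the
    ``window_beats``-wide neighborhood excluding beat i (windows clamped
    at the series boundaries).  ``coef`` therefore acts on a robust-SD
    scale; the default 3.32 corresponds to a ~0.1% two-sided false-flag
    rate on clean Gaussian variability.
    """
    series.validate()
    if window_beats < 5 or window_beats % 2 == 0:
        raise ValueError("window_beats must be odd and >= 5")
    flags = np.zeros(series.n_beats, dtype=np.uint8)
    if series.n_beats < window_beats:
        logger.warning(
            "series %s shorter than artifact window (%d < %d): no flags assigned",
            series.subject_id, series.n_beats, window_beats,
        )
        return IbiSeries(series.subject_id, series.t.copy(), series.ibi.copy(), flags)
    flags = flag_outliers(series.ibi, window_beats, coef / QD_TO_SD, floor_ms)
    flags[flags != 0] = ARTIFACT
    # timestamps / intervals are shared with the input (not mutated here)
    return IbiSeries(series.subject_id, series.t, series.ibi, flags)


def _runs(mask: np.ndarray):
    """Start/stop (half-open) index pairs of each maximal True run."""
    if not mask.any():
        return []
    d = np.diff(mask.astype(np.int8))
    starts = list(np.where(d == 1)[0] + 1)
    stops = list(np.where(d == -1)[0] + 1)
    if mask[0]:
        starts.insert(0, 0)
    if mask[-1]:
        stops.append(mask.size)
    return list(zip(starts, stops))


def correct_artifacts(series: IbiSeries) -> IbiSeries:
    """Replace each flagged run by linearly interpolated beats.

    The run's elapsed time is conserved: the replacement count k is the
    nearest integer to gap-time / local mean IBI (at least 1), and the k
    replacement intervals ramp linearly between the flanking clean beats,
    rescaled to sum exactly to the gap.  Runs touching the series
    boundary have no flanking beat on one side and are dropped instead.
    Timestamps are rebuilt cumulatively from the first retained beat.
    """
    mask = series.flags == ARTIFACT
    if not mask.any():
        return IbiSeries(series.subject_id, series.t, series.ibi, series.flags)
    n = series.n_beats
    runs = _runs(mask)
    starts = np.array([r[0] for r in runs], dtype=np.int64)
    stops = np.array([r[1] for r in runs], dtype=np.int64)
    interior = (starts > 0) & (stops < n)
    if (~interior).any():
        logger.info(
            "subject %s: dropping %d flagged beats at series boundary",
            series.subject_id, int((stops[~interior] - starts[~interior]).sum()),
        )
    s_j, e_j = starts[interior], stops[interior]
    gap = slice_sums(series.ibi, s_j, e_j)
    left = series.ibi[s_j - 1]
    right = series.ibi[e_j]
    k = np.maximum(1, np.round(gap / (0.5 * (left + right))).astype(np.int64))
    scale = gap / (k * 0.5 * (left + right))
    keep = ~mask
    cumkeep = np.concatenate([[0], np.cumsum(keep)])
    cumk = np.concatenate([[0], np.cumsum(k)])
    n_out = int(cumkeep[-1] + cumk[-1])
    ibi = np.empty(n_out)
    flags = np.empty(n_out, dtype=np.uint8)
    # output slot of each kept beat: kept-rank + replacements inserted
    # earlier (a step function over the original index, jumping at each
    # interior run's stop)
    kept_idx = np.where(keep)[0]
    reps_step = np.repeat(cumk, np.diff(np.concatenate([[0], e_j, [n]])))
    out_kept = np.arange(kept_idx.size) + reps_step[kept_idx]
    ibi[out_kept] = series.ibi[kept_idx]
    flags[out_kept] = series.flags[kept_idx]
    if s_j.size:
        # flat replacement values: linear ramp between the flanking beats,
        # rescaled so each gap's elapsed time is conserved exactly
        rep_run = np.repeat(np.arange(s_j.size), k)
        p = np.arange(int(cumk[-1])) - np.repeat(cumk[:-1], k) + 1.0
        vals = (left[rep_run] + (right - left)[rep_run] * p / (k[rep_run] + 1.0)) * scale[rep_run]
        start_out = cumkeep[s_j] + cumk[:-1]
        out_rep = np.repeat(start_out, k) + (p - 1.0).astype(np.int64)
        ibi[out_rep] = vals
        flags[out_rep] = INTERPOLATED
    # anchor timestamps so the first retained beat keeps its original time
    offset = (series.t[kept_idx[0]] - ibi[0] / 1000.0) if kept_idx.size else 0.0
    t = np.cumsum(ibi) / 1000.0 + offset
    return IbiSeries(series.subject_id, t, ibi, flags)


def slice_sums(x: np.ndarray, i0: np.ndarray, i1: np.ndarray) -> np.ndarray:
    """Sums of ``x`` over half-open index slices [i0, i1) in one pass."""
    x2 = np.concatenate([x, [0.0]])
    bounds = np.empty(i0.size * 2, dtype=np.int64)
    bounds[0::2] = i0
    bounds[1::2] = i1
    s = np.add.reduceat(x2, bounds)[0::2]
    s[i0 == i1] = 0.0
    return s


def _seg_max_interp_run(idx: np.ndarray, seg: np.ndarray, n_seg: int) -> np.ndarray:
    """Longest run of interpolated beats inside each segment, given the
    interpolated beat indices and their segment ids (runs are broken at
    segment boundaries: a segment only sees its own part)."""
    out = np.zeros(n_seg, dtype=np.int64)
    if idx.size == 0:
        return out
    brk = np.concatenate([[True], (np.diff(idx) != 1) | (seg[1:] != seg[:-1])])
    run_id = np.cumsum(brk) - 1
    lengths = np.bincount(run_id)
    run_seg = seg[brk]
    ok = (run_seg >= 0) & (run_seg < n_seg)
    np.maximum.at(out, run_seg[ok], lengths[ok])
    return out


def segment_table(
    series: IbiSeries,
    activity: Optional[ActivitySeries] = None,
    seg_seconds: float = SEGMENT_SECONDS,
) -> pd.DataFrame:
    """Vectorized segment bookkeeping.

    Returns one row per full 5-min window from recording start (trailing
    partial window discarded) with beat index bounds ``i0``/``i1``, beat
    and interpolation counts, the longest within-segment interpolated run
    and the mean movement magnitude over the span.
    """
    series.validate()
    if series.n_beats == 0:
        raise ValueError("empty IBI series")
    t0 = 0.0
    total = series.t[-1] - t0
    n_seg = int(total // seg_seconds)
    cols = ["start", "i0", "i1", "n_beats", "n_interpolated", "max_interpolated_run", "mean_activity"]
    if n_seg == 0:
        return pd.DataFrame(columns=cols)
    starts = t0 + seg_seconds * np.arange(n_seg)
    # beat belongs to the segment containing its timestamp
    i0 = np.searchsorted(series.t, starts, side="left")
    i1 = np.searchsorted(series.t, starts + seg_seconds, side="left")
    n_beats = i1 - i0
    interp_idx = np.where(series.flags == INTERPOLATED)[0]
    seg_of_interp = np.floor((series.t[interp_idx] - t0) / seg_seconds).astype(np.int64)
    in_range = seg_of_interp < n_seg
    n_interp = np.bincount(seg_of_interp[in_range], minlength=n_seg)
    max_run = _seg_max_interp_run(interp_idx, seg_of_interp, n_seg)
    mean_act = np.full(n_seg, np.nan)
    if activity is not None and activity.t.size:
        a0 = np.searchsorted(activity.t, starts, side="left")
        a1 = np.searchsorted(activity.t, starts + seg_seconds, side="left")
        cnt = (a1 - a0).astype(float)
        with np.errstate(invalid="ignore"):
            mean_act = np.where(
                cnt > 0,
                slice_sums(np.asarray(activity.magnitude, dtype=np.float64), a0, a1)
                / np.maximum(cnt, 1),
                np.nan,
            )
    return pd.DataFrame({
        "start": starts,
        "i0": i0,
        "i1": i1,
        "n_beats": n_beats,
        "n_interpolated": n_interp,
        "max_interpolated_run": max_run,
        "mean_activity": mean_act,
    })


def segment(
    series: IbiSeries,
    activity: Optional[ActivitySeries] = None,
    seg_seconds: float = SEGMENT_SECONDS,
) -> List[Segment]:
    """Divide a corrected series into non-overlapping 5-min segments."""
    table = segment_table(series, activity, seg_seconds)
    out = []
    for row in table.itertuples(index=False):
        i0, i1 = int(row.i0), int(row.i1)
        out.append(Segment(
            subject_id=series.subject_id,
            start=float(row.start),
            ibi=series.ibi[i0:i1],
            flags=series.flags[i0:i1],
            t=series.t[i0:i1],
            n_interpolated=int(row.n_interpolated),
            max_interpolated_run=int(row.max_interpolated_run),
            mean_activity=float(row.mean_activity) if np.isfinite(row.mean_activity) else np.nan,
            duration=seg_seconds,
        ))
    return out


def apply_validity(
    table: pd.DataFrame,
    activity_threshold: Optional[float] = None,
    min_beats: int = DEFAULT_MIN_BEATS,
    max_interp_run: int = MAX_INTERPOLATED_RUN,
) -> pd.DataFrame:
    """Validity columns for a segment table; first matching rule wins in
    the order interpolation_run > activity > too_few_beats."""
    table = table.copy()
    reason = np.full(len(table), EXCLUSION_NONE, dtype=object)
    bad_interp = table["max_interpolated_run"].to_numpy() > max_interp_run
    reason[bad_interp] = EXCLUSION_INTERPOLATION
    if activity_threshold is not None:
        act = table["mean_activity"].to_numpy()
        bad_act = np.isfinite(act) & (act > activity_threshold) & (reason == EXCLUSION_NONE)
        reason[bad_act] = EXCLUSION_ACTIVITY
    few = (table["n_beats"].to_numpy() < min_beats) & (reason == EXCLUSION_NONE)
    reason[few] = EXCLUSION_TOO_FEW
    table["exclusion_reason"] = reason
    table["valid"] = reason == EXCLUSION_NONE
    return table


def filter_segments(
    segments: List[Segment],
    activity_threshold: Optional[float] = None,
    min_beats: int = DEFAULT_MIN_BEATS,
    max_interp_run: int = MAX_INTERPOLATED_RUN,
) -> List[Segment]:
    """Set validity on Segment objects (idempotent)."""
    for s in segments:
        if s.max_interpolated_run > max_interp_run:
            s.valid, s.exclusion_reason = False, EXCLUSION_INTERPOLATION
        elif (
            activity_threshold is not None
            and np.isfinite(s.mean_activity)
            and s.mean_activity > activity_threshold
        ):
            s.valid, s.exclusion_reason = False, EXCLUSION_ACTIVITY
        elif s.n_beats < min_beats:
            s.valid, s.exclusion_reason = False, EXCLUSION_TOO_FEW
        else:
            s.valid, s.exclusion_reason = True, EXCLUSION_NONE
    return segments


def wake_activity_threshold(
    table: pd.DataFrame,
    wake_mask: np.ndarray,
    quantile: float = 0.9,
) -> float:
    """Subject-specific activity cutoff: the ``quantile`` of wake-time
    mean segment activity (the default rule for 'excessive activity')."""
    act = table["mean_activity"].to_numpy()[np.asarray(wake_mask, dtype=bool)]
    act = act[np.isfinite(act)]
    if act.size == 0:
        return np.inf
    return float(np.quantile(act, quantile))
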