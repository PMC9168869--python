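"""Per-segment HRV metrics and normative percentage scores.

Time domain follows the standard task-force estimators (sample-SD SDNN,
RMSSD, pNN20/pNN50 with strict inequality); the Poincaré axes are
computed from the same segment's RMSSD/SDNN via the standard identities

    SD1 = RMSSD / sqrt(2)        SD2^2 = 2 SDNN^2 - RMSSD^2 / 2

which yield the exact conservation law SD1^2 + SD2^2 = 2 SDNN^2 on every
segment.  Spectral power uses a 4 Hz cubic-spline resampled, mean-removed
tachogram with a Welch estimate integrated over the LF (0.04-0.15 Hz) and
HF (0.15-0.40 Hz) bands.

Normative percentage scores divide each metric by the reference value for
the subject's sex, age band and the clock hour of the segment midpoint.
"""
from __future__ import annotations

import logging
from typing import Iterable, Optional, Tuple

import numpy as np
import pandas as pd
from scipy import interpolate, signal, stats

from .types import HrvVector, NormalizedHrv, NormativeTable, Segment

logger = logging.getLogger(__name__)

LF_BAND = (0.04, 0.15)
HF_BAND = (0.15, 0.40)
RESAMPLE_HZ = 4.0
WELCH_SEGMENT_S = 120.0

#: raw-metric name -> percentage-score name
PCT_OF = {"sdnn": "sdnn_pct", "sd1": "sd1_pct", "sd2": "sd2_pct", "hf": "hf_pct", "lf": "lf_pct"}


class UndefinedMetricError(ValueError):
    """Raised when a segment is too short for the requested metric."""


def _ibis(segment) -> np.ndarray:
    if isinstance(segment, Segment):
        return np.asarray(segment.ibi, dtype=float)
    return np.asarray(segment, dtype=float)


def time_domain(segment) -> Tuple[float, float, float, float]:
    """(sdnn, rmssd, pnn20, pnn50) of one segment's IBIs.

    SDNN is the n-1 sample SD; pNNx uses strict '> x ms'.
    """
    x = _ibis(segment)
    if x.size < 2:
        raise UndefinedMetricError("time-domain metrics need >= 2 beats")
    sdnn = float(np.std(x, ddof=1))
    d = np.abs(np.diff(x))
    rmssd = float(np.sqrt(np.mean(np.square(d))))
    pnn20 = float(100.0 * np.mean(d > 20.0))
    pnn50 = float(100.0 * np.mean(d > 50.0))
    return sdnn, rmssd, pnn20, pnn50


def poincare(segment) -> Tuple[float, float]:
    """(sd1, sd2) from the segment's RMSSD/SDNN identities."""
    x = _ibis(segment)
    if x.size < 3:
        raise UndefinedMetricError("Poincaré metrics need >= 3 beats")
    sdnn, rmssd, _, _ = time_domain(x)
    sd1 = rmssd / np.sqrt(2.0)
    sd2 = float(np.sqrt(max(0.0, 2.0 * sdnn**2 - 0.5 * rmssd**2)))
    return float(sd1), sd2


def frequency_domain(
    segment,
    t: Optional[np.ndarray] = None,
    lf_band: Tuple[float, float] = LF_BAND,
    hf_band: Tuple[float, float] = HF_BAND,
) -> Tuple[float, float]:
    """(hf, lf) band powers in ms² of one segment.

    The beat-time tachogram is resampled at 4 Hz with a cubic spline,
    mean-removed, and a Welch periodogram (120 s Hann windows, 50%
    overlap) is integrated over the two bands.
    """
    if isinstance(segment, Segment):
        x = np.asarray(segment.ibi, dtype=float)
        bt = np.asarray(segment.t, dtype=float)
    else:
        x = np.asarray(segment, dtype=float)
        bt = np.asarray(t, dtype=float) if t is not None else np.cumsum(x) / 1000.0
    if x.size < 4 or bt[-1] - bt[0] < 120.0:
        raise UndefinedMetricError("frequency-domain metrics need >= 2 min of beats")
    if np.ptp(x) == 0.0:
        return 0.0, 0.0
    fs = RESAMPLE_HZ
    grid = np.arange(bt[0], bt[-1], 1.0 / fs)
    tach = interpolate.CubicSpline(bt, x)(grid)
    tach = tach - tach.mean()
    nperseg = min(int(WELCH_SEGMENT_S * fs), tach.size)
    freqs, psd = signal.welch(tach, fs=fs, window="hann", nperseg=nperseg, noverlap=nperseg // 2)
    def band_power(lo, hi):
        m = (freqs >= lo) & (freqs < hi)
        if m.sum() < 2:
            return 0.0
        return float(np.trapezoid(psd[m], freqs[m]))
    return band_power(*hf_band), band_power(*lf_band)


def metrics_vector(segment) -> HrvVector:
    """All eight metrics of one segment (HF/LF set to NaN when the
    segment is too short for a spectral estimate)."""
    sdnn, rmssd, pnn20, pnn50 = time_domain(segment)
    sd1, sd2 = poincare(segment)
    try:
        hf, lf = frequency_domain(segment)
    except UndefinedMetricError:
        hf, lf = np.nan, np.nan
    return HrvVector(sdnn=sdnn, rmssd=rmssd, pnn20=pnn20, pnn50=pnn50, hf=hf, lf=lf, sd1=sd1, sd2=sd2)


def batch_time_domain(ibi: np.ndarray, i0: np.ndarray, i1: np.ndarray) -> pd.DataFrame:
    """Vectorized (sdnn, rmssd, sd1, sd2) for many contiguous segments.

    ``i0``/``i1`` are half-open beat index bounds per segment into
    ``ibi``.  Matches :func:`time_domain` / :func:`poincare` exactly;
    segments with < 3 beats yield NaN.
    """
    ibi = np.asarray(ibi, dtype=float)
    i0 = np.asarray(i0, dtype=np.int64)
    i1 = np.asarray(i1, dtype=np.int64)
    from .preprocess import slice_sums

    n = i1 - i0
    s1 = slice_sums(ibi, i0, i1)
    s2 = slice_sums(ibi * ibi, i0, i1)
    with np.errstate(invalid="ignore", divide="ignore"):
        var = (s2 - s1 * s1 / np.maximum(n, 1)) / np.maximum(n - 1, 1)
        sdnn = np.sqrt(np.maximum(var, 0.0))
    d2 = np.square(np.diff(ibi)) if ibi.size > 1 else np.zeros(0)
    # successive differences fully inside the segment: indices [i0, i1-1)
    j1 = np.maximum(i1 - 1, i0)
    sum_d2 = slice_sums(d2, i0, j1)
    n_d = np.maximum(j1 - i0, 0)
    with np.errstate(invalid="ignore", divide="ignore"):
        rmssd = np.sqrt(sum_d2 / np.maximum(n_d, 1))
    sd1 = rmssd / np.sqrt(2.0)
    sd2_sq = 2.0 * sdnn**2 - 0.5 * rmssd**2
    sd2 = np.sqrt(np.maximum(sd2_sq, 0.0))
    out = pd.DataFrame({"sdnn": sdnn, "rmssd": rmssd, "sd1": sd1, "sd2": sd2})
    out[n < 3] = np.nan
    return out


def normalize(
    metrics: HrvVector,
    sex: str,
    age: float,
    clock_hour: int,
    table: NormativeTable,
) -> NormalizedHrv:
    """Percentage scores: 100 * metric / reference for the matching cell."""
    def pct(name, value):
        if value is None or not np.isfinite(value):
            return None
        return float(100.0 * value / table.lookup(sex, age, clock_hour, name))
    return NormalizedHrv(
        sdnn_pct=pct("sdnn", metrics.sdnn),
        sd1_pct=pct("sd1", metrics.sd1),
        sd2_pct=pct("sd2", metrics.sd2),
        hf_pct=pct("hf", metrics.hf),
        lf_pct=pct("lf", metrics.lf),
    )


def normalize_table(
    seg_metrics: pd.DataFrame,
    sex: str,
    age: float,
    clock_hours: np.ndarray,
    table: NormativeTable,
    metrics: Iterable[str] = ("sdnn", "sd1", "sd2"),
) -> pd.DataFrame:
    """Vectorized percentage scores for a per-segment metric table."""
    out = {}
    hours = np.asarray(clock_hours, dtype=int)
    for m in metrics:
        refs = table.lookup_vec(sex, age, hours, m)
        out[PCT_OF[m]] = 100.0 * seg_metrics[m].to_numpy() / refs
    return pd.DataFrame(out, index=seg_metrics.index)


def fisher_ci(r: float, n: int, alpha: float = 0.05) -> Tuple[float, float]:
    """Fisher-z confidence interval for a correlation coefficient."""
    r = float(np.clip(r, -1 + 1e-15, 1 - 1e-15))
    if n < 4:
        return (np.nan, np.nan)
    z = np.arctanh(r)
    se = 1.0 / np.sqrt(n - 3)
    zc = stats.norm.ppf(1 - alpha / 2)
    return (float(np.tanh(z - zc * se)), float(np.tanh(z + zc * se)))


def crossdomain_correlation(scores: pd.DataFrame) -> pd.DataFrame:
    """Pearson correlations between the nonlinear and spectral percentage
    scores pooled over segments: (sd1_pct, hf_pct) and (sd2_pct, lf_pct).

    Returns one row per pair with r, Fisher-z CI and n.
    """
    rows = []
    for a, b in (("sd1_pct", "hf_pct"), ("sd2_pct", "lf_pct")):
        sub = scores[[a, b]].dropna()
        if len(sub) < 3:
            raise ValueError(f"need >= 3 paired values for {a} vs {b}")
        if np.std(sub[a]) == 0 or np.std(sub[b]) == 0:
            raise ValueError(f"degenerate variance for {a} vs {b}")
        r, p = stats.pearsonr(sub[a], sub[b])
        lo, hi = fisher_ci(float(r), len(sub))
        rows.append({"pair": f"{a}~{b}", "r_pearson": float(r), "p": float(p),
                     "ci_low": lo, "ci_high": hi, "n": len(sub)})
    return pd.DataFrame(rows)
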