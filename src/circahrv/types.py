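"""Core domain containers shared by the pipeline stages.

Arrays are plain numpy; per-beat status flags use the integer codes
CLEAN / ARTIFACT / INTERPOLATED.  Timestamps are seconds since the start
of a subject's recording; the clock time of that start (seconds after
local midnight) travels with the subject metadata so normative lookups
can resolve the hour of day.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

CLEAN = 0
ARTIFACT = 1
INTERPOLATED = 2

#: metrics the downstream trend / discrimination stages operate on by
#: default (the remaining metrics are computable and exportable but are
#: dropped from group analysis as redundant or artifact-prone).
DEFAULT_METRICS = ("sdnn_pct", "sd1_pct", "sd2_pct")


@dataclass
class IbiSeries:
    """Timestamped inter-beat intervals of one subject.

    ``t`` holds the beat timestamps in seconds since recording start
    (cumulative sum of the intervals), ``ibi`` the intervals in ms and
    ``flags`` the per-beat status.
    """

    subject_id: str
    t: np.ndarray
    ibi: np.ndarray
    flags: np.ndarray

    def __post_init__(self):
        self.t = np.asarray(self.t, dtype=float)
        self.ibi = np.asarray(self.ibi, dtype=float)
        if self.flags is None:
            self.flags = np.zeros(self.ibi.shape[0], dtype=np.uint8)
        self.flags = np.asarray(self.flags, dtype=np.uint8)

    def validate(self) -> None:
        if self.t.shape != self.ibi.shape or self.flags.shape != self.ibi.shape:
            raise ValueError("t, ibi and flags must have equal length")
        if self.ibi.size and not np.all(np.isfinite(self.ibi)):
            raise ValueError("non-finite inter-beat intervals")
        if self.ibi.size and np.any(self.ibi <= 0):
            raise ValueError("inter-beat intervals must be positive")
        if self.t.size > 1 and np.any(np.diff(self.t) <= 0):
            raise ValueError("beat timestamps must be strictly increasing")

    @property
    def n_beats(self) -> int:
        return int(self.ibi.shape[0])

    @classmethod
    def from_ibis(cls, subject_id: str, ibi: Sequence[float], flags=None) -> "IbiSeries":
        ibi = np.asarray(ibi, dtype=float)
        return cls(subject_id, np.cumsum(ibi) / 1000.0, ibi, flags)


@dataclass
class ActivitySeries:
    """Movement magnitude samples, nominally 1 Hz, device units."""

    subject_id: str
    t: np.ndarray
    magnitude: np.ndarray

    def __post_init__(self):
        self.t = np.asarray(self.t, dtype=float)
        self.magnitude = np.asarray(self.magnitude)  # dtype preserved (1 Hz streams can stay float32)

    def validate(self) -> None:
        if self.t.shape != self.magnitude.shape:
            raise ValueError("t and magnitude must have equal length")
        if self.t.size > 1 and np.any(np.diff(self.t) < 0):
            raise ValueError("activity timestamps must be non-decreasing")
        if self.magnitude.size and np.any(self.magnitude < 0):
            raise ValueError("activity magnitude must be non-negative")


@dataclass
class SleepWakeLabels:
    """Per-day wake / sleep onset times, seconds since recording start.

    ``wake_onset`` has one more entry than ``sleep_onset`` so the last
    night is bounded by the final morning's wake onset.
    """

    subject_id: str
    wake_onset: np.ndarray
    sleep_onset: np.ndarray

    def __post_init__(self):
        self.wake_onset = np.asarray(self.wake_onset, dtype=float)
        self.sleep_onset = np.asarray(self.sleep_onset, dtype=float)

    def validate(self) -> None:
        if self.wake_onset.size != self.sleep_onset.size + 1:
            raise ValueError("need len(wake_onset) == len(sleep_onset) + 1")
        for d in range(self.sleep_onset.size):
            if not (self.wake_onset[d] < self.sleep_onset[d] < self.wake_onset[d + 1]):
                raise ValueError(f"day {d}: need wake < sleep < next wake")

    @property
    def n_days(self) -> int:
        return int(self.sleep_onset.size)


EXCLUSION_NONE = "none"
EXCLUSION_INTERPOLATION = "interpolation_run"
EXCLUSION_ACTIVITY = "activity"
EXCLUSION_TOO_FEW = "too_few_beats"

SEGMENT_SECONDS = 300.0


@dataclass
class Segment:
    """One non-overlapping 5-minute window of a subject's recording."""

    subject_id: str
    start: float
    ibi: np.ndarray
    flags: np.ndarray
    t: np.ndarray
    n_interpolated: int
    max_interpolated_run: int
    mean_activity: float
    valid: bool = True
    exclusion_reason: str = EXCLUSION_NONE
    duration: float = SEGMENT_SECONDS

    @property
    def n_beats(self) -> int:
        return int(self.ibi.shape[0])

    @property
    def midpoint(self) -> float:
        return self.start + self.duration / 2.0


@dataclass
class HrvVector:
    sdnn: float
    rmssd: float
    pnn20: float
    pnn50: float
    hf: float
    lf: float
    sd1: float
    sd2: float


@dataclass
class NormalizedHrv:
    sdnn_pct: float
    sd1_pct: float
    sd2_pct: float
    hf_pct: Optional[float] = None
    lf_pct: Optional[float] = None


class NormativeTable:
    """Reference HRV values keyed by sex x age band x hour of day x metric.

    Lookup floors the age to its containing band and uses the integer
    hour; no interpolation between cells (sources publish banded tables).
    """

    def __init__(self, frame: pd.DataFrame):
        required = {"sex", "age_min", "age_max", "hour", "metric", "reference"}
        missing = required - set(frame.columns)
        if missing:
            raise ValueError(f"normative table missing columns: {sorted(missing)}")
        if (frame["reference"] <= 0).any():
            raise ValueError("normative references must be positive")
        self.frame = frame.reset_index(drop=True)
        self._bands = {}
        self._grids = {}
        for (sex, metric), sub in frame.groupby(["sex", "metric"]):
            edges = np.sort(sub["age_min"].unique()).astype(float)
            self._bands[(sex, metric)] = edges
            grid = np.full((edges.size, 24), np.nan)
            band_idx = {a: i for i, a in enumerate(edges)}
            for _, row in sub.iterrows():
                grid[band_idx[float(row["age_min"])], int(row["hour"])] = row["reference"]
            self._grids[(sex, metric)] = grid
        self._age_max = {
            (sex, metric): sub["age_max"].max()
            for (sex, metric), sub in frame.groupby(["sex", "metric"])
        }

    def lookup(self, sex: str, age: float, hour: int, metric: str) -> float:
        vals = self.lookup_vec(sex, age, np.asarray([hour]), metric)
        return float(vals[0])

    def lookup_vec(self, sex: str, age: float, hours: np.ndarray, metric: str) -> np.ndarray:
        key = (sex, metric)
        if key not in self._bands:
            raise KeyError(f"no normative entries for sex={sex!r}, metric={metric!r}")
        edges = self._bands[key]
        if age < edges[0] or age > self._age_max[key]:
            raise KeyError(f"age {age} outside declared bands for sex={sex!r}")
        band = int(np.searchsorted(edges, age, side="right") - 1)
        hours = np.asarray(hours, dtype=int) % 24
        vals = self._grids[key][band, hours]
        if np.any(np.isnan(vals)):
            raise KeyError(f"missing normative cell for sex={sex!r}, metric={metric!r}")
        return vals

    def __eq__(self, other):
        return isinstance(other, NormativeTable) and self.frame.equals(other.frame)


@dataclass
class CircadianTrend:
    """Fitted circadian trend of one normalized metric.

    ``chebyshev`` holds the fitted numpy Chebyshev polynomial over the
    margin-extended standardized-day domain; ``window_medians`` the ten
    medians of the trend over the 0.1-wide bins (five wake, five sleep).
    """

    metric: str
    chebyshev: np.polynomial.Chebyshev
    window_medians: np.ndarray
    n_points: np.ndarray
    degree: int
    margin_fraction: float

    def __call__(self, position: np.ndarray) -> np.ndarray:
        return self.chebyshev(np.asarray(position, dtype=float))

    def grid(self, points_per_bin: int = 1000) -> np.ndarray:
        pos = np.linspace(0.0, 1.0, 10 * points_per_bin, endpoint=False)
        return self.chebyshev(pos)


@dataclass(frozen=True, order=True)
class WindowSpec:
    """Contiguous range of 20%-bins inside one phase of the standardized
    day ('day' = wake, 'night' = sleep); bins are inclusive 0..4."""

    phase: str
    start_bin: int
    end_bin: int

    def __post_init__(self):
        if self.phase not in ("day", "night"):
            raise ValueError("phase must be 'day' or 'night'")
        if not (0 <= self.start_bin <= self.end_bin <= 4):
            raise ValueError("need 0 <= start_bin <= end_bin <= 4")

    def label(self) -> str:
        return f"{self.start_bin * 20}%-{(self.end_bin + 1) * 20}% {self.phase}"

    def position_range(self) -> tuple:
        off = 0.0 if self.phase == "day" else 0.5
        return (off + 0.05 * self.start_bin * 2, off + 0.05 * (self.end_bin + 1) * 2)

    def grid_slice(self, points_per_bin: int = 1000) -> slice:
        off = 0 if self.phase == "day" else 5
        return slice((off + self.start_bin) * points_per_bin, (off + self.end_bin + 1) * points_per_bin)


@dataclass(frozen=True, order=True)
class DeltaSpec:
    """Subject value = median-of-trend(window_a) - median-of-trend(window_b)."""

    window_a: WindowSpec
    window_b: WindowSpec

    def __post_init__(self):
        if self.window_a == self.window_b:
            raise ValueError("delta windows must differ")

    def label(self) -> str:
        return f"{self.window_a.label()} and {self.window_b.label()}"


@dataclass
class ComparisonResult:
    """Statistical battery attached to one (grouping, selector, metric)."""

    grouping: str
    selector: object  # WindowSpec or DeltaSpec
    metric: str
    auc: float
    auc_ci: tuple
    p_mwu: float
    n_case: int
    n_comparison: int
    p_adjusted: Optional[float] = None
    smd: Optional[float] = None
    smd_ci: Optional[tuple] = None
    correlations: Optional[dict] = None
    confounders: Optional[list] = None

    def to_dict(self) -> dict:
        d = {
            "grouping": self.grouping,
            "selector": self.selector.label(),
            "metric": self.metric,
            "auc": self.auc,
            "auc_ci_low": self.auc_ci[0],
            "auc_ci_high": self.auc_ci[1],
            "p_mwu": self.p_mwu,
            "p_adjusted": self.p_adjusted,
            "smd": self.smd,
            "n_case": self.n_case,
            "n_comparison": self.n_comparison,
        }
        if self.smd_ci is not None:
            d["smd_ci_low"], d["smd_ci_high"] = self.smd_ci
        return d
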