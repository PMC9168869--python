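"""CSV / YAML interfaces.

All streams are plain CSV with declared schemas:

* IBI:        ``subject_id,timestamp_s,ibi_ms[,flag]``
* activity:   ``subject_id,timestamp_s,magnitude``
* labels:     ``subject_id,day_index,wake_onset_ts,sleep_onset_ts`` —
  one row per recorded day plus a final row carrying the last morning's
  wake onset (empty ``sleep_onset_ts``)
* metadata:   one row per subject, must include ``subject_id`` and
  ``group``; demographic and clinical grouping columns as available
* normative:  ``sex,age_min,age_max,hour,metric,reference``

Validation failures name the offending line.
"""
from __future__ import annotations

import hashlib
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Dict, List, Optional

import numpy as np
import pandas as pd
import yaml

from .types import ActivitySeries, CircadianTrend, IbiSeries, NormativeTable, SleepWakeLabels

logger = logging.getLogger(__name__)

FLAG_NAMES = {0: "clean", 1: "artifact", 2: "interpolated"}
FLAG_CODES = {v: k for k, v in FLAG_NAMES.items()}


def _require_columns(df: pd.DataFrame, cols, path) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")


def read_ibi_csv(path) -> Dict[str, IbiSeries]:
    df = pd.read_csv(path, float_precision="round_trip")
    _require_columns(df, ["subject_id", "timestamp_s", "ibi_ms"], path)
    out = {}
    for sid, sub in df.groupby("subject_id", sort=True):
        t = sub["timestamp_s"].to_numpy(dtype=float)
        bad = np.where(np.diff(t) <= 0)[0]
        if bad.size:
            line = sub.index[bad[0] + 1] + 2  # header + 0-based
            raise ValueError(f"{path}: non-increasing timestamp for {sid} at line {line}")
        flags = None
        if "flag" in sub.columns:
            flags = sub["flag"].map(FLAG_CODES).to_numpy(dtype=np.uint8)
        series = IbiSeries(str(sid), t, sub["ibi_ms"].to_numpy(dtype=float), flags)
        series.validate()
        out[str(sid)] = series
    return out


def write_ibi_csv(path, series_by_subject: Dict[str, IbiSeries]) -> None:
    frames = []
    for sid, s in series_by_subject.items():
        frames.append(pd.DataFrame({
            "subject_id": sid,
            "timestamp_s": s.t,
            "ibi_ms": s.ibi,
            "flag": pd.Series(s.flags).map(FLAG_NAMES),
        }))
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def read_activity_csv(path) -> Dict[str, ActivitySeries]:
    df = pd.read_csv(path, float_precision="round_trip")
    _require_columns(df, ["subject_id", "timestamp_s", "magnitude"], path)
    out = {}
    for sid, sub in df.groupby("subject_id", sort=True):
        a = ActivitySeries(str(sid), sub["timestamp_s"].to_numpy(float), sub["magnitude"].to_numpy(float))
        a.validate()
        out[str(sid)] = a
    return out


def write_activity_csv(path, series_by_subject: Dict[str, ActivitySeries]) -> None:
    frames = [
        pd.DataFrame({"subject_id": sid, "timestamp_s": a.t, "magnitude": a.magnitude})
        for sid, a in series_by_subject.items()
    ]
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def read_labels_csv(path) -> Dict[str, SleepWakeLabels]:
    df = pd.read_csv(path, float_precision="round_trip")
    _require_columns(df, ["subject_id", "day_index", "wake_onset_ts", "sleep_onset_ts"], path)
    out = {}
    for sid, sub in df.groupby("subject_id", sort=True):
        sub = sub.sort_values("day_index")
        wake = sub["wake_onset_ts"].to_numpy(dtype=float)
        sleep = sub["sleep_onset_ts"].to_numpy(dtype=float)
        if np.isnan(sleep[-1]):
            sleep = sleep[:-1]
        labels = SleepWakeLabels(str(sid), wake, sleep)
        labels.validate()
        out[str(sid)] = labels
    return out


def write_labels_csv(path, labels_by_subject: Dict[str, SleepWakeLabels]) -> None:
    rows = []
    for sid, lab in labels_by_subject.items():
        for d in range(lab.n_days):
            rows.append({"subject_id": sid, "day_index": d,
                         "wake_onset_ts": lab.wake_onset[d], "sleep_onset_ts": lab.sleep_onset[d]})
        rows.append({"subject_id": sid, "day_index": lab.n_days,
                     "wake_onset_ts": lab.wake_onset[lab.n_days], "sleep_onset_ts": np.nan})
    pd.DataFrame(rows).to_csv(path, index=False)


def read_metadata_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path, float_precision="round_trip")
    _require_columns(df, ["subject_id", "group"], path)
    return df.set_index("subject_id", drop=False)


def read_normative_csv(path) -> NormativeTable:
    return NormativeTable(pd.read_csv(path, float_precision="round_trip"))


def write_normative_csv(path, table: NormativeTable) -> None:
    table.frame.to_csv(path, index=False)


def check_subjects_known(streams: Dict[str, object], metadata: pd.DataFrame, what: str) -> None:
    unknown = sorted(set(streams) - set(metadata["subject_id"].astype(str)))
    if unknown:
        raise ValueError(f"{what} rows for subjects absent from metadata: {unknown}")


def write_trends_csv(path, trends: Dict[str, Dict[str, CircadianTrend]]) -> None:
    rows = []
    for sid, per_metric in trends.items():
        for metric, tr in per_metric.items():
            row = {"subject_id": sid, "metric": metric, "degree": tr.degree,
                   "margin_fraction": tr.margin_fraction}
            for i, c in enumerate(tr.chebyshev.coef):
                row[f"coef_{i}"] = c
            for b, m in enumerate(tr.window_medians):
                row[f"median_{b}"] = m
            rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False)


def read_trends_csv(path) -> Dict[str, Dict[str, CircadianTrend]]:
    df = pd.read_csv(path, float_precision="round_trip")
    out: Dict[str, Dict[str, CircadianTrend]] = {}
    for _, row in df.iterrows():
        margin = float(row["margin_fraction"])
        coefs = [row[c] for c in df.columns if c.startswith("coef_") and pd.notna(row[c])]
        cheb = np.polynomial.Chebyshev(np.asarray(coefs, float), domain=[-margin, 1 + margin])
        medians = np.asarray([row[f"median_{b}"] for b in range(10)], float)
        tr = CircadianTrend(metric=row["metric"], chebyshev=cheb, window_medians=medians,
                            n_points=np.zeros(10, int), degree=int(row["degree"]),
                            margin_fraction=margin)
        out.setdefault(str(row["subject_id"]), {})[row["metric"]] = tr
    return out


@dataclass
class PipelineConfig:
    """Paths, parameters and groupings for one reproducible run."""

    ibi_path: str = ""
    activity_path: str = ""
    labels_path: str = ""
    metadata_path: str = ""
    normative_path: str = ""
    output_dir: str = "results"
    window_beats: int = 41
    artifact_coef: float = 3.32
    artifact_floor_ms: float = 50.0
    min_beats: int = 100
    activity_quantile: float = 0.9
    activity_threshold: Optional[float] = None
    degree: int = 10
    margin_fraction: float = 0.15
    metrics: List[str] = field(default_factory=lambda: ["sdnn_pct", "sd1_pct", "sd2_pct"])
    groupings: List[dict] = field(default_factory=list)
    seed: int = 0

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=True)

    def check_inputs(self) -> None:
        for name in ("ibi_path", "activity_path", "labels_path", "metadata_path", "normative_path"):
            p = getattr(self, name)
            if p and not Path(p).exists():
                raise FileNotFoundError(f"{name}: {p} does not exist")

    def digest(self) -> str:
        return hashlib.sha256(yaml.safe_dump(asdict(self), sort_keys=True).encode()).hexdigest()[:16]


@dataclass
class RunManifest:
    """Per-run accounting: seeds, config hash and segment conservation."""

    config_hash: str
    package_version: str
    seed: int
    subject_counts: Dict[str, Dict[str, int]] = field(default_factory=dict)

    def check_conservation(self) -> None:
        for sid, c in self.subject_counts.items():
            excluded = sum(v for k, v in c.items() if k.startswith("excluded_"))
            if c.get("segments_total", 0) != c.get("valid", 0) + excluded:
                raise AssertionError(f"segment accounting violated for {sid}: {c}")

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=True)
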