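"""End-to-end orchestration: streams -> trends -> window discrimination.

Stage order: artifact check -> interpolation -> segmentation -> validity
filtering -> per-segment metrics -> normative percentage scores -> wake-
anchored time standardization -> polynomial trend per metric -> ten
window medians -> single / Δ window search with the statistics battery.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence

import numpy as np
import pandas as pd

from . import __version__, circadian, discriminate, hrv, io, preprocess
from .types import (
    ActivitySeries,
    CircadianTrend,
    IbiSeries,
    NormativeTable,
    SleepWakeLabels,
)

logger = logging.getLogger(__name__)

RAW_METRICS = ("sdnn", "sd1", "sd2")


@dataclass
class SubjectAnalysis:
    subject_id: str
    trends: Dict[str, CircadianTrend]
    segments: pd.DataFrame  # per-segment stats, scores, positions
    counts: Dict[str, int]


@dataclass
class CohortAnalysis:
    trends: Dict[str, Dict[str, CircadianTrend]]
    metadata: pd.DataFrame
    counts: Dict[str, Dict[str, int]]
    segments: Dict[str, pd.DataFrame] = field(default_factory=dict)


def analyze_subject(
    series: IbiSeries,
    activity: Optional[ActivitySeries],
    labels: SleepWakeLabels,
    sex: str,
    age: float,
    start_clock_s: float,
    table: NormativeTable,
    window_beats: int = preprocess.DEFAULT_WINDOW_BEATS,
    artifact_coef: float = preprocess.DEFAULT_COEF,
    artifact_floor_ms: float = preprocess.DEFAULT_FLOOR_MS,
    min_beats: int = preprocess.DEFAULT_MIN_BEATS,
    activity_quantile: float = 0.9,
    activity_threshold: Optional[float] = None,
    degree: int = circadian.DEFAULT_DEGREE,
    margin_fraction: float = circadian.DEFAULT_MARGIN,
    metrics: Sequence[str] = RAW_METRICS,
    keep_segments: bool = False,
) -> SubjectAnalysis:
    """Run the full per-subject chain and fit one trend per metric."""
    flagged = preprocess.detect_artifacts(series, window_beats, artifact_coef, artifact_floor_ms)
    corrected = preprocess.correct_artifacts(flagged)
    seg = preprocess.segment_table(corrected, activity)
    if seg.empty:
        raise ValueError(f"subject {series.subject_id}: recording shorter than one segment")
    mids = seg["start"].to_numpy() + preprocess.SEGMENT_SECONDS / 2.0
    pos = circadian.standardize_positions(mids, labels)
    if activity_threshold is None and activity is not None:
        wake_mask = np.isfinite(pos) & (pos < 0.5)
        activity_threshold = preprocess.wake_activity_threshold(seg, wake_mask, activity_quantile)
    seg = preprocess.apply_validity(seg, activity_threshold, min_beats)
    counts = {"segments_total": int(len(seg)), "valid": int(seg["valid"].sum())}
    for reason, cnt in seg.loc[~seg["valid"], "exclusion_reason"].value_counts().items():
        counts[f"excluded_{reason}"] = int(cnt)
    seg["position"] = pos
    seg["day"] = np.searchsorted(labels.wake_onset, mids, side="right") - 1
    use = seg["valid"].to_numpy() & np.isfinite(pos)
    counts["valid_unlabeled"] = int((seg["valid"] & ~np.isfinite(pos)).sum())
    sub = seg[use]
    td = hrv.batch_time_domain(corrected.ibi, sub["i0"].to_numpy(), sub["i1"].to_numpy())
    hours = (((start_clock_s + mids[use]) // 3600.0) % 24).astype(int)
    scores = hrv.normalize_table(td, sex, age, hours, table, metrics)
    scores.index = sub.index
    seg = seg.join(scores)
    trends = {}
    for m in metrics:
        col = hrv.PCT_OF[m]
        vals = seg.loc[use, col].to_numpy()
        p = seg.loc[use, "position"].to_numpy()
        ok = np.isfinite(vals)
        trends[col] = circadian.fit_trend(p[ok], vals[ok], degree, margin_fraction, col)
    return SubjectAnalysis(
        subject_id=series.subject_id,
        trends=trends,
        segments=seg if keep_segments else seg.loc[use, ["start", "day", "position"] + list(scores.columns)],
        counts=counts,
    )


def analyze_cohort(
    subjects,
    metadata: pd.DataFrame,
    table: NormativeTable,
    keep_segments: bool = False,
    **params,
) -> CohortAnalysis:
    """Per-subject analysis over a cohort.

    ``subjects`` is an iterable of objects with ``ibi``, ``activity`` and
    ``labels`` attributes (e.g. :class:`~circahrv.synthetic.SimulatedSubject`)
    or ``(ibi, activity, labels)`` tuples.  Subjects whose streams yield
    no usable segments are excluded with a log message.
    """
    trends, counts, segs = {}, {}, {}
    for sub in subjects:
        if hasattr(sub, "ibi"):
            series, activity, labels = sub.ibi, sub.activity, sub.labels
        else:
            series, activity, labels = sub
        sid = series.subject_id
        rec = metadata.loc[sid]
        try:
            ana = analyze_subject(
                series, activity, labels,
                sex=rec["sex"], age=float(rec["age"]),
                start_clock_s=float(rec.get("start_clock_s", 0.0)),
                table=table, keep_segments=keep_segments, **params,
            )
        except ValueError as e:
            logger.warning("subject %s excluded: %s", sid, e)
            continue
        trends[sid] = ana.trends
        counts[sid] = ana.counts
        segs[sid] = ana.segments
    return CohortAnalysis(trends=trends, metadata=metadata.loc[list(trends)], counts=counts,
                          segments=segs)


def run_search(
    cohort: CohortAnalysis,
    groupings: Optional[List[discriminate.GroupingConfig]] = None,
    metrics: Optional[Sequence[str]] = None,
    modes: Sequence[str] = ("single", "delta"),
    top_k: int = 1,
) -> pd.DataFrame:
    """Ranked window search for every grouping; returns the top-k rows
    per (grouping, mode) as a flat table."""
    if groupings is None:
        groupings = discriminate.default_groupings()
    if metrics is None:
        metrics = sorted(next(iter(cohort.trends.values())).keys())
    rows = []
    for g in groupings:
        try:
            labels = g.split(cohort.metadata)
        except KeyError:
            logger.info("grouping %s skipped: missing metadata field", g.name)
            continue
        labels = labels[labels.index.isin(cohort.trends)]
        if labels.sum() < 2 or (~labels).sum() < 2:
            logger.info("grouping %s skipped: fewer than 2 subjects per class", g.name)
            continue
        cov = cohort.metadata.loc[labels.index]
        cov = cov[[c for c in ("age", "sex", "medication") if c in cov.columns]].rename(
            columns={"sex": "gender"})
        for mode in modes:
            fn = discriminate.search_single if mode == "single" else discriminate.search_delta
            results = fn(cohort.trends, labels, metrics, grouping=g.name, covariates=cov, top_k=top_k)
            for res in results[:top_k]:
                row = res.to_dict()
                row["mode"] = mode
                row["n_flagged_confounders"] = (
                    sum(1 for f in res.confounders if f["flagged"]) if res.confounders else 0
                )
                rows.append(row)
    return pd.DataFrame(rows)


def run_pipeline(config: io.PipelineConfig):
    """File-driven end-to-end run; writes result tables and a manifest
    into ``config.output_dir`` and returns (results, manifest)."""
    config.check_inputs()
    ibi = io.read_ibi_csv(config.ibi_path)
    activity = io.read_activity_csv(config.activity_path) if config.activity_path else {}
    labels = io.read_labels_csv(config.labels_path)
    metadata = io.read_metadata_csv(config.metadata_path)
    table = io.read_normative_csv(config.normative_path)
    io.check_subjects_known(ibi, metadata, "IBI")
    io.check_subjects_known(labels, metadata, "label")
    subjects = [
        (ibi[sid], activity.get(sid), labels[sid]) for sid in sorted(ibi) if sid in labels
    ]
    raw = [m.replace("_pct", "") for m in config.metrics]
    cohort = analyze_cohort(
        subjects, metadata, table,
        window_beats=config.window_beats,
        artifact_coef=config.artifact_coef,
        artifact_floor_ms=config.artifact_floor_ms,
        min_beats=config.min_beats,
        activity_quantile=config.activity_quantile,
        activity_threshold=config.activity_threshold,
        degree=config.degree,
        margin_fraction=config.margin_fraction,
        metrics=raw,
    )
    groupings = (
        [discriminate.GroupingConfig(**g) for g in config.groupings]
        if config.groupings else None
    )
    results = run_search(cohort, groupings, metrics=config.metrics)
    manifest = io.RunManifest(
        config_hash=config.digest(),
        package_version=__version__,
        seed=config.seed,
        subject_counts=cohort.counts,
    )
    manifest.check_conservation()
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    io.write_trends_csv(out / "trends.csv", cohort.trends)
    results.to_csv(out / "results.tsv", sep="\t", index=False)
    manifest.to_yaml(out / "manifest.yaml")
    return results, manifest
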