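"""Synthetic wearable cohorts with known circadian HRV ground truth.

Beat-to-beat variability is modeled as a Gaussian AR(1) process whose
parameters (mean IBI, marginal SD, lag-1 autocorrelation) are functions
of the standardized day position and are held fixed within each 5-minute
block; the standardized AR(1) state is carried across blocks.  This gives
closed-form oracles for every downstream metric:

    SDNN = sigma,   RMSSD = sigma * sqrt(2 (1 - rho)),
    SD1  = sigma * sqrt(1 - rho),   SD2 = sigma * sqrt(1 + rho).

Detection artifacts are injected as beat splits (one interval becomes
two short ones) and beat merges (two intervals become one long one) at a
Poisson rate, with affected output-beat indices recorded as ground truth.
Movement magnitude is near-zero during sleep with bursts during wake,
and sleep/wake labels follow a per-subject schedule with day-to-day
Gaussian jitter.

Group effects are injected by multiplying the case group's target-metric
profile inside a circadian window with a raised-cosine taper; the
multiplier is calibrated so the between-group standardized mean
difference of that window's trend median hits the requested value (the
calibration runs the deterministic base curve through the actual trend-
fit operator, so polynomial smoothing is accounted for).
"""
from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from typing import Callable, Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import optimize

from ._fast import ar1_blocks
from .circadian import fit_trend, standardize_positions
from .types import (
    ActivitySeries,
    IbiSeries,
    NormativeTable,
    SleepWakeLabels,
    WindowSpec,
)

logger = logging.getLogger(__name__)

BLOCK_S = 300.0
DAY_S = 86400.0

#: metric name -> value from (sigma, rho) under the AR(1) closed forms
_METRIC_OF = {
    "sdnn": lambda s, r: s,
    "rmssd": lambda s, r: s * np.sqrt(2.0 * (1.0 - r)),
    "sd1": lambda s, r: s * np.sqrt(1.0 - r),
    "sd2": lambda s, r: s * np.sqrt(1.0 + r),
}


# ------------------------------------------------------------- profiles

def base_sigma(pos):
    """Marginal IBI SD (ms) over the standardized day: lower while awake,
    peaking mid-sleep."""
    pos = np.asarray(pos, dtype=float)
    return 45.0 + 15.0 * np.cos(2.0 * np.pi * (pos - 0.72))


def base_rho(pos):
    """Lag-1 IBI autocorrelation: respiratory-type short-term structure,
    stronger at night."""
    pos = np.asarray(pos, dtype=float)
    return 0.45 + 0.18 * np.cos(2.0 * np.pi * (pos - 0.72))


def base_mean_ibi(pos):
    """Mean IBI (ms): ~71 bpm mid-afternoon slowing to ~56 bpm during
    sleep, a typical adult resting profile."""
    pos = np.asarray(pos, dtype=float)
    return 960.0 + 120.0 * np.cos(2.0 * np.pi * (pos - 0.74))


def _agesex_factor(sex: str, age: float) -> float:
    """Shared multiplicative demographic modulation of HRV magnitude,
    used identically by subject truth and the normative table so the
    percentage scores cancel it."""
    f = 1.0 - 0.008 * (age - 35.0)
    if sex == "w":
        f *= 0.96
    return max(f, 0.3)


# ---------------------------------------------------------------- types

@dataclass
class SubjectTruth:
    """Generative ground truth of one subject."""

    subject_id: str
    sigma_profile: Callable = base_sigma
    rho_profile: Callable = base_rho
    mean_ibi_profile: Callable = base_mean_ibi
    wake_duration: float = 16.0          # hours
    sleep_duration: float = 8.0          # hours
    schedule_jitter_sd: float = 20.0     # minutes
    artifact_rate: float = 2.0           # expected artifacts per hour
    activity_burst_rate: float = 2.0     # bursts per waking hour
    wake_onset_clock_s: float = 7 * 3600.0

    def validate(self) -> None:
        pos = np.linspace(0, 1, 97, endpoint=False)
        sig = np.asarray(self.sigma_profile(pos), dtype=float)
        rho = np.asarray(self.rho_profile(pos), dtype=float)
        mu = np.asarray(self.mean_ibi_profile(pos), dtype=float)
        if not (np.all(np.isfinite(sig)) and np.all(np.isfinite(rho)) and np.all(np.isfinite(mu))):
            raise ValueError(f"subject {self.subject_id}: non-finite profile values")
        if np.any(sig <= 0):
            raise ValueError(f"subject {self.subject_id}: sigma profile must be positive")
        if np.any(np.abs(rho) >= 1):
            raise ValueError(f"subject {self.subject_id}: |rho| must be < 1")
        if np.any((mu < 300) | (mu > 1500)):
            raise ValueError(f"subject {self.subject_id}: mean IBI outside 300-1500 ms")
        if abs(self.wake_duration + self.sleep_duration - 24.0) > 0.5:
            raise ValueError(f"subject {self.subject_id}: wake + sleep must be ~24 h")


@dataclass
class SimulatedSubject:
    """One subject's simulated streams plus generative ground truth."""

    truth: SubjectTruth
    ibi: IbiSeries
    activity: ActivitySeries
    labels: SleepWakeLabels
    artifact_beat_indices: np.ndarray


@dataclass
class GroupEffect:
    """Injected between-group difference: the case group's target-metric
    window median is shifted to a standardized mean difference ``smd``."""

    window: WindowSpec
    metric: str  # 'sdnn_pct', 'sd1_pct' or 'sd2_pct'
    smd: float


@dataclass
class CohortConfig:
    n_per_group: int = 24
    group_effects: List[GroupEffect] = field(default_factory=list)
    days: int = 14
    seed: int = 0
    tau: float = 0.25                 # between-subject log-normal scale SD
    age_mean: Dict[str, float] = field(default_factory=lambda: {"control": 33.5, "patient": 36.8})
    age_sd: Dict[str, float] = field(default_factory=lambda: {"control": 10.6, "patient": 9.5})
    prop_women: Dict[str, float] = field(default_factory=lambda: {"control": 0.54, "patient": 0.64})
    artifact_rate: float = 2.0
    activity_burst_rate: float = 2.0
    schedule_jitter_sd: float = 20.0

    def validate(self) -> None:
        if self.n_per_group < 2:
            raise ValueError("n_per_group must be >= 2")
        if not (1 <= self.days <= 31):
            raise ValueError("days must be in 1..31")
        for eff in self.group_effects:
            if eff.metric not in ("sdnn_pct", "sd1_pct", "sd2_pct"):
                raise ValueError(f"unsupported effect metric {eff.metric!r}")


# ----------------------------------------------------------- simulation

def _schedule(truth: SubjectTruth, days: int, rng) -> SleepWakeLabels:
    jit = rng.normal(0.0, truth.schedule_jitter_sd * 60.0, size=(days + 1, 2))
    wake = DAY_S * np.arange(days + 1) + jit[:, 0]
    wake[0] = 0.0
    sleep = wake[:days] + truth.wake_duration * 3600.0 + jit[:days, 1]
    sleep = np.minimum(sleep, wake[1:] - 1800.0)  # keep >= 30 min of sleep
    return SleepWakeLabels(truth.subject_id, wake, sleep)


def _inject_artifacts(ibi: np.ndarray, rate_per_h: float, rng) -> Tuple[np.ndarray, np.ndarray]:
    """Insert beat splits / merges; returns (new_ibi, artifact output
    indices)."""
    n = ibi.size
    total_h = ibi.sum() / 3.6e6
    n_events = rng.poisson(rate_per_h * total_h)
    if n_events == 0 or n < 10:
        return ibi, np.zeros(0, dtype=np.int64)
    idx = np.sort(rng.integers(1, n - 2, size=n_events))
    keep = np.concatenate([[True], np.diff(idx) >= 3])
    idx = idx[keep]
    kind = rng.random(idx.size) < 0.5  # True = split, False = merge
    counts = np.ones(n, dtype=np.int64)
    counts[idx[kind]] = 2
    counts[idx[~kind] + 1] = 0
    out_start = np.cumsum(counts) - counts
    new = np.repeat(ibi, counts)
    split_idx = idx[kind]
    u = rng.uniform(0.35, 0.65, size=split_idx.size)
    new[out_start[split_idx]] = u * ibi[split_idx]
    new[out_start[split_idx] + 1] = (1.0 - u) * ibi[split_idx]
    merge_idx = idx[~kind]
    new[out_start[merge_idx]] = ibi[merge_idx] + ibi[merge_idx + 1]
    gt = np.sort(np.concatenate([
        out_start[split_idx], out_start[split_idx] + 1, out_start[merge_idx],
    ]))
    return new, gt


def _wake_mask(times: np.ndarray, labels: SleepWakeLabels) -> np.ndarray:
    day = np.clip(np.searchsorted(labels.wake_onset, times, side="right") - 1, 0, labels.n_days - 1)
    return (times >= labels.wake_onset[day]) & (times < labels.sleep_onset[day])


def _activity(truth: SubjectTruth, labels: SleepWakeLabels, t_end: float, rng) -> ActivitySeries:
    t = np.arange(0.0, t_end, 1.0)
    wake = _wake_mask(t, labels)
    z = rng.standard_normal(t.size, dtype=np.float32)
    mag = np.where(wake, np.abs(0.6 + 0.25 * z), np.abs(0.05 + 0.03 * z))
    wake_hours = labels.n_days * truth.wake_duration
    n_bursts = rng.poisson(truth.activity_burst_rate * wake_hours)
    wake_idx = np.where(wake)[0]
    if n_bursts and wake_idx.size:
        starts = rng.choice(wake_idx, size=n_bursts)
        durs = rng.uniform(120, 600, size=n_bursts).astype(int)
        amps = rng.gamma(2.0, 2.0, size=n_bursts)
        for s0, du, am in zip(starts, durs, amps):
            mag[s0 : s0 + du] += am
    return ActivitySeries(truth.subject_id, t, mag.astype(float))


def generate_ibi_series(truth: SubjectTruth, days: int, seed=0) -> SimulatedSubject:
    """Simulate one subject's IBI + activity streams and sleep/wake labels.

    Per 5-minute block the IBIs are a stationary Gaussian AR(1) with
    mean ``mean_ibi_profile(pos)``, marginal SD ``sigma_profile(pos)``
    and lag-1 autocorrelation ``rho_profile(pos)`` at the block's
    standardized day position; the standardized state carries across
    blocks.  Artifacts are injected per :func:`_inject_artifacts` with
    ground-truth positions recorded.
    """
    truth.validate()
    if days < 1:
        raise ValueError("days must be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    labels = _schedule(truth, days, rng)
    t_end = float(labels.wake_onset[days])
    n_blocks = int(math.ceil(t_end / BLOCK_S))
    mids = BLOCK_S * (np.arange(n_blocks) + 0.5)
    pos = standardize_positions(np.minimum(mids, t_end - 1.0), labels)
    pos = np.nan_to_num(pos, nan=0.0)
    mean_b = np.asarray(truth.mean_ibi_profile(pos), dtype=float)
    sigma_b = np.asarray(truth.sigma_profile(pos), dtype=float)
    rho_b = np.clip(np.asarray(truth.rho_profile(pos), dtype=float), -0.98, 0.98)
    expected = float(np.sum(BLOCK_S / (mean_b / 1000.0)))
    z0 = rng.standard_normal()
    for attempt in range(4):
        n_eps = int(expected * (1.06 + 0.1 * attempt)) + 500
        eps = rng.standard_normal(n_eps)
        ibi, t, _, ok = ar1_blocks(mean_b, sigma_b, rho_b, BLOCK_S, eps, z0, t_end)
        if ok:
            break
    else:  # pragma: no cover
        raise RuntimeError("AR(1) generation failed to cover the recording")
    ibi, gt = _inject_artifacts(ibi, truth.artifact_rate, rng)
    t = np.cumsum(ibi) / 1000.0
    series = IbiSeries(truth.subject_id, t, ibi, None)
    activity = _activity(truth, labels, t_end, rng)
    return SimulatedSubject(truth, series, activity, labels, gt)


# ---------------------------------------------------- effect calibration

def _raised_cosine(window: WindowSpec):
    lo, hi = window.position_range()

    def bump(pos):
        pos = np.asarray(pos, dtype=float)
        b = np.zeros_like(pos)
        inside = (pos >= lo) & (pos < hi)
        b[inside] = np.sin(np.pi * (pos[inside] - lo) / (hi - lo)) ** 2
        return b

    return bump


def _nominal_hours(pos: np.ndarray, truth: SubjectTruth) -> np.ndarray:
    """Clock hour corresponding to standardized positions under the
    nominal (jitter-free) schedule."""
    pos = np.asarray(pos, dtype=float)
    wake_s = truth.wake_duration * 3600.0
    sleep_s = truth.sleep_duration * 3600.0
    elapsed = np.where(pos < 0.5, pos / 0.5 * wake_s, wake_s + (pos - 0.5) / 0.5 * sleep_s)
    return ((truth.wake_onset_clock_s + elapsed) / 3600.0).astype(int) % 24


def _norm_reference_shape(metric: str, hours: np.ndarray) -> np.ndarray:
    base = {"sdnn": 50.0, "rmssd": 36.0, "sd1": 26.0, "sd2": 64.0, "hf": 600.0, "lf": 900.0}[metric]
    return base * (1.0 + 0.25 * np.cos(2.0 * np.pi * (hours - 4.0) / 24.0))


def _sample_positions(truth: SubjectTruth) -> np.ndarray:
    nw = int(truth.wake_duration * 12)
    ns = int(truth.sleep_duration * 12)
    wake = 0.5 * (np.arange(nw) + 0.5) / nw
    sleep = 0.5 + 0.5 * (np.arange(ns) + 0.5) / ns
    return np.concatenate([wake, sleep])


def _metric_curve(truth: SubjectTruth, metric: str, pos: np.ndarray) -> np.ndarray:
    raw = metric.replace("_pct", "")
    sig = np.asarray(truth.sigma_profile(pos), dtype=float)
    rho = np.asarray(truth.rho_profile(pos), dtype=float)
    vals = _METRIC_OF[raw](sig, rho)
    ref = _norm_reference_shape(raw, _nominal_hours(pos, truth))
    return 100.0 * vals / ref


def _window_median_of_curve(pos, curve, window: WindowSpec) -> float:
    trend = fit_trend(pos, curve, metric="cal")
    lo, hi = window.position_range()
    grid = np.linspace(0.0, 1.0, 10000, endpoint=False)
    sel = (grid >= lo) & (grid < hi)
    return float(np.median(trend(grid)[sel]))


def _ratio_for_smd(smd: float, tau: float) -> float:
    """Case/comparison ratio r of the window median that yields the
    target SMD when subject scales are log-normal(0, tau):
    smd = (r - 1) / (cv * sqrt((1 + r^2) / 2)), cv = sqrt(e^{tau^2}-1)."""
    cv = math.sqrt(math.exp(tau * tau) - 1.0)
    c = smd * cv
    a = 1.0 - c * c / 2.0
    if a <= 0:
        raise ValueError("requested SMD too large for the between-subject spread")
    disc = max(1.0 - a * a, 0.0)
    root = math.sqrt(disc)
    return (1.0 + root) / a if smd >= 0 else (1.0 - root) / a


def calibrate_kappa(truth: SubjectTruth, effect: GroupEffect, tau: float) -> float:
    """In-window multiplicative shift kappa for the case group so that
    the SMD of the target window median equals ``effect.smd``."""
    pos = _sample_positions(truth)
    curve = _metric_curve(truth, effect.metric, pos)
    bump = _raised_cosine(effect.window)(pos)
    m1 = _window_median_of_curve(pos, curve, effect.window)
    target = _ratio_for_smd(effect.smd, tau) * m1

    def objective(kappa):
        f = 1.0 + (kappa - 1.0) * bump
        return _window_median_of_curve(pos, curve * f, effect.window) - target

    return float(optimize.brentq(objective, 0.05, 20.0, xtol=1e-6))


def _apply_effect(truth: SubjectTruth, effect: GroupEffect, kappa: float) -> SubjectTruth:
    """Shift the truth's sigma/rho profiles so the target metric is
    multiplied by f(pos) = 1 + (kappa - 1) bump(pos) inside the window."""
    bump = _raised_cosine(effect.window)
    sig0, rho0 = truth.sigma_profile, truth.rho_profile

    def f(pos):
        return 1.0 + (kappa - 1.0) * bump(pos)

    if effect.metric == "sdnn_pct":
        new_sigma = lambda pos, s=sig0: np.asarray(s(pos), dtype=float) * f(pos)
        return replace(truth, sigma_profile=new_sigma)
    if effect.metric == "sd1_pct":
        # sd1 = sigma sqrt(1-rho): scale by f via rho
        new_rho = lambda pos, r=rho0: np.clip(
            1.0 - f(pos) ** 2 * (1.0 - np.asarray(r(pos), dtype=float)), -0.98, 0.98)
        return replace(truth, rho_profile=new_rho)
    # sd2_pct: sd2 = sigma sqrt(1+rho)
    new_rho = lambda pos, r=rho0: np.clip(
        f(pos) ** 2 * (1.0 + np.asarray(r(pos), dtype=float)) - 1.0, -0.98, 0.98)
    return replace(truth, rho_profile=new_rho)


# --------------------------------------------------------------- cohort

def _patient_fields(rng, n: int) -> dict:
    edss = np.clip(np.round(rng.normal(2.2, 1.4, n) * 2) / 2, 0.0, 8.0)
    return {
        "edss": edss,
        "armss": np.clip(1.8 * edss + rng.normal(0, 1.0, n), 0.1, 10.0),
        "compass31": np.clip(rng.normal(16.9, 8.6, n), 0.0, None),
        "fsmc_total": np.clip(rng.normal(53.0, 21.8, n), 20.0, 100.0),
        "inflammatory_activity": rng.random(n) < 17 / 55,
        "progressive": rng.random(n) < 14 / 55,
        "medication": rng.random(n) < 20 / 55,
    }


def plan_cohort(config: CohortConfig):
    """Deterministic cohort plan: per-subject truths (with calibrated
    effects applied to the case group), metadata and the effect ledger —
    without simulating any streams yet."""
    config.validate()
    root = np.random.SeedSequence(config.seed)
    base_truth = SubjectTruth(
        subject_id="base",
        schedule_jitter_sd=config.schedule_jitter_sd,
        artifact_rate=config.artifact_rate,
        activity_burst_rate=config.activity_burst_rate,
    )
    ledger_rows = []
    case_truth = base_truth
    for eff in config.group_effects:
        if not (0 <= eff.window.start_bin <= eff.window.end_bin <= 4):
            raise ValueError("effect window outside the ten-bin grid")
        kappa = calibrate_kappa(base_truth, eff, config.tau)
        case_truth = _apply_effect(case_truth, eff, kappa)
        ledger_rows.append({
            "window": eff.window.label(), "metric": eff.metric,
            "smd": eff.smd, "kappa": kappa,
        })
    meta_rows = []
    plan = []
    rng_demo = np.random.default_rng(root.spawn(1)[0])
    child_seeds = root.spawn(2 * config.n_per_group + 1)[1:]
    groups = ["control"] * config.n_per_group + ["patient"] * config.n_per_group
    pat = _patient_fields(rng_demo, config.n_per_group)
    p_i = 0
    for i, group in enumerate(groups):
        sid = f"{group[:3]}{i:03d}"
        age = float(np.clip(rng_demo.normal(config.age_mean[group], config.age_sd[group]), 18.0, 75.0))
        sex = "w" if rng_demo.random() < config.prop_women[group] else "m"
        scale = float(np.exp(rng_demo.normal(0.0, config.tau)))
        demo = scale * _agesex_factor(sex, age)
        tmpl = case_truth if group == "patient" else base_truth
        truth = replace(
            tmpl,
            subject_id=sid,
            sigma_profile=lambda pos, s=tmpl.sigma_profile, d=demo: d * np.asarray(s(pos), dtype=float),
            wake_onset_clock_s=float(np.clip(rng_demo.normal(7 * 3600.0, 1800.0), 5 * 3600.0, 10 * 3600.0)),
        )
        plan.append((truth, child_seeds[i]))
        row = {
            "subject_id": sid, "group": group, "age": age, "sex": sex,
            "start_clock_s": truth.wake_onset_clock_s, "days": config.days,
            "scale": scale,
            "edss": np.nan, "armss": np.nan, "compass31": np.nan, "fsmc_total": np.nan,
            "inflammatory_activity": pd.NA, "progressive": pd.NA, "medication": pd.NA,
        }
        if group == "patient":
            for k, arr in pat.items():
                row[k] = arr[p_i]
            p_i += 1
        meta_rows.append(row)
    metadata = pd.DataFrame(meta_rows).set_index("subject_id", drop=False)
    return plan, metadata, pd.DataFrame(ledger_rows)


def iter_cohort(config: CohortConfig):
    """Yield the cohort's :class:`SimulatedSubject` streams one at a
    time (memory-friendly for large cohorts)."""
    plan, _, _ = plan_cohort(config)
    for truth, seed in plan:
        yield generate_ibi_series(truth, config.days, np.random.default_rng(seed))


def generate_cohort(config: CohortConfig):
    """Simulate a two-group cohort.

    Returns ``(subjects, metadata, effect_ledger)``: a list of
    :class:`SimulatedSubject`, a metadata table with demographic and
    clinical grouping fields, and the ledger of injected effects with
    their calibrated multipliers.
    """
    plan, metadata, ledger = plan_cohort(config)
    subjects = [
        generate_ibi_series(truth, config.days, np.random.default_rng(seed))
        for truth, seed in plan
    ]
    return subjects, metadata, ledger


# ------------------------------------------------------ normative table

DEFAULT_AGE_BANDS = ((18, 29), (30, 39), (40, 49), (50, 59), (60, 80))
TABLE_METRICS = ("sdnn", "rmssd", "sd1", "sd2", "hf", "lf")


def generate_normative_table(
    seed: int = 0,
    bands: Sequence[Tuple[int, int]] = DEFAULT_AGE_BANDS,
    metrics: Sequence[str] = TABLE_METRICS,
) -> NormativeTable:
    """Synthetic normative reference table (sex x age band x hour x
    metric), smooth in hour, with small seeded cell-group perturbations
    standing in for an external population reference."""
    if bands[0][0] > 18 or bands[-1][1] < 80:
        raise ValueError("bands must cover ages 18-80")
    rng = np.random.default_rng(seed)
    hours = np.arange(24)
    rows = []
    for sex in ("m", "w"):
        for lo, hi in bands:
            mid = 0.5 * (lo + hi)
            for metric in metrics:
                noise = float(np.exp(rng.normal(0.0, 0.05)))
                refs = _norm_reference_shape(metric, hours) * _agesex_factor(sex, mid) * noise
                for h, v in zip(hours, refs):
                    rows.append({
                        "sex": sex, "age_min": lo, "age_max": hi,
                        "hour": int(h), "metric": metric, "reference": float(v),
                    })
    return NormativeTable(pd.DataFrame(rows))
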