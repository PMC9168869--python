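"""Circadian-window group discrimination and the statistics battery.

Subjects are summarized per candidate selector — a single contiguous
window of the standardized day (median of the fitted trend over the
window) or an adaptive difference Δ between two windows — and selectors
are ranked by how far their Mann-Whitney AUC is from chance.  The best
selectors get the full battery: DeLong AUC confidence interval,
Mann-Whitney-U p, standardized mean difference with CI,
Benjamini-Hochberg adjustment over the search family, and a confounder
screen for age, gender and concomitant medication.
"""
from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator
from statsmodels.stats.multitest import multipletests

from .hrv import fisher_ci
from .types import DEFAULT_METRICS, CircadianTrend, ComparisonResult, DeltaSpec, WindowSpec

logger = logging.getLogger(__name__)

POINTS_PER_BIN = 1000
ALPHA = 0.05


# ---------------------------------------------------------------- windows

def enumerate_windows() -> List[WindowSpec]:
    """All 30 contiguous within-phase windows over the ten 20% bins,
    in deterministic (phase, start, end) order."""
    return [
        WindowSpec(phase, s, e)
        for phase in ("day", "night")
        for s in range(5)
        for e in range(s, 5)
    ]


def enumerate_window_pairs() -> List[DeltaSpec]:
    """All 435 unordered pairs of distinct windows."""
    wins = enumerate_windows()
    return [DeltaSpec(a, b) for a, b in itertools.combinations(wins, 2)]


def window_value(grid: np.ndarray, window: WindowSpec, points_per_bin: int = POINTS_PER_BIN) -> float:
    """Median of a dense trend grid over the window's span."""
    return float(np.median(grid[window.grid_slice(points_per_bin)]))


# ---------------------------------------------------------------- DeLong

def auc_delong(values: np.ndarray, labels: np.ndarray, alpha: float = ALPHA) -> Tuple[float, float, float]:
    """Mann-Whitney AUC with DeLong CI.

    AUC orients the positive class (labels truthy): ties count 1/2.  The
    variance uses DeLong's structural components (per-case and
    per-comparison placement values, n-1 sample variances).  The 95% CI
    is formed on the log-odds scale (delta method) and mapped back,
    which keeps small-sample coverage close to nominal and the bounds
    inside (0, 1); degenerate AUCs of exactly 0 or 1 fall back to the
    clipped normal interval.
    """
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels, dtype=bool)
    x = values[labels]   # cases
    y = values[~labels]  # comparison
    m, n = x.size, y.size
    if m == 0 or n == 0:
        raise ValueError("both classes must be non-empty")
    psi = (x[:, None] > y[None, :]).astype(float) + 0.5 * (x[:, None] == y[None, :])
    auc = float(psi.mean())
    v10 = psi.mean(axis=1)  # per-case placements
    v01 = psi.mean(axis=0)  # per-comparison placements
    var = 0.0
    if m > 1:
        var += np.var(v10, ddof=1) / m
    if n > 1:
        var += np.var(v01, ddof=1) / n
    se = math.sqrt(var)
    zc = stats.norm.ppf(1 - alpha / 2)
    if se == 0.0 or auc <= 0.0 or auc >= 1.0:
        return auc, max(0.0, auc - zc * se), min(1.0, auc + zc * se)
    logit = math.log(auc / (1.0 - auc))
    se_logit = se / (auc * (1.0 - auc))
    lo = 1.0 / (1.0 + math.exp(-(logit - zc * se_logit)))
    hi = 1.0 / (1.0 + math.exp(-(logit + zc * se_logit)))
    return auc, lo, hi


# ------------------------------------------------------------ basic stats

def compare_groups(values: np.ndarray, labels: np.ndarray) -> Tuple[float, float, Tuple[float, float]]:
    """(p_mwu, smd, smd_ci) for case (labels truthy) vs comparison.

    Mann-Whitney-U is two-sided; exact when both groups have n <= 8 and
    the data is tie-free, otherwise the normal approximation with tie and
    continuity correction.  SMD = (mean_case - mean_comparison) / pooled
    n-1 SD, with the usual asymptotic-variance CI.
    """
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels, dtype=bool)
    x, y = values[labels], values[~labels]
    if x.size < 2 or y.size < 2:
        raise ValueError("need >= 2 observations per group")
    if np.ptp(values) == 0:  # all observations identical: no evidence
        return 1.0, 0.0, (0.0, 0.0)
    has_ties = np.unique(values).size < values.size
    if x.size <= 8 and y.size <= 8 and not has_ties:
        p = float(stats.mannwhitneyu(x, y, alternative="two-sided", method="exact").pvalue)
    else:
        p = float(stats.mannwhitneyu(x, y, alternative="two-sided", method="asymptotic").pvalue)
    m, n = x.size, y.size
    sp2 = ((m - 1) * np.var(x, ddof=1) + (n - 1) * np.var(y, ddof=1)) / (m + n - 2)
    if sp2 == 0:
        if np.mean(x) == np.mean(y):
            return p, 0.0, (0.0, 0.0)
        raise ValueError("zero pooled SD with unequal means: SMD undefined")
    d = float((np.mean(x) - np.mean(y)) / math.sqrt(sp2))
    se = math.sqrt((m + n) / (m * n) + d * d / (2.0 * (m + n)))
    zc = stats.norm.ppf(1 - ALPHA / 2)
    return p, d, (d - zc * se, d + zc * se)


def correlate(values: np.ndarray, scores: np.ndarray) -> Dict[str, float]:
    """Pearson and Spearman correlations with Fisher-z CIs and p-values.

    Binary covariates coded 0/1 are accepted as-is (the Pearson r is then
    the point-biserial correlation).
    """
    values = np.asarray(values, dtype=float)
    scores = np.asarray(scores, dtype=float)
    ok = np.isfinite(values) & np.isfinite(scores)
    values, scores = values[ok], scores[ok]
    n = values.size
    if n < 4:
        raise ValueError("need >= 4 pairs")
    if np.std(values) == 0 or np.std(scores) == 0:
        raise ValueError("degenerate variance")
    rp, pp = stats.pearsonr(values, scores)
    rs, ps = stats.spearmanr(values, scores)
    lo_p, hi_p = fisher_ci(float(rp), n)
    lo_s, hi_s = fisher_ci(float(rs), n)
    return {
        "r_pearson": float(rp), "p_pearson": float(pp),
        "pearson_ci_low": lo_p, "pearson_ci_high": hi_p,
        "r_spearman": float(rs), "p_spearman": float(ps),
        "spearman_ci_low": lo_s, "spearman_ci_high": hi_s,
        "n": n,
    }


def adjust_bh(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (capped at 1)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


# ---------------------------------------------------------------- search

class WindowAucSearch(BaseEstimator):
    """Ranked AUC search over circadian windows for one metric.

    The estimator is fitted on ``X`` of shape ``(n_subjects, n_grid)``
    holding each subject's fitted trend evaluated on the dense
    standardized-day grid (``n_grid = 10 * points_per_bin``), and binary
    ``y`` (1 = case).  ``mode='single'`` searches the 30 contiguous
    windows, ``mode='delta'`` the 435 window pairs (subject value =
    median over window_a minus median over window_b).

    Ranking is by ``|auc - 0.5|`` descending (orientation-free); ties
    break in deterministic selector order.  Reported AUCs stay oriented
    to the positive class.

    Attributes
    ----------
    results_ : DataFrame of selector, auc, |auc-0.5|, rank.
    selectors_ : selector objects in ranked order.
    best_ : top-ranked selector.
    """

    def __init__(self, mode: str = "single", points_per_bin: int = POINTS_PER_BIN):
        self.mode = mode
        self.points_per_bin = points_per_bin

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y).astype(bool)
        if X.ndim != 2 or X.shape[0] != y.size:
            raise ValueError("X must be (n_subjects, n_grid) aligned with y")
        if y.all() or not y.any():
            raise ValueError("need both classes")
        if self.mode not in ("single", "delta"):
            raise ValueError("mode must be 'single' or 'delta'")
        windows = enumerate_windows()
        med = np.column_stack([
            np.median(X[:, w.grid_slice(self.points_per_bin)], axis=1) for w in windows
        ])
        if self.mode == "single":
            selectors: List[object] = list(windows)
            vals = med
        else:
            pairs = list(itertools.combinations(range(len(windows)), 2))
            selectors = [DeltaSpec(windows[i], windows[j]) for i, j in pairs]
            vals = np.column_stack([med[:, i] - med[:, j] for i, j in pairs])
        aucs = np.empty(len(selectors))
        cis = np.empty((len(selectors), 2))
        for k in range(len(selectors)):
            aucs[k], cis[k, 0], cis[k, 1] = auc_delong(vals[:, k], y)
        # the AUC is a rational with denominator m*n: round the ranking
        # key so float summation dust cannot perturb deterministic ties
        dist = np.round(np.abs(aucs - 0.5), 12)
        order = np.lexsort((np.arange(len(selectors)), -dist))
        self.selectors_ = [selectors[k] for k in order]
        self.values_ = vals[:, order]
        self.results_ = pd.DataFrame({
            "selector": [s.label() for s in self.selectors_],
            "auc": aucs[order],
            "auc_ci_low": cis[order, 0],
            "auc_ci_high": cis[order, 1],
            "abs_dist": dist[order],
            "rank": np.arange(1, len(selectors) + 1),
        })
        self.best_ = self.selectors_[0]
        self.n_features_in_ = X.shape[1]
        return self

    def transform(self, X):
        """Subject values under the ranked selectors (same order as
        ``selectors_``)."""
        from sklearn.utils.validation import check_is_fitted

        check_is_fitted(self, "selectors_")
        X = np.asarray(X, dtype=float)
        windows = enumerate_windows()
        med = {w: np.median(X[:, w.grid_slice(self.points_per_bin)], axis=1) for w in windows}
        cols = []
        for s in self.selectors_:
            if isinstance(s, WindowSpec):
                cols.append(med[s])
            else:
                cols.append(med[s.window_a] - med[s.window_b])
        return np.column_stack(cols)


def _trend_grids(trends: Dict[str, Dict[str, CircadianTrend]], metric: str,
                 subject_ids: Sequence[str], points_per_bin: int = POINTS_PER_BIN) -> np.ndarray:
    return np.vstack([trends[sid][metric].grid(points_per_bin) for sid in subject_ids])


def _search(
    trends: Dict[str, Dict[str, CircadianTrend]],
    labels: pd.Series,
    metrics: Sequence[str],
    mode: str,
    grouping: str,
    covariates: Optional[pd.DataFrame],
    top_k: int,
) -> List[ComparisonResult]:
    subject_ids = list(labels.index)
    y = labels.to_numpy().astype(bool)
    rows = []
    for metric in metrics:
        grids = _trend_grids(trends, metric, subject_ids)
        search = WindowAucSearch(mode=mode).fit(grids, y)
        for k in range(len(search.selectors_)):
            rows.append({
                "metric": metric,
                "selector": search.selectors_[k],
                "auc": search.results_["auc"].iloc[k],
                "ci": (search.results_["auc_ci_low"].iloc[k], search.results_["auc_ci_high"].iloc[k]),
                "values": search.values_[:, k],
            })
    rows.sort(key=lambda r: (-round(abs(r["auc"] - 0.5), 12), metrics.index(r["metric"]), r["selector"]))
    results = []
    pvals = []
    for r in rows:
        try:
            p, d, dci = compare_groups(r["values"], y)
        except ValueError:  # degenerate selector (e.g. zero pooled SD)
            p, d, dci = 1.0, None, None
        pvals.append(p)
        results.append(ComparisonResult(
            grouping=grouping, selector=r["selector"], metric=r["metric"],
            auc=r["auc"], auc_ci=r["ci"], p_mwu=p,
            n_case=int(y.sum()), n_comparison=int((~y).sum()),
            smd=d, smd_ci=dci,
        ))
    adj = adjust_bh(pvals)
    for res, pa in zip(results, adj):
        res.p_adjusted = float(pa)
    if covariates is not None and results:
        for i, res in enumerate(results[:top_k]):
            res.confounders = confounder_screen(
                rows[i]["values"],
                age=covariates.get("age"),
                gender=covariates.get("gender"),
                medication=covariates.get("medication"),
            )
    return results


def search_single(
    trends: Dict[str, Dict[str, CircadianTrend]],
    labels: pd.Series,
    metrics: Sequence[str] = DEFAULT_METRICS,
    grouping: str = "",
    covariates: Optional[pd.DataFrame] = None,
    top_k: int = 1,
) -> List[ComparisonResult]:
    """Ranked single-window discrimination across metrics.

    ``trends`` maps subject id -> metric -> fitted CircadianTrend;
    ``labels`` is a boolean Series indexed by subject id (True = case).
    """
    return _search(trends, labels, list(metrics), "single", grouping, covariates, top_k)


def search_delta(
    trends: Dict[str, Dict[str, CircadianTrend]],
    labels: pd.Series,
    metrics: Sequence[str] = DEFAULT_METRICS,
    grouping: str = "",
    covariates: Optional[pd.DataFrame] = None,
    top_k: int = 1,
) -> List[ComparisonResult]:
    """Ranked adaptive-difference (Δ between two windows) discrimination."""
    return _search(trends, labels, list(metrics), "delta", grouping, covariates, top_k)


# ------------------------------------------------------------ confounders

def confounder_screen(
    values: np.ndarray,
    age: Optional[pd.Series] = None,
    gender: Optional[pd.Series] = None,
    medication: Optional[pd.Series] = None,
    alpha: float = ALPHA,
) -> List[dict]:
    """Flag covariates associated with the selected HRV values.

    Age is screened by Pearson/Spearman correlation; gender and
    medication (0/1) by the Mann-Whitney + SMD group comparison.
    Single-level binary covariates are skipped (logged).
    """
    findings = []
    values = np.asarray(values, dtype=float)
    if age is not None:
        a = np.asarray(age, dtype=float)
        try:
            c = correlate(values, a)
            flagged = min(c["p_pearson"], c["p_spearman"]) < alpha
            findings.append({"covariate": "age", "flagged": bool(flagged), **c})
        except ValueError as e:
            logger.info("age screen skipped: %s", e)
    for name, cov in (("gender", gender), ("medication", medication)):
        if cov is None:
            continue
        g = np.asarray(cov)
        levels = pd.unique(g[pd.notna(g)])
        if levels.size < 2:
            logger.info("%s screen skipped: single level", name)
            continue
        mask = g == levels[0]
        try:
            p, d, dci = compare_groups(values, mask)
            findings.append({
                "covariate": name, "flagged": bool(p < alpha),
                "p_mwu": p, "smd": d, "smd_ci_low": dci[0], "smd_ci_high": dci[1],
            })
        except ValueError as e:
            logger.info("%s screen skipped: %s", name, e)
    return findings


# --------------------------------------------------------------- cohorts

@dataclass
class GroupingConfig:
    """How to split the cohort into case vs comparison subjects.

    ``field`` is a metadata column; ``op`` one of >=, >, <=, <, ==;
    ``comparison`` selects the comparison population: 'controls',
    'other_patients' or 'all_others'.
    """

    name: str
    field: str
    op: str = "=="
    threshold: object = True
    comparison: str = "controls"
    restrict_to_patients: bool = True

    _OPS = {
        ">=": np.greater_equal, ">": np.greater,
        "<=": np.less_equal, "<": np.less, "==": np.equal,
    }

    def split(self, metadata: pd.DataFrame) -> pd.Series:
        """Boolean case labels indexed by subject id; excluded subjects
        (neither case nor comparison) are absent from the result."""
        is_patient = metadata["group"].to_numpy() == "patient"
        vals = metadata[self.field]
        with np.errstate(invalid="ignore"):
            case = self._OPS[self.op](vals.to_numpy(), self.threshold)
        case = np.asarray(case, dtype=bool) & pd.notna(vals).to_numpy()
        if self.restrict_to_patients:
            case &= is_patient
        if self.comparison == "controls":
            comp = ~is_patient
        elif self.comparison == "other_patients":
            comp = is_patient & ~case & pd.notna(vals).to_numpy()
        else:
            comp = ~case
        keep = case | comp
        return pd.Series(case[keep], index=metadata.index[keep], name=self.name)


def default_groupings() -> List[GroupingConfig]:
    """The clinical grouping battery: disease status, inflammatory and
    radiological/clinical activity, progression, disability (EDSS >= 3),
    severity (ARMSS > 4) and symptom questionnaires (COMPASS-31 >= 17,
    FSMC total >= 65)."""
    return [
        GroupingConfig("pwMS", "group", "==", "patient", "controls", restrict_to_patients=False),
        GroupingConfig("inflammation", "inflammatory_activity", "==", True, "other_patients"),
        GroupingConfig("progression", "progressive", "==", True, "other_patients"),
        GroupingConfig("EDSS", "edss", ">=", 3.0, "other_patients"),
        GroupingConfig("ARMSS", "armss", ">", 4.0, "other_patients"),
        GroupingConfig("COMPASS-31", "compass31", ">=", 17.0, "controls"),
        GroupingConfig("COMPASS-31 pwMS", "compass31", ">=", 17.0, "other_patients"),
        GroupingConfig("FSMC", "fsmc_total", ">=", 65.0, "other_patients"),
    ]


def describe_cohort(metadata: pd.DataFrame, group_col: str = "group",
                    categorical: Optional[Sequence[str]] = None,
                    continuous: Optional[Sequence[str]] = None) -> pd.DataFrame:
    """Descriptive comparison of the two cohort groups.

    Categorical fields get a chi-square test on the contingency table
    (Yates continuity correction for 2x2, Pearson otherwise; zero-margin
    rows dropped); continuous fields a two-sided Mann-Whitney-U.  Emits
    counts or mean (SD) per group plus the p-value.
    """
    groups = pd.unique(metadata[group_col].dropna())
    if groups.size != 2:
        raise ValueError("describe_cohort expects exactly two groups")
    g0 = metadata[metadata[group_col] == groups[0]]
    g1 = metadata[metadata[group_col] == groups[1]]
    if categorical is None and continuous is None:
        categorical, continuous = [], []
        for c in metadata.columns:
            if c == group_col:
                continue
            if pd.api.types.is_numeric_dtype(metadata[c]) and metadata[c].nunique() > 5:
                continuous.append(c)
            else:
                categorical.append(c)
    rows = []
    for c in categorical or []:
        tab = pd.crosstab(metadata[c], metadata[group_col])
        tab = tab.loc[tab.sum(axis=1) > 0, tab.sum(axis=0) > 0]
        if tab.shape[0] < 2 or tab.shape[1] < 2:
            p = np.nan
        else:
            p = chi_square(tab.to_numpy())
        rows.append({
            "field": c, "type": "categorical",
            str(groups[0]): "; ".join(f"{i}:{v}" for i, v in tab.get(groups[0], pd.Series()).items()),
            str(groups[1]): "; ".join(f"{i}:{v}" for i, v in tab.get(groups[1], pd.Series()).items()),
            "p": p,
        })
    for c in continuous or []:
        x = g0[c].dropna().to_numpy(dtype=float)
        y = g1[c].dropna().to_numpy(dtype=float)
        if x.size < 2 or y.size < 2:
            p = np.nan
        else:
            p = float(stats.mannwhitneyu(x, y, alternative="two-sided").pvalue)
        rows.append({
            "field": c, "type": "continuous",
            str(groups[0]): f"{np.mean(x):.2f} ({np.std(x, ddof=1):.2f})" if x.size > 1 else "",
            str(groups[1]): f"{np.mean(y):.2f} ({np.std(y, ddof=1):.2f})" if y.size > 1 else "",
            "p": p,
        })
    return pd.DataFrame(rows)


def chi_square(table: np.ndarray) -> float:
    """Chi-square p-value on a contingency table: Yates continuity
    correction for 2x2, uncorrected Pearson for larger tables."""
    table = np.asarray(table)
    correction = table.shape == (2, 2)
    return float(stats.chi2_contingency(table, correction=correction)[1])


def auc_heatmap_matrix(results: List[ComparisonResult], metric: str) -> pd.DataFrame:
    """Bins x bins AUC grid for Δ selectors of one metric (export helper:
    row = window_a start/end code, column = window_b)."""
    labels = sorted({r.selector.window_a.label() for r in results if isinstance(r.selector, DeltaSpec)}
                    | {r.selector.window_b.label() for r in results if isinstance(r.selector, DeltaSpec)})
    mat = pd.DataFrame(np.nan, index=labels, columns=labels)
    for r in results:
        if isinstance(r.selector, DeltaSpec) and r.metric == metric:
            mat.loc[r.selector.window_a.label(), r.selector.window_b.label()] = r.auc
    return mat
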