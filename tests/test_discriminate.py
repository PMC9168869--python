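"""Window enumeration, DeLong AUC, searches and the statistics battery."""
import itertools
import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from circahrv import discriminate
from circahrv.circadian import fit_trend
from circahrv.discriminate import (
    GroupingConfig,
    WindowAucSearch,
    adjust_bh,
    auc_delong,
    chi_square,
    compare_groups,
    confounder_screen,
    correlate,
    describe_cohort,
    enumerate_window_pairs,
    enumerate_windows,
    search_delta,
    search_single,
)
from circahrv.types import DeltaSpec, WindowSpec


def pair_counting_auc(values, labels):
    """Exhaustive pair enumeration oracle."""
    x = values[labels]
    y = values[~labels]
    wins = sum(1.0 if a > b else 0.5 if a == b else 0.0 for a in x for b in y)
    return wins / (len(x) * len(y))


class TestWindows:
    def test_thirty_windows_in_deterministic_order(self):
        wins = enumerate_windows()
        assert len(wins) == 30
        assert wins == sorted(wins)
        assert WindowSpec("night", 0, 4) in wins  # full-phase night range

    def test_no_window_crosses_the_phase_boundary(self):
        for w in enumerate_windows():
            lo, hi = w.position_range()
            assert (hi <= 0.5) or (lo >= 0.5)

    def test_435_delta_pairs(self):
        assert len(enumerate_window_pairs()) == math.comb(30, 2) == 435

    def test_window_labels(self):
        assert WindowSpec("night", 2, 3).label() == "40%-80% night"
        assert WindowSpec("day", 0, 4).label() == "0%-100% day"


class TestDelong:
    def test_perfect_separation(self):
        auc, lo, hi = auc_delong(np.r_[np.zeros(5), np.ones(5)], np.r_[np.zeros(5), np.ones(5)])
        assert auc == 1.0 and hi == 1.0

    def test_chance_level_for_independent_labels(self):
        rng = np.random.default_rng(0)
        auc, lo, hi = auc_delong(rng.normal(size=2000), rng.random(2000) < 0.5)
        assert auc == pytest.approx(0.5, abs=0.04)
        assert lo < 0.5 < hi

    @settings(deadline=None, max_examples=60, derandomize=True)
    @given(st.integers(0, 10_000))
    def test_equals_pair_counting_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = rng.integers(4, 13)
        values = rng.integers(0, 6, n).astype(float)  # ties likely
        labels = np.zeros(n, bool)
        labels[rng.choice(n, rng.integers(1, n), replace=False)] = True
        if labels.all() or not labels.any():
            labels[0] = ~labels[0]
        auc, _, _ = auc_delong(values, labels)
        assert auc == pytest.approx(pair_counting_auc(values, labels), abs=1e-12)

    def test_label_flip_antisymmetry(self):
        rng = np.random.default_rng(4)
        values = rng.normal(size=30)
        labels = rng.random(30) < 0.4
        a1, _, _ = auc_delong(values, labels)
        a2, _, _ = auc_delong(values, ~labels)
        assert a1 + a2 == pytest.approx(1.0)

    def test_one_class_rejected(self):
        with pytest.raises(ValueError):
            auc_delong(np.arange(5.0), np.ones(5, bool))


class TestCompareGroups:
    def test_identical_samples_zero_smd(self):
        v = np.r_[np.arange(5.0), np.arange(5.0)]
        labels = np.r_[np.ones(5, bool), np.zeros(5, bool)]
        p, smd, ci = compare_groups(v, labels)
        assert smd == 0.0

    def test_exact_p_equals_permutation_enumeration(self):
        rng = np.random.default_rng(8)
        x = rng.normal(0, 1, 4)
        y = rng.normal(1, 1, 4)
        values = np.r_[x, y]
        labels = np.r_[np.ones(4, bool), np.zeros(4, bool)]
        p, _, _ = compare_groups(values, labels)
        # enumerate all label assignments; two-sided p on the U statistic
        def u_stat(xs, ys):
            return sum(1.0 if a > b else 0.5 if a == b else 0.0 for a in xs for b in ys)
        u_obs = u_stat(x, y)
        mean_u = 4 * 4 / 2
        count = 0
        total = 0
        for combo in itertools.combinations(range(8), 4):
            xs = values[list(combo)]
            ys = np.delete(values, list(combo))
            total += 1
            if abs(u_stat(xs, ys) - mean_u) >= abs(u_obs - mean_u) - 1e-12:
                count += 1
        assert p == pytest.approx(count / total, abs=1e-12)

    def test_large_sample_smd_recovers_one(self):
        rng = np.random.default_rng(1)
        values = np.r_[rng.normal(1, 1, 10_000), rng.normal(0, 1, 10_000)]
        labels = np.r_[np.ones(10_000, bool), np.zeros(10_000, bool)]
        _, smd, ci = compare_groups(values, labels)
        assert smd == pytest.approx(1.0, abs=0.05)
        assert ci[0] < smd < ci[1]

    def test_label_flip_negates_smd(self):
        rng = np.random.default_rng(2)
        values = rng.normal(size=40)
        labels = rng.random(40) < 0.5
        _, s1, _ = compare_groups(values, labels)
        _, s2, _ = compare_groups(values, ~labels)
        assert s1 == pytest.approx(-s2)

    def test_zero_pooled_sd_rejected(self):
        with pytest.raises(ValueError):
            compare_groups(np.r_[np.ones(3), np.zeros(3)],
                           np.r_[np.ones(3, bool), np.zeros(3, bool)])


class TestCorrelate:
    def test_identity_relation(self):
        x = np.arange(10.0)
        out = correlate(x, x)
        assert out["r_pearson"] == pytest.approx(1.0)
        assert out["r_spearman"] == pytest.approx(1.0)

    def test_monotone_nonlinear(self):
        x = np.linspace(0, 3, 30)
        out = correlate(x, np.exp(x))
        assert out["r_spearman"] == pytest.approx(1.0)
        assert out["r_pearson"] < 1.0

    def test_six_pair_toy_matches_direct_formula(self):
        x = np.array([1.0, 4.0, 2.0, 7.0, 5.0, 3.0])
        y = np.array([2.0, 3.0, 2.5, 9.0, 4.0, 2.8])
        out = correlate(x, y)
        r_direct = np.corrcoef(x, y)[0, 1]
        assert out["r_pearson"] == pytest.approx(r_direct, abs=1e-12)
        rx, ry = np.argsort(np.argsort(x)), np.argsort(np.argsort(y))
        assert out["r_spearman"] == pytest.approx(np.corrcoef(rx, ry)[0, 1], abs=1e-12)


class TestBenjaminiHochberg:
    def test_stepup_worked_example(self):
        assert adjust_bh([0.01, 0.02, 0.03, 0.04]) == pytest.approx([0.04] * 4)

    def test_single_p_unchanged(self):
        assert adjust_bh([0.123]) == pytest.approx([0.123])

    def test_all_ones(self):
        assert adjust_bh([1.0, 1.0, 1.0]) == pytest.approx([1.0, 1.0, 1.0])

    @settings(deadline=None, max_examples=40, derandomize=True)
    @given(st.lists(st.floats(0, 1), min_size=1, max_size=12))
    def test_order_invariance_and_lower_bound(self, ps):
        ps = np.asarray(ps)
        adj = adjust_bh(ps)
        perm = np.random.default_rng(0).permutation(ps.size)
        adj_perm = adjust_bh(ps[perm])
        assert adj[perm] == pytest.approx(adj_perm, nan_ok=True)
        # step-up adjustment never drops below the raw p-value
        assert np.all(adj >= ps - 1e-15)
        assert np.all(adj <= 1.0)


def _toy_trends(n_subjects=12, seed=0):
    """Trend fixture: random smooth curves per subject."""
    rng = np.random.default_rng(seed)
    pos = np.linspace(0, 1, 240, endpoint=False)
    trends = {}
    for i in range(n_subjects):
        vals = (100 + rng.normal(0, 15) + 10 * np.sin(2 * np.pi * (pos - rng.uniform(0, 1)))
                + rng.normal(0, 2, pos.size))
        sid = f"s{i:02d}"
        trends[sid] = {m: fit_trend(pos, vals + 5 * k, metric=m)
                       for k, m in enumerate(["sdnn_pct", "sd1_pct", "sd2_pct"])}
    labels = pd.Series(np.arange(n_subjects) < n_subjects // 2,
                       index=list(trends.keys()))
    return trends, labels


def brute_force_ranking(trends, labels, mode, metrics=("sdnn_pct", "sd1_pct", "sd2_pct")):
    """Independent naive re-implementation of the ranked search."""
    grid = np.linspace(0, 1, 10_000, endpoint=False)
    sids = list(labels.index)
    y = labels.to_numpy()
    windows = [(ph, s, e) for ph in ("day", "night") for s in range(5) for e in range(s, 5)]

    def med(sid, metric, win):
        # bins are defined on the 1000-points-per-bin uniform grid, so
        # index arithmetic avoids one-ulp ambiguity at bin edges
        ph, s, e = win
        off = 0 if ph == "day" else 5000
        curve = trends[sid][metric](grid)
        return np.median(curve[off + 1000 * s: off + 1000 * (e + 1)])

    rows = []
    if mode == "single":
        selectors = [(w,) for w in windows]
    else:
        selectors = list(itertools.combinations(windows, 2))
    for mi, metric in enumerate(metrics):
        for sel in selectors:
            if mode == "single":
                vals = np.array([med(s, metric, sel[0]) for s in sids])
            else:
                vals = np.array([med(s, metric, sel[0]) - med(s, metric, sel[1]) for s in sids])
            auc = pair_counting_auc(vals, y)
            # distances are rationals with denominator m*n; round away
            # float summation dust so exact ties break on selector order
            rows.append((round(abs(auc - 0.5), 12), mi, sel, metric, auc))
    rows.sort(key=lambda r: (-r[0], r[1], r[2]))
    return [(r[3], r[2], round(r[4], 12)) for r in rows]


class TestSearch:
    def test_single_matches_brute_force_on_12_subjects(self):
        trends, labels = _toy_trends()
        results = search_single(trends, labels)
        assert len(results) == 90
        oracle = brute_force_ranking(trends, labels, "single")
        got = [
            (r.metric, (("day" if r.selector.phase == "day" else "night",
                         r.selector.start_bin, r.selector.end_bin),), round(r.auc, 12))
            for r in results
        ]
        assert got == oracle

    def test_delta_matches_brute_force_on_12_subjects(self):
        trends, labels = _toy_trends(seed=3)
        results = search_delta(trends, labels)
        assert len(results) == 3 * 435
        oracle = brute_force_ranking(trends, labels, "delta")
        got = []
        for r in results:
            a, b = r.selector.window_a, r.selector.window_b
            got.append((r.metric, ((a.phase, a.start_bin, a.end_bin),
                                   (b.phase, b.start_bin, b.end_bin)), round(r.auc, 12)))
        assert got == oracle

    def test_identical_cohorts_all_chance_with_tiebreak_order(self):
        trends, labels = _toy_trends(seed=5)
        # duplicate case subjects from controls: exchangeable values
        sids = list(labels.index)
        half = len(sids) // 2
        for i in range(half):
            trends[sids[i]] = trends[sids[half + i]]
        results = search_single(trends, labels)
        assert all(r.auc == pytest.approx(0.5) for r in results)
        keys = [(["sdnn_pct", "sd1_pct", "sd2_pct"].index(r.metric), r.selector)
                for r in results]
        assert keys == sorted(keys)

    def test_delta_of_constant_trends_is_chance(self):
        from circahrv.types import CircadianTrend

        def constant_trend(c):
            return CircadianTrend(
                metric="sdnn_pct",
                chebyshev=np.polynomial.Chebyshev([c], domain=[-0.15, 1.15]),
                window_medians=np.full(10, c), n_points=np.full(10, 12),
                degree=10, margin_fraction=0.15)

        trends = {f"s{i}": {"sdnn_pct": constant_trend(90.0 + i)} for i in range(8)}
        labels = pd.Series([True] * 4 + [False] * 4, index=list(trends.keys()))
        results = search_delta(trends, labels, metrics=["sdnn_pct"])
        assert all(r.auc == pytest.approx(0.5, abs=1e-9) for r in results)

    def test_bh_family_is_the_search_report(self):
        trends, labels = _toy_trends(seed=7)
        results = search_single(trends, labels)
        raw = [r.p_mwu for r in results]
        assert [r.p_adjusted for r in results] == pytest.approx(adjust_bh(raw))


class TestWindowAucSearchEstimator:
    def test_sklearn_api_and_transform(self):
        from sklearn.base import clone

        rng = np.random.default_rng(0)
        X = rng.normal(100, 10, (10, 10_000))
        y = np.r_[np.ones(5, bool), np.zeros(5, bool)]
        est = WindowAucSearch(mode="single")
        assert clone(est).get_params() == est.get_params()
        est.fit(X, y)
        assert len(est.selectors_) == 30
        vals = est.transform(X)
        assert vals.shape == (10, 30)
        assert vals[:, 0] == pytest.approx(est.values_[:, 0])


class TestConfounders:
    def test_planted_age_association_flagged(self):
        rng = np.random.default_rng(0)
        age = rng.uniform(20, 70, 60)
        values = age * 0.8 + rng.normal(0, 3, 60)
        findings = confounder_screen(values, age=pd.Series(age))
        assert any(f["covariate"] == "age" and f["flagged"] for f in findings)

    def test_single_level_gender_skipped(self):
        rng = np.random.default_rng(1)
        findings = confounder_screen(rng.normal(size=20),
                                     gender=pd.Series(["w"] * 20))
        assert not any(f["covariate"] == "gender" for f in findings)

    def test_independent_covariates_not_flagged(self):
        rng = np.random.default_rng(2)
        values = rng.normal(size=200)
        findings = confounder_screen(
            values,
            age=pd.Series(rng.uniform(20, 70, 200)),
            gender=pd.Series(rng.choice(["m", "w"], 200)),
            medication=pd.Series(rng.integers(0, 2, 200)),
        )
        # flags occur at roughly the nominal alpha rate; none or one here
        assert sum(f["flagged"] for f in findings) <= 1


class TestDescribeCohort:
    def test_printed_gender_table(self):
        # control 11 m / 13 w vs patient 20 m / 35 w
        assert chi_square(np.array([[11, 20], [13, 35]])) == pytest.approx(0.588, abs=1e-3)

    def test_printed_ethnicity_table(self):
        tab = np.array([[3, 18, 1, 2], [0, 51, 0, 3]])
        assert chi_square(tab.T) == pytest.approx(0.019, abs=1e-3)

    def test_identical_compositions_p_one(self):
        meta = pd.DataFrame({
            "group": ["a"] * 20 + ["b"] * 20,
            "sex": (["m"] * 10 + ["w"] * 10) * 2,
        })
        out = describe_cohort(meta, categorical=["sex"], continuous=[])
        assert out["p"].iloc[0] == pytest.approx(1.0)

    def test_continuous_field_uses_mwu(self):
        rng = np.random.default_rng(0)
        meta = pd.DataFrame({
            "group": ["a"] * 30 + ["b"] * 30,
            "age": np.r_[rng.normal(30, 5, 30), rng.normal(45, 5, 30)],
        })
        out = describe_cohort(meta, categorical=[], continuous=["age"])
        assert out["p"].iloc[0] < 1e-6


class TestGrouping:
    def test_threshold_split(self):
        meta = pd.DataFrame({
            "subject_id": [f"s{i}" for i in range(6)],
            "group": ["control", "control", "patient", "patient", "patient", "patient"],
            "edss": [np.nan, np.nan, 1.0, 3.0, 4.5, 2.0],
        }).set_index("subject_id", drop=False)
        g = GroupingConfig("EDSS", "edss", ">=", 3.0, "other_patients")
        labels = g.split(meta)
        assert list(labels.index) == ["s2", "s3", "s4", "s5"]
        assert list(labels) == [False, True, True, False]

    def test_patient_vs_controls(self):
        meta = pd.DataFrame({
            "subject_id": ["a", "b", "c"],
            "group": ["control", "patient", "patient"],
        }).set_index("subject_id", drop=False)
        g = GroupingConfig("pwMS", "group", "==", "patient", "controls",
                           restrict_to_patients=False)
        labels = g.split(meta)
        assert list(labels) == [False, True, True]
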