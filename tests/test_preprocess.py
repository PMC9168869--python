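"""Artifact screen, correction, segmentation and validity filtering."""
import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from circahrv import preprocess
from circahrv.preprocess import (
    DEFAULT_COEF,
    DEFAULT_FLOOR_MS,
    DEFAULT_WINDOW_BEATS,
    QD_TO_SD,
    apply_validity,
    correct_artifacts,
    detect_artifacts,
    filter_segments,
    segment,
    segment_table,
)
from circahrv.types import ARTIFACT, CLEAN, INTERPOLATED, ActivitySeries, IbiSeries

from conftest import make_series


def brute_force_flags(ibi, window_beats=DEFAULT_WINDOW_BEATS, coef=DEFAULT_COEF,
                      floor=DEFAULT_FLOOR_MS):
    """Independent evaluation of the artifact criterion at every index."""
    ibi = np.asarray(ibi, dtype=float)
    n = ibi.size
    flags = np.zeros(n, dtype=bool)
    if n < window_beats:
        return flags
    half = window_beats // 2
    for i in range(n):
        lo = min(max(i - half, 0), n - window_beats)
        nb = np.delete(ibi[lo:lo + window_beats], i - lo)
        med = np.median(nb)
        qd = 0.5 * (np.percentile(nb, 75) - np.percentile(nb, 25))
        flags[i] = abs(ibi[i] - med) > max(coef * qd / QD_TO_SD, floor)
    return flags


class TestDetect:
    def test_constant_series_has_no_artifacts(self):
        s = make_series([800.0] * 100)
        out = detect_artifacts(s)
        assert not (out.flags == ARTIFACT).any()

    def test_single_outlier_flagged_and_matches_brute_force(self):
        ibi = np.full(100, 800.0)
        ibi[37] = 300.0
        out = detect_artifacts(make_series(ibi))
        assert np.array_equal(out.flags == ARTIFACT, brute_force_flags(ibi))
        assert out.flags[37] == ARTIFACT and (out.flags == ARTIFACT).sum() == 1

    def test_alternating_rhythm_not_flagged(self):
        ibi = np.tile([790.0, 810.0], 60)
        out = detect_artifacts(make_series(ibi))
        assert not (out.flags == ARTIFACT).any()

    def test_matches_brute_force_on_noisy_series(self):
        rng = np.random.default_rng(3)
        ibi = rng.normal(850, 40, 300)
        ibi[[20, 150, 280]] = [400, 1600, 2000]
        out = detect_artifacts(make_series(ibi))
        assert np.array_equal(out.flags == ARTIFACT, brute_force_flags(ibi))

    def test_short_series_gets_no_flags(self, caplog):
        s = make_series([800.0] * 10)
        out = detect_artifacts(s)
        assert not out.flags.any()

    def test_window_must_be_odd(self):
        with pytest.raises(ValueError):
            detect_artifacts(make_series([800.0] * 100), window_beats=40)


class TestCorrect:
    def test_no_artifacts_identity(self):
        s = make_series(np.random.default_rng(0).normal(800, 30, 200))
        out = correct_artifacts(detect_artifacts(s))
        assert np.array_equal(out.ibi, s.ibi)
        assert np.array_equal(out.t, s.t)

    def test_gap_time_conserved_with_two_replacements(self):
        # a 1900 ms gap between clean 800 ms beats is closest to two
        # beats of the local rhythm; exhaustive search over replacement
        # counts confirms k=2 minimizes the time mismatch
        ibi = np.array([800.0] * 10 + [1900.0] + [800.0] * 10)
        gap, local = 1900.0, 800.0
        best_k = min(range(1, 6), key=lambda k: abs(gap - k * local))
        assert best_k == 2
        s = make_series(ibi)
        s.flags[10] = ARTIFACT
        out = correct_artifacts(s)
        assert (out.flags == INTERPOLATED).sum() == 2
        assert np.isclose(out.ibi[10] + out.ibi[11], 1900.0)
        assert np.isclose(out.t[-1], s.t[-1])

    def test_run_of_three_interpolated_as_single_gap(self):
        ibi = np.array([800.0] * 20 + [290.0, 300.0, 310.0] + [800.0] * 20)
        s = make_series(ibi)
        s.flags[20:23] = ARTIFACT
        out = correct_artifacts(s)
        assert (out.flags == ARTIFACT).sum() == 0
        assert (out.flags == INTERPOLATED).sum() >= 1
        assert np.isclose(out.t[-1], s.t[-1])

    def test_boundary_run_dropped_not_interpolated(self):
        s = make_series([300.0] + [800.0] * 50)
        s.flags[0] = ARTIFACT
        out = correct_artifacts(s)
        assert out.n_beats == 50
        assert not (out.flags == INTERPOLATED).any()

    @settings(deadline=None, max_examples=25, derandomize=True)
    @given(st.lists(st.integers(5, 95), min_size=1, max_size=6, unique=True))
    def test_elapsed_time_conserved_for_interior_runs(self, idx):
        rng = np.random.default_rng(11)
        s = make_series(rng.normal(820, 35, 100))
        s.flags[np.asarray(idx)] = ARTIFACT
        out = correct_artifacts(s)
        assert np.isclose(out.t[-1], s.t[-1])
        # flag partition: artifacts never survive correction
        assert set(np.unique(out.flags)) <= {CLEAN, INTERPOLATED}


class TestSegmentation:
    def test_20_minutes_gives_4_segments(self):
        s = make_series([1000.0] * 1200)  # exactly 20 min
        assert len(segment(s)) == 4

    def test_trailing_partial_window_dropped(self):
        s = make_series([1000.0] * 840)  # 14 min
        assert len(segment(s)) == 2

    def test_interpolated_run_statistics(self):
        ibi = np.full(1200, 1000.0)
        s = make_series(ibi)
        s.flags[100:105] = INTERPOLATED
        segs = segment(s)
        assert segs[0].max_interpolated_run == 5
        assert segs[0].n_interpolated == 5
        assert segs[1].max_interpolated_run == 0

    def test_mean_activity_per_segment(self):
        s = make_series([1000.0] * 600)
        act = ActivitySeries("t", np.arange(600.0), np.r_[np.ones(300), 3 * np.ones(300)])
        segs = segment(s, act)
        assert np.isclose(segs[0].mean_activity, 1.0)
        assert np.isclose(segs[1].mean_activity, 3.0)

    def test_objects_match_table(self, small_subject):
        from circahrv.preprocess import segment_table

        s = detect_artifacts(small_subject.ibi)
        c = correct_artifacts(s)
        tab = segment_table(c, small_subject.activity)
        objs = segment(c, small_subject.activity)
        assert len(objs) == len(tab)
        k = len(objs) // 2
        assert objs[k].n_beats == tab["n_beats"].iloc[k]
        assert objs[k].n_interpolated == tab["n_interpolated"].iloc[k]
        assert np.isclose(objs[k].mean_activity, tab["mean_activity"].iloc[k])


class TestValidity:
    def _seg(self, max_run=0, activity=0.0, n_beats=300):
        s = make_series([1000.0] * 1200)
        segs = segment(s)
        seg = segs[0]
        seg.max_interpolated_run = max_run
        seg.mean_activity = activity
        if n_beats != 300:
            seg.ibi = seg.ibi[:n_beats]
        return seg

    def test_five_long_run_excluded_four_survives(self):
        segs = [self._seg(max_run=5), self._seg(max_run=4)]
        filter_segments(segs, activity_threshold=10.0)
        assert not segs[0].valid and segs[0].exclusion_reason == "interpolation_run"
        assert segs[1].valid

    def test_activity_exclusion_and_order(self):
        seg = self._seg(max_run=5, activity=100.0)
        filter_segments([seg], activity_threshold=10.0)
        assert seg.exclusion_reason == "interpolation_run"  # first rule wins
        seg2 = self._seg(activity=100.0)
        filter_segments([seg2], activity_threshold=10.0)
        assert seg2.exclusion_reason == "activity"

    def test_too_few_beats(self):
        seg = self._seg(n_beats=50)
        filter_segments([seg], activity_threshold=10.0, min_beats=100)
        assert seg.exclusion_reason == "too_few_beats"

    def test_idempotent(self):
        segs = [self._seg(max_run=5), self._seg(), self._seg(activity=99.0)]
        filter_segments(segs, activity_threshold=10.0)
        first = [(s.valid, s.exclusion_reason) for s in segs]
        filter_segments(segs, activity_threshold=10.0)
        assert first == [(s.valid, s.exclusion_reason) for s in segs]

    def test_apply_validity_matches_objects(self):
        s = make_series([1000.0] * 2400)
        s.flags[310:316] = INTERPOLATED
        tab = apply_validity(segment_table(s), activity_threshold=None, min_beats=100)
        objs = filter_segments(segment(s), activity_threshold=None, min_beats=100)
        assert list(tab["valid"]) == [o.valid for o in objs]
        assert list(tab["exclusion_reason"]) == [o.exclusion_reason for o in objs]


class TestRecoveryOnSimulatedData:
    def test_sensitivity_and_false_flag_rate(self, small_subject):
        out = detect_artifacts(small_subject.ibi)
        flagged = set(np.where(out.flags == ARTIFACT)[0])
        truth = set(small_subject.artifact_beat_indices.tolist())
        assert truth, "fixture should contain artifacts"
        sens = len(truth & flagged) / len(truth)
        false = len(flagged - truth) / (small_subject.ibi.n_beats - len(truth))
        assert sens >= 0.95
        assert false <= 0.01
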