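"""Robust maximum-likelihood piecewise-linear segmentation: the score
definition, exact small-instance optimality against a brute-force
enumeration oracle, exact recovery on noise-free inputs, and outlier
robustness."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from conftest import gaze_frame
from enumeration_oracle import candidate_score, oracle_best
from okncurve.segmentation import (
    Segment,
    SegmentationParams,
    classify_segments,
    fitted_positions,
    per_sample_velocity,
    segment_gaze,
    segmentation_score,
)

P = SegmentationParams()


def ols_segment(df, s, e, outliers=()):
    t = df["t"].to_numpy()
    use = np.array([i not in set(outliers) for i in range(s, e)])
    t0 = t[s]
    ch = np.polyfit(t[s:e][use] - t0, df["h"].to_numpy()[s:e][use], 1)
    cv = np.polyfit(t[s:e][use] - t0, df["v"].to_numpy()[s:e][use], 1)
    return Segment(s, e, ch[0], cv[0], ch[1], cv[1], t0)


class TestScore:
    def test_collinear_points_match_direct_formula(self):
        """One perfect segment: residual term vanishes and the score
        equals the closed-form constant terms; every alternative
        partition or outlier flag scores strictly lower."""
        t = np.arange(6) / 60.0
        df = gaze_frame(t, 2.0 - 6.9 * t, -1.0 + 0.5 * t)
        seg = [ols_segment(df, 0, 6)]
        got = segmentation_score(df, seg, [], P)
        expected = candidate_score(t, df["h"].to_numpy(), df["v"].to_numpy(),
                                   [0], (), P)
        assert got == pytest.approx(expected, abs=1e-9)
        # closed form: 12 Gaussian max-density terms + priors + param cost
        sigma, dt = P.noise_sd, 1 / 60
        pc = dt / P.expected_segment_length
        q = P.outlier_rate * dt
        by_hand = (12 * np.log(1 / (sigma * np.sqrt(2 * np.pi)))
                   + 5 * np.log(1 - pc) + 6 * np.log(1 - q) - 2 * np.log(6))
        assert got == pytest.approx(by_hand, abs=1e-9)

    def test_flagging_perfect_point_lowers_score(self):
        t = np.arange(8) / 60.0
        df = gaze_frame(t, 1.0 + 3.0 * t, np.zeros(8))
        base = segmentation_score(df, [ols_segment(df, 0, 8)], [], P)
        flagged = segmentation_score(df, [ols_segment(df, 0, 8, [4])], [4], P)
        assert flagged < base

    def test_changepoint_in_linear_run_lowers_score(self):
        t = np.arange(12) / 60.0
        df = gaze_frame(t, -6.9 * t, 0.2 * t)
        one = segmentation_score(df, [ols_segment(df, 0, 12)], [], P)
        two = segmentation_score(df, [ols_segment(df, 0, 6), ols_segment(df, 6, 12)], [], P)
        assert two < one

    def test_invalid_candidates_rejected(self):
        t = np.arange(6) / 60.0
        df = gaze_frame(t, t, t)
        with pytest.raises(ValueError):
            segmentation_score(df, [], [], P)
        with pytest.raises(ValueError):  # does not cover all samples
            segmentation_score(df, [ols_segment(df, 0, 4)], [], P)


class TestSmallInstanceOptimality:
    def test_12_samples_one_outlier_exact(self):
        rng = np.random.default_rng(7)
        t = np.arange(12) / 60.0
        h = 1.0 - 6.9 * t + rng.normal(0, 0.5, 12)
        v = rng.normal(0, 0.5, 12)
        h[5] = 25.0
        df = gaze_frame(t, h, v)
        res = segment_gaze(df, P)
        score, bounds, outliers = oracle_best(t, h, v, P)
        assert res.score == pytest.approx(score, abs=1e-9)
        assert list(res.outlier_idx) == list(outliers) == [5]
        assert [s.start_idx for s in res.segments] == bounds


class TestExactRecovery:
    def test_constant_position_single_segment(self):
        t = np.arange(60) / 60.0
        df = gaze_frame(t, np.full(60, 4.0), np.full(60, -2.0))
        res = segment_gaze(df, P)
        assert len(res.segments) == 1
        assert res.segments[0].slope_h == pytest.approx(0.0, abs=1e-12)
        assert len(res.outlier_idx) == 0

    def test_two_piece_breakpoint_and_slopes(self):
        """Noise-free slow phase followed by a saccadic segment: the
        breakpoint and both slopes are recovered to numerical accuracy."""
        t = np.arange(60) / 60.0
        h = np.where(np.arange(60) < 30, -6.9 * t, 3.0 + 200.0 * (t - 0.5))
        df = gaze_frame(t, h, np.zeros(60))
        res = segment_gaze(df, P)
        assert [s.start_idx for s in res.segments] == [0, 30]
        assert res.segments[0].slope_h == pytest.approx(-6.9, abs=1e-6)
        assert res.segments[1].slope_h == pytest.approx(200.0, abs=1e-6)

    def test_multi_piece_recovery(self):
        t = np.arange(90) / 60.0
        h = np.concatenate([
            -6.9 * t[:30],
            (-6.9 * t[29] + 5.0) + 10.0 * (t[30:60] - t[30]),
            np.full(30, 2.0),
        ])
        v = np.concatenate([0.5 * t[:30], np.full(30, -1.0), -2.0 * (t[60:] - t[60])])
        df = gaze_frame(t, h, v)
        res = segment_gaze(df, P)
        assert [s.start_idx for s in res.segments] == [0, 30, 60]
        for seg, sl_h, sl_v in zip(res.segments, (-6.9, 10.0, 0.0), (0.5, 0.0, -2.0)):
            assert seg.slope_h == pytest.approx(sl_h, abs=1e-6)
            assert seg.slope_v == pytest.approx(sl_v, abs=1e-6)


class TestOutlierRobustness:
    def test_single_outlier_leaves_slopes_unchanged(self):
        t = np.arange(80) / 60.0
        h = -6.9 * t
        v = 0.3 * t
        clean = segment_gaze(gaze_frame(t, h, v), P)
        h2 = h.copy()
        h2[37] = 22.0
        dirty = segment_gaze(gaze_frame(t, h2, v), P)
        assert list(dirty.outlier_idx) == [37]
        assert len(dirty.segments) == len(clean.segments) == 1
        assert dirty.segments[0].slope_h == pytest.approx(
            clean.segments[0].slope_h, abs=1e-3)

    def test_score_consistency_on_noisy_input(self):
        rng = np.random.default_rng(3)
        t = np.arange(200) / 60.0
        h = np.where(np.arange(200) < 110, -6.9 * t, 5 + 4.0 * t)
        h = h + rng.normal(0, 0.5, 200)
        v = rng.normal(0, 0.5, 200)
        h[50] = -28.0
        df = gaze_frame(t, h, v)
        res = segment_gaze(df, P)
        assert res.score == pytest.approx(
            segmentation_score(df, res.segments, res.outlier_idx, P), abs=1e-9)


class TestInputHandling:
    def test_too_few_valid_samples(self):
        t = np.arange(2) / 60.0
        with pytest.raises(ValueError):
            segment_gaze(gaze_frame(t, t, t), P)

    def test_invalid_params(self):
        with pytest.raises(ValueError):
            SegmentationParams(noise_sd=0.0)
        with pytest.raises(ValueError):
            SegmentationParams(min_segment_samples=2)

    def test_long_invalid_gap_splits_series(self):
        """Two linear stretches separated by >0.5 s of invalid samples are
        segmented independently (no changepoint penalty across the gap)."""
        t = np.arange(120) / 60.0
        h = np.where(np.arange(120) < 60, -6.9 * t, 50.0)  # junk in the gap
        valid = np.ones(120, int)
        valid[55:95] = 0
        h2 = np.where(np.arange(120) >= 95, 3.0 + 2.0 * (t - t[95]), h)
        df = gaze_frame(t, h2, np.zeros(120), valid)
        res = segment_gaze(df, P)
        assert len(res.segments) == 2
        assert res.segments[0].end_idx <= 55
        assert res.segments[1].start_idx >= 95

    def test_short_invalid_run_bridged(self):
        t = np.arange(60) / 60.0
        h = -6.9 * t
        valid = np.ones(60, int)
        valid[20:25] = 0
        df = gaze_frame(t, h, np.zeros(60), valid)
        res = segment_gaze(df, P)
        assert len(res.segments) == 1
        assert res.segments[0].slope_h == pytest.approx(-6.9, abs=1e-9)


class TestVelocityAndClassification:
    def test_velocity_inherits_segment_slopes(self):
        t = np.arange(60) / 60.0
        h = np.where(np.arange(60) < 30, -6.9 * t, 4 + 200.0 * (t - 0.5))
        df = gaze_frame(t, h, -1.0 * t)
        res = segment_gaze(df, P)
        vel = per_sample_velocity(res, df)
        assert np.allclose(vel["vel_h"][:30], -6.9)
        assert np.allclose(vel["vel_h"][30:], 200.0)
        assert vel["ok"].all()

    def test_outlier_samples_get_no_velocity(self):
        t = np.arange(60) / 60.0
        h = (-6.9 * t).copy()
        h[10] = 25.0
        res = segment_gaze(gaze_frame(t, h, np.zeros(60)), P)
        vel = per_sample_velocity(res, gaze_frame(t, h, np.zeros(60)))
        assert not vel["ok"][10]
        assert np.isnan(vel["vel_h"][10])

    @pytest.mark.parametrize("slope_h,slope_v,label", [
        (7.0, 0.0, "SP"),          # pursuit speed, below threshold
        (120.0, 160.0, "QP"),      # saccadic speed
        (24.0, 32.0, "QP"),        # exactly 40 deg/s: tie goes to QP
        (-6.9, -1.7, "SP"),
    ])
    def test_classification_threshold(self, slope_h, slope_v, label):
        seg = Segment(0, 10, slope_h, slope_v, 0.0, 0.0, 0.0)
        from okncurve.segmentation import SegmentationResult
        res = SegmentationResult([seg], np.array([], dtype=int), 0.0)
        assert classify_segments(res, 40.0).segments[0].label == label

    def test_fitted_positions_denoise(self):
        rng = np.random.default_rng(11)
        t = np.arange(120) / 60.0
        h_true = -6.9 * t
        h = h_true + rng.normal(0, 0.5, 120)
        df = gaze_frame(t, h, rng.normal(0, 0.5, 120))
        res = segment_gaze(df, P)
        fit = fitted_positions(res, df)
        ok = fit["ok"].to_numpy()
        raw_rms = np.sqrt(np.mean((h - h_true) ** 2))
        fit_rms = np.sqrt(np.mean((fit["h"].to_numpy()[ok] - h_true[ok]) ** 2))
        assert fit_rms < raw_rms


@settings(deadline=None, max_examples=25, derandomize=True)
@given(
    slope=st.floats(-20, 20),
    intercept=st.floats(-10, 10),
    n=st.integers(10, 40),
)
def test_property_noise_free_line_always_one_segment(slope, intercept, n):
    """Any noise-free line, whatever its slope, is a single segment with
    the exact slope and no outliers."""
    t = np.arange(n) / 60.0
    df = gaze_frame(t, intercept + slope * t, np.zeros(n))
    res = segment_gaze(df, P)
    assert len(res.segments) == 1
    assert len(res.outlier_idx) == 0
    assert res.segments[0].slope_h == pytest.approx(slope, abs=1e-6)
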