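"""Statistical surface: displacement, AOI catch, exact sign test,
Silverman bandwidth, 2-D KDE and mode refinement, Hotelling T² regions,
the slow-phase orientation convention, and yaw/2 consistency."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats as sps

from okncurve.segmentation import Segment
from okncurve.stats import (
    aoi_catch,
    aoi_catch_table,
    circular_mean_deg,
    displacement_from_tp,
    entry_vs_cornering_sign_test,
    estimate_mode,
    hotelling_region,
    kde2d,
    silverman_bandwidth,
    sp_orientation_histogram,
    yaw_gaze_consistency,
)


class TestDisplacement:
    def test_gaze_at_tp_is_origin(self):
        g = np.random.default_rng(0).normal(size=(50, 2))
        assert np.allclose(displacement_from_tp(g, g), 0.0)

    def test_elementwise_subtraction(self):
        d = displacement_from_tp(np.array([[10.0, 5.0]]), np.array([[17.0, 2.0]]))
        assert np.allclose(d, [[-7.0, 3.0]])

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            displacement_from_tp(np.zeros((3, 2)), np.zeros((4, 2)))


class TestAoiCatch:
    def test_all_at_tp_is_100(self):
        assert aoi_catch(np.zeros((20, 2)), 2.0) == 100.0

    def test_worked_example(self):
        disp = np.array([[0, 0], [1, 1], [4, 0], [0, 5], [2, 2]], dtype=float)
        assert aoi_catch(disp, 3.0) == pytest.approx(60.0)

    def test_table_radii(self):
        rng = np.random.default_rng(1)
        table = aoi_catch_table(rng.normal(0, 3, (500, 2)))
        assert sorted(table) == list(range(2, 11))

    def test_no_valid_samples_rejected(self):
        with pytest.raises(ValueError):
            aoi_catch(np.full((4, 2), np.nan), 3.0)

    @settings(deadline=None, max_examples=30, derandomize=True)
    @given(seed=st.integers(0, 10_000))
    def test_monotone_in_radius(self, seed):
        rng = np.random.default_rng(seed)
        disp = rng.normal(0, rng.uniform(0.5, 5.0), (100, 2))
        catches = [aoi_catch(disp, r) for r in (2.0, 5.0, 10.0)]
        assert catches[0] <= catches[1] <= catches[2]


class TestSignTest:
    def test_15_of_17_positive(self):
        d = np.array([1.0] * 15 + [-1.0] * 2)
        # exact two-sided binomial sum: 2 * sum_{k=15}^{17} C(17,k) / 2^17
        assert entry_vs_cornering_sign_test(d) == pytest.approx(308 / 131072)

    def test_symmetric_case_capped_at_one(self):
        d = np.array([1.0] * 8 + [-1.0] * 8)
        assert entry_vs_cornering_sign_test(d) == 1.0

    def test_all_positive_boundary(self):
        assert entry_vs_cornering_sign_test(np.ones(17)) == pytest.approx(2 / 2**17)

    def test_zeros_dropped(self):
        d = np.array([1.0] * 15 + [-1.0] * 2 + [0.0] * 5)
        assert entry_vs_cornering_sign_test(d) == pytest.approx(308 / 131072)
        with pytest.raises(ValueError):
            entry_vs_cornering_sign_test(np.zeros(4))


class TestSilverman:
    def test_exact_at_n64_unit_sd(self):
        rng = np.random.default_rng(0)
        p = rng.normal(size=(64, 2))
        p = (p - p.mean(0)) / p.std(0, ddof=1)  # unit sample SD exactly
        hx, hy = silverman_bandwidth(p)
        assert hx == pytest.approx(0.5, abs=1e-12)   # 64 ** (-1/6)
        assert hy == pytest.approx(0.5, abs=1e-12)

    def test_scale_equivariance(self):
        rng = np.random.default_rng(1)
        p = rng.normal(size=(100, 2))
        h1 = silverman_bandwidth(p)
        h3 = silverman_bandwidth(3.0 * p)
        assert h3[0] == pytest.approx(3 * h1[0])
        assert h3[1] == pytest.approx(3 * h1[1])

    def test_monotone_in_n(self):
        rng = np.random.default_rng(2)
        base = rng.normal(size=(1000, 2))
        small = silverman_bandwidth(base[:50])
        # same spread, more points -> smaller bandwidth
        big = silverman_bandwidth(np.vstack([base] * 2)[:2000])
        assert big[0] < small[0]

    def test_degenerate_axis_rejected(self):
        p = np.column_stack([np.arange(10.0), np.ones(10)])
        with pytest.raises(ValueError):
            silverman_bandwidth(p)


class TestKde2d:
    def test_single_point_density(self):
        d = kde2d(np.array([[1.0, -2.0]]), 0.5)
        assert d.integral() == pytest.approx(1.0, abs=0.01)
        m = estimate_mode(d)
        assert m.location[0] == pytest.approx(1.0, abs=1e-6)
        assert m.location[1] == pytest.approx(-2.0, abs=1e-6)

    def test_normalization_on_random_samples(self):
        rng = np.random.default_rng(3)
        for _ in range(5):
            p = rng.normal(rng.uniform(-5, 5, 2), rng.uniform(0.5, 3.0), (200, 2))
            d = kde2d(p, silverman_bandwidth(p))
            assert d.integral() == pytest.approx(1.0, abs=0.01)

    def test_symmetric_clusters_symmetric_density(self):
        a = np.array([[-3.0, 0.0]] * 50 + [[3.0, 0.0]] * 50)
        d = kde2d(a, 1.0, grid_step=0.25)
        mid = d.evaluate(np.array([0.0]), np.array([0.0]))[0]
        left = d.evaluate(np.array([-3.0]), np.array([0.0]))[0]
        right = d.evaluate(np.array([3.0]), np.array([0.0]))[0]
        assert abs(left - right) < 1e-9
        assert mid < left

    def test_majority_cluster_wins_the_mode(self):
        rng = np.random.default_rng(4)
        p = np.vstack([
            rng.normal([-5, 0], 0.8, (800, 2)),
            rng.normal([5, 0], 0.8, (200, 2)),
        ])
        mode = estimate_mode(kde2d(p, silverman_bandwidth(p)))
        assert mode.location[0] < 0

    def test_invalid_bandwidth_rejected(self):
        with pytest.raises(ValueError):
            kde2d(np.zeros((5, 2)), 0.0)


class TestModeEstimate:
    def test_refined_density_not_below_grid_max(self):
        rng = np.random.default_rng(5)
        p = rng.normal([1.3, -0.7], 1.0, (500, 2))
        d = kde2d(p, silverman_bandwidth(p))
        m = estimate_mode(d)
        assert m.density >= d.values.max() - 1e-12

    def test_gaussian_sample_mode_near_mean(self):
        """Consistency against the sample-mean oracle: for Gaussian
        samples (n = 10^4, sd 1) the KDE mode tracks the true mean, with
        a median per-axis error under 0.15."""
        errs = []
        for seed in range(5):
            rng = np.random.default_rng(seed)
            p = rng.normal([2.0, -3.0], 1.0, (10_000, 2))
            m = estimate_mode(kde2d(p, silverman_bandwidth(p)))
            errs += [abs(m.location[0] - 2.0), abs(m.location[1] + 3.0)]
        assert np.median(errs) < 0.15
        assert max(errs) < 0.5


class TestHotelling:
    def test_identity_covariance_closed_form(self):
        """With S = I the 95% region is a circle whose squared radius is
        (2(N-1)/(N-2)) F_{2,N-2}(0.95) / N."""
        rng = np.random.default_rng(7)
        p = rng.normal(size=(17, 2))
        e = hotelling_region(p)
        e.covariance = np.eye(2)
        r2 = e.critical_value(0.95) / 17
        crit = 2 * 16 / 15 * sps.f.ppf(0.95, 2, 15)
        assert r2 == pytest.approx(crit / 17)
        boundary = e.center + np.array([np.sqrt(r2), 0.0])
        assert e.mahalanobis2(boundary) == pytest.approx(e.critical_value(0.95))

    def test_nesting(self):
        rng = np.random.default_rng(8)
        e = hotelling_region(rng.normal(size=(17, 2)))
        assert (e.critical_value(0.95) < e.critical_value(0.99)
                < e.critical_value(0.999))
        pts95 = e.ellipse_points(0.95)
        for p in pts95:  # 95% boundary lies inside the 99.9% region
            assert e.mahalanobis2(p) <= e.critical_value(0.999)

    def test_monte_carlo_coverage(self):
        """Over simulated N=17 Gaussian samples the 95% region contains
        the true mean ~95% of the time (quick check; the full-precision
        run lives in the acceptance suite)."""
        rng = np.random.default_rng(9)
        mu = np.array([1.0, -2.0])
        hits = sum(
            hotelling_region(rng.normal(mu, 1.0, (17, 2))).contains(mu, 0.95)
            for _ in range(400)
        )
        assert abs(hits / 400 - 0.95) < 0.03

    def test_degenerate_sample_rejected(self):
        p = np.column_stack([np.arange(10.0), 2 * np.arange(10.0)])
        with pytest.raises(ValueError):
            hotelling_region(p)


def sp(slope_h, slope_v):
    return Segment(0, 10, slope_h, slope_v, 0.0, 0.0, 0.0, label="SP")


class TestOrientationHistogram:
    def test_convention_up_is_zero_clockwise_positive_h(self):
        counts, edges, _ = sp_orientation_histogram([sp(0, 1)])
        assert counts[0] == 1                      # up -> first bin
        counts, _, _ = sp_orientation_histogram([sp(1, 0)])
        assert counts[9] == 1                      # right -> 90 deg
        counts, _, _ = sp_orientation_histogram([sp(-1, 0)])
        assert counts[27] == 1                     # left -> 270 deg

    def test_zero_velocity_excluded_and_counted(self):
        counts, _, n_zero = sp_orientation_histogram([sp(0, 0), sp(0, 1)])
        assert n_zero == 1
        assert counts.sum() == 1

    def test_down_left_pattern_for_pursuit_slopes(self):
        """Slow phases at (-omega/2, small negative) all land in the
        180-270 deg quadrant (down-left), the optokinetic pursuit
        signature of far-zone tracking."""
        rng = np.random.default_rng(10)
        segs = [sp(-6.9 + rng.normal(0, 0.3), -1.7 + rng.normal(0, 0.3))
                for _ in range(200)]
        counts, edges, _ = sp_orientation_histogram(segs)
        centers = 0.5 * (edges[:-1] + edges[1:])
        mean_dir = circular_mean_deg(
            np.repeat(centers, counts))
        assert 180.0 < mean_dir < 270.0

    def test_qp_segments_ignored(self):
        qp = Segment(0, 5, 200.0, 0.0, 0.0, 0.0, 0.0, label="QP")
        counts, _, _ = sp_orientation_histogram([qp, sp(0, 1)])
        assert counts.sum() == 1
        with pytest.raises(ValueError):
            sp_orientation_histogram([qp])


class TestYawConsistency:
    def test_perfect_half_yaw_gives_zero(self):
        yc = yaw_gaze_consistency(np.full(6, 13.8), np.full(6, -6.9))
        assert yc.mean == 0.0
        assert yc.ci95 == (0.0, 0.0)

    def test_tp_fixation_pattern_excludes_zero(self):
        """Near-zero gaze velocity leaves d ~ omega/2, far from zero."""
        rng = np.random.default_rng(11)
        yaws = rng.normal(13.8, 1.4, 17)
        modal = rng.normal(0.0, 0.05, 17)
        yc = yaw_gaze_consistency(yaws, modal)
        assert yc.mean == pytest.approx(13.8 / 2, abs=1.0)
        assert yc.ci95[0] > 0.0

    def test_signs_pooled_by_magnitude(self):
        yc_pos = yaw_gaze_consistency(np.full(4, 13.8), np.full(4, -6.9))
        yc_neg = yaw_gaze_consistency(np.full(4, -13.8), np.full(4, 6.9))
        assert yc_pos.mean == yc_neg.mean == 0.0

    def test_correlations_and_guards(self):
        rng = np.random.default_rng(12)
        yaw_series = rng.normal(13.8, 0.5, 300)
        sp_series = yaw_series / 2 + rng.normal(0, 1.0, 300)
        yc = yaw_gaze_consistency(
            np.array([13.8, 13.8]), np.array([-6.9, -6.9]),
            [(yaw_series, sp_series), (np.full(300, 13.8), sp_series)],
        )
        assert yc.correlations[0] > 0.2
        assert np.isnan(yc.correlations[1])  # constant yaw: undefined

    def test_too_few_subjects_rejected(self):
        with pytest.raises(ValueError):
            yaw_gaze_consistency(np.array([13.8]), np.array([-6.9]))
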