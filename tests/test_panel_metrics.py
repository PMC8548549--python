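"""Regression and angular-distance metrics against independent oracles."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

import panelgauge as pg
from panelgauge.panel_metrics import (
    DegenerateFitError,
    HYPERMUTATION_INCLUDED,
    NON_HYPERMUTATION,
    UndefinedMetricError,
)


def _pair(x, y, hyper=False, pid="P"):
    return pg.PairedTMB(patient_id=pid, panel_tmb=x, wes_tmb=y, hypermutated=hyper)


class TestFitLinear:
    def test_two_points_determine_the_line(self):
        fit = pg.fit_linear([0, 1], [1, 3])
        assert (fit.slope, fit.intercept) == (2.0, 1.0)

    def test_identity_data_gives_unit_slope_zero_intercept(self):
        x = np.array([1.0, 2.0, 5.0, 9.0])
        fit = pg.fit_linear(x, x)
        assert (fit.slope, fit.intercept) == (1.0, 0.0)

    def test_matches_independent_solver_on_random_vectors(self):
        rng = np.random.default_rng(42)
        for _ in range(100):
            n = int(rng.integers(3, 30))
            x = rng.normal(size=n) * rng.uniform(0.1, 50)
            y = rng.normal(size=n) * rng.uniform(0.1, 50)
            fit = pg.fit_linear(x, y)
            oracle = stats.linregress(x, y)
            assert fit.slope == pytest.approx(oracle.slope, rel=1e-9)
            assert fit.intercept == pytest.approx(oracle.intercept, rel=1e-9, abs=1e-12)
            residuals = y - fit.predict(x)
            assert abs(residuals.sum()) <= 1e-9 * max(1.0, np.abs(y).sum())

    def test_constant_x_raises(self):
        with pytest.raises(DegenerateFitError):
            pg.fit_linear([2.0, 2.0, 2.0], [1.0, 2.0, 3.0])

    def test_length_mismatch_raises(self):
        with pytest.raises(ValueError):
            pg.fit_linear([1.0, 2.0], [1.0])


class TestRSquared:
    def test_perfect_line_gives_one(self):
        x = np.array([1.0, 2.0, 3.0])
        assert pg.r_squared(x, 2 * x + 1) == pytest.approx(1.0)

    def test_equals_squared_pearson_correlation(self):
        rng = np.random.default_rng(7)
        for _ in range(100):
            n = int(rng.integers(3, 40))
            x = rng.uniform(0, 100, size=n)
            y = rng.uniform(0, 100, size=n)
            if np.std(x) == 0 or np.std(y) == 0:
                continue
            r, _ = stats.pearsonr(x, y)
            assert pg.r_squared(x, y) == pytest.approx(r**2, rel=1e-9, abs=1e-12)

    def test_constant_y_raises(self):
        with pytest.raises(UndefinedMetricError):
            pg.r_squared([1.0, 2.0, 3.0], [5.0, 5.0, 5.0])


class TestPolar:
    def test_diagonal_point(self):
        p = pg.to_polar(1.0, 1.0)
        assert p.radius == pytest.approx(math.sqrt(2))
        assert p.angle == pytest.approx(math.pi / 4)

    def test_axis_and_origin_conventions(self):
        assert pg.to_polar(0.0, 5.0).angle == pytest.approx(math.pi / 2)
        assert pg.to_polar(0.0, 0.0).angle == pytest.approx(math.pi / 4)
        assert pg.to_polar(5.0, 0.0).angle == 0.0

    def test_three_four_five_triangle(self):
        p = pg.to_polar(3.0, 4.0)
        assert p.radius == pytest.approx(5.0)
        assert p.angle == pytest.approx(math.atan(4 / 3))

    def test_negative_input_rejected(self):
        with pytest.raises(ValueError):
            pg.to_polar(-1.0, 1.0)


class TestAngularDistance:
    def test_twenty_percent_bias_value(self):
        assert round(pg.angular_distance(0.8, 1.0), 4) == 0.1107

    def test_ten_percent_bias_value(self):
        assert round(pg.angular_distance(0.9, 1.0), 4) == 0.0526

    def test_perfect_agreement_is_zero(self):
        assert pg.angular_distance(7.3, 7.3) == 0.0

    def test_missed_patient_reaches_maximum(self):
        assert pg.angular_distance(0.0, 5.0) == pytest.approx(math.pi / 4)

    @given(
        st.floats(0, 1e6), st.floats(0, 1e6),
        st.floats(1e-3, 1e3),
    )
    @settings(max_examples=200, deadline=None)
    def test_range_symmetry_scale_invariance(self, x, y, k):
        theta = pg.angular_distance(x, y)
        assert 0.0 <= theta <= math.pi / 4 + 1e-12
        assert pg.angular_distance(y, x) == pytest.approx(theta, abs=1e-12)
        assert pg.angular_distance(k * x, k * y) == pytest.approx(theta, abs=1e-9)

    def test_monotone_divergence_from_identity(self):
        y = 10.0
        below = [pg.angular_distance(x, y) for x in (1.0, 4.0, 8.0, 10.0)]
        assert below == sorted(below, reverse=True)
        above = [pg.angular_distance(x, y) for x in (10.0, 14.0, 30.0, 200.0)]
        assert above == sorted(above)

    def test_vectorised_matches_scalar(self):
        rng = np.random.default_rng(3)
        x = rng.uniform(0, 50, 200)
        y = rng.uniform(0, 50, 200)
        x[:5] = 0.0
        y[3:8] = 0.0  # includes (0,0) pairs
        vec = pg.angular_distances(x, y)
        scalar = [pg.angular_distance(a, b) for a, b in zip(x, y)]
        assert vec == pytest.approx(scalar)


class TestMeanAngularDistance:
    def test_mean_of_extremes(self):
        pairs = [_pair(5, 5), _pair(0, 5)]
        assert pg.mean_angular_distance(pairs) == pytest.approx(math.pi / 8)

    def test_empty_cohort_raises(self):
        with pytest.raises(ValueError):
            pg.mean_angular_distance([])

    def test_global_rescaling_leaves_mean_unchanged(self):
        rng = np.random.default_rng(5)
        xy = rng.uniform(0.1, 40, size=(50, 2))
        pairs = [_pair(x, y) for x, y in xy]
        scaled = [_pair(7.7 * x, 7.7 * y) for x, y in xy]
        assert pg.mean_angular_distance(scaled) == pytest.approx(
            pg.mean_angular_distance(pairs)
        )


class TestBiasToTheta:
    def test_printed_threshold_values(self):
        assert round(pg.bias_to_theta(0.20), 4) == 0.1107
        assert round(pg.bias_to_theta(0.10), 4) == 0.0526

    def test_under_over_estimation_symmetry(self):
        assert abs(math.pi / 4 - math.atan(0.8)) == pytest.approx(
            abs(math.pi / 4 - math.atan(1.25)), abs=1e-12
        )
        assert pg.bias_to_theta(0.2) == pytest.approx(
            abs(math.pi / 4 - math.atan(0.8)), abs=1e-12
        )

    def test_vanishes_in_zero_bias_limit(self):
        assert pg.bias_to_theta(1e-9) == pytest.approx(0.0, abs=1e-8)

    @pytest.mark.parametrize("bad", [0.0, 1.0, -0.1, 1.5])
    def test_out_of_range_bias_raises(self, bad):
        with pytest.raises(ValueError):
            pg.bias_to_theta(bad)


class TestBiasRatio:
    def test_ratio_and_zero_numerator(self):
        assert pg.bias_ratio(_pair(8, 10)) == pytest.approx(0.8)
        assert pg.bias_ratio(_pair(0, 10)) == 0.0

    def test_zero_wes_is_undefined_marker(self):
        assert math.isnan(pg.bias_ratio(_pair(5, 0)))


class TestClassificationAccuracy:
    def test_both_misclassified(self):
        pairs = [_pair(9, 11), _pair(11, 9)]
        assert pg.classification_accuracy(pairs, 10.0) == 0.0

    def test_both_concordant(self):
        pairs = [_pair(12, 11), _pair(8, 9)]
        assert pg.classification_accuracy(pairs, 10.0) == 1.0

    def test_identity_pairs_always_perfect(self):
        pairs = [_pair(v, v) for v in (1.0, 9.5, 10.0, 44.0)]
        assert pg.classification_accuracy(pairs, 10.0) == 1.0

    def test_band_is_closed_and_filters(self):
        pairs = [_pair(8, 9), _pair(12, 11), _pair(5, 30)]
        assert pg.classification_accuracy(pairs, 10.0, band=(9, 11)) == 1.0

    def test_empty_band_gives_nan(self):
        assert math.isnan(
            pg.classification_accuracy([_pair(1, 1)], 10.0, band=(9, 11))
        )

    def test_inverted_band_raises(self):
        with pytest.raises(ValueError):
            pg.classification_accuracy([_pair(1, 1)], 10.0, band=(11, 9))


class TestEvaluatePanel:
    def test_identity_panel_is_perfect_in_both_datasets(self):
        pairs = [_pair(v, v, hyper=v > 50) for v in (1.0, 4.0, 9.0, 80.0)]
        for ev in pg.evaluate_panel(pairs):
            assert ev.r_squared == 1.0
            assert ev.mean_angular_distance == 0.0

    def test_no_hypermutated_patients_gives_identical_splits(self):
        rng = np.random.default_rng(9)
        pairs = [_pair(x, x + rng.uniform(0, 1)) for x in rng.uniform(1, 20, 40)]
        included, non_hyper = pg.evaluate_panel(pairs)
        assert included.dataset_label == HYPERMUTATION_INCLUDED
        assert non_hyper.dataset_label == NON_HYPERMUTATION
        assert included.r_squared == non_hyper.r_squared
        assert included.mean_angular_distance == non_hyper.mean_angular_distance

    def test_degenerate_split_reports_theta_with_nan_regression(self):
        pairs = [_pair(3.0, 4.0)]
        (ev,) = pg.evaluate_panel(pairs, split_hypermutation=False)
        assert math.isnan(ev.r_squared)
        assert ev.mean_angular_distance == pytest.approx(pg.angular_distance(3, 4))

    def test_one_extreme_concordant_outlier_inflates_r2_not_theta(self):
        rng = np.random.default_rng(12)
        lam = rng.uniform(1, 10, 300)
        y = rng.poisson(lam * 30) / 30
        x = rng.poisson(lam * 1.0) / 1.0
        base = [_pair(a, b, pid=f"P{i}") for i, (a, b) in enumerate(zip(x, y))]
        augmented = base + [_pair(300.0, 300.0, hyper=True, pid="OUT")]
        ev_base = pg.evaluate_panel(base, split_hypermutation=False)[0]
        ev_incl, ev_excl = pg.evaluate_panel(augmented)
        assert ev_incl.r_squared > ev_excl.r_squared
        assert ev_incl.r_squared > ev_base.r_squared
        assert abs(
            ev_incl.mean_angular_distance - ev_excl.mean_angular_distance
        ) < 0.01


class TestLeverage:
    def test_scaled_concordant_patient_contributes_k_squared_residual(self):
        # cloud noise is orthogonal to (1, x), and each probe patient is
        # paired with a mirror across the line, so the fit is exactly
        # y = 1.05x and the probes see an intercept-free regression
        slope = 1.05
        x_cloud = np.arange(1.0, 201.0)
        noise = np.tile([1.0, -1.0, -1.0, 1.0], 50) * 0.8
        y_cloud = slope * x_cloud + noise
        xm, ym = 10.0, 12.0
        for k in (5.0, 10.0):
            probes_x = np.array([xm, xm, k * xm, k * xm])
            probes_y = np.array(
                [ym, 2 * slope * xm - ym, k * ym, 2 * slope * k * xm - k * ym]
            )
            x = np.concatenate([x_cloud, probes_x])
            y = np.concatenate([y_cloud, probes_y])
            fit = pg.fit_linear(x, y)
            r_base = (ym - fit.predict(xm)) ** 2
            r_scaled = (k * ym - fit.predict(k * xm)) ** 2
            assert r_scaled / r_base == pytest.approx(k**2, rel=0.05)
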