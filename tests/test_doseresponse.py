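"""Dose-response statistics: compensation fraction, LOWESS trends,
Gaussian-window variance. Oracles are brute-force summation and
closed-form regression."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from parmap import doseresponse, synthetic
from parmap.errors import DegenerateFitError, ValidationError


class TestCompensationFraction:
    @pytest.mark.parametrize(
        "hom, hw, hn, expected",
        [
            (1.0, 0.5, 0.5, 0.0),  # no compensation
            (1.0, 0.5, 1.0, 1.0),  # full compensation
            (1.0, 0.5, 0.6, 0.2),
        ],
    )
    def test_tagged_examples(self, hom, hw, hn, expected):
        res = doseresponse.compensation_fraction(hom, hw, hn)
        assert res.fraction == pytest.approx(expected, abs=1e-12)

    def test_outside_unit_interval_flagged(self):
        res = doseresponse.compensation_fraction(1.0, 0.5, 1.2)
        assert "outside_unit_interval" in res.flags

    def test_degenerate_denominator_rejected(self):
        with pytest.raises(ValidationError):
            doseresponse.compensation_fraction(0.5, 0.5, 0.6)

    @settings(max_examples=40, deadline=None, derandomize=True)
    @given(scale=st.floats(0.01, 100.0))
    def test_rescaling_invariance(self, scale):
        base = doseresponse.compensation_fraction(1.0, 0.4, 0.55).fraction
        scaled = doseresponse.compensation_fraction(
            scale * 1.0, scale * 0.4, scale * 0.55
        ).fraction
        assert scaled == pytest.approx(base, rel=1e-9)

    def test_delta_method_ci_brackets_point(self):
        res = doseresponse.compensation_fraction(1.0, 0.5, 0.6, sems=(0.02, 0.02, 0.02))
        assert res.ci_low < res.fraction < res.ci_high

    def test_recovers_generator_truth(self):
        cohorts, truth = synthetic.simulate_genotype_cohorts(
            compensation_fraction_true=0.3, noise_sd=0.02, n_per_genotype=50, seed=5
        )
        res = doseresponse.compensation_fraction(
            cohorts["hom"].mean(), cohorts["het_wt"].mean(), cohorts["het_null"].mean()
        )
        assert res.fraction == pytest.approx(0.3, abs=0.05)


class TestLowess:
    def test_exact_on_linear_data(self):
        x = np.linspace(0, 1, 40)
        tf = doseresponse.lowess_bootstrap(x, 2.0 * x, span=0.5, n_boot=50, seed=0)
        np.testing.assert_allclose(tf.fit, 2.0 * tf.x, atol=1e-8)
        assert np.max(tf.upper - tf.lower) < 1e-8

    def test_constant_y(self):
        rng = np.random.default_rng(1)
        x = rng.uniform(0, 1, 50)
        tf = doseresponse.lowess_bootstrap(x, np.full(50, 3.0), n_boot=50, seed=0)
        np.testing.assert_allclose(tf.fit, 3.0, atol=1e-10)

    def test_flat_kernel_full_span_is_ols(self):
        rng = np.random.default_rng(2)
        x = rng.uniform(0, 1, 60)
        y = 1.5 * x + rng.normal(0, 0.3, 60)
        tf = doseresponse.lowess_bootstrap(x, y, span=1.0, kernel="flat", n_boot=10, seed=0)
        slope, intercept = np.polyfit(x, y, 1)
        np.testing.assert_allclose(tf.fit, intercept + slope * tf.x, atol=1e-8)

    def test_matches_statsmodels_on_smooth_data(self):
        """Independent cross-check: statsmodels' tricube local fit agrees
        with ours within the (local-linear vs local-constant-free) scheme
        differences on a smooth trend."""
        sm = pytest.importorskip("statsmodels.api")
        rng = np.random.default_rng(3)
        x = np.sort(rng.uniform(0, 1, 150))
        y = np.sin(2 * x) + rng.normal(0, 0.02, 150)
        ours = doseresponse.lowess_bootstrap(x, y, span=0.3, n_boot=10, seed=0, grid=x)
        theirs = sm.nonparametric.lowess(y, x, frac=0.3, it=0, return_sorted=False)
        assert np.max(np.abs(ours.fit - theirs)) < 0.02

    def test_hill_recovery_and_steepest_point(self):
        hill = synthetic.HillPhenotype(0.0, 1.0, 0.5, 6.0)
        rng = np.random.default_rng(4)
        x = rng.uniform(0, 1, 200)
        y = hill(x) + rng.normal(0, 0.05, 200)
        tf = doseresponse.lowess_bootstrap(x, y, n_boot=100, seed=1)
        sel = (tf.x >= 0.1) & (tf.x <= 1.0)
        assert np.max(np.abs(tf.fit - hill(tf.x))[sel]) < 0.05
        assert abs(doseresponse.steepest_point(tf) - 0.5) < 0.05

    def test_band_brackets_fit_and_is_reproducible(self):
        rng = np.random.default_rng(5)
        x = rng.uniform(0, 1, 80)
        y = x**2 + rng.normal(0, 0.1, 80)
        tf1 = doseresponse.lowess_bootstrap(x, y, n_boot=200, seed=42)
        tf2 = doseresponse.lowess_bootstrap(x, y, n_boot=200, seed=42)
        assert np.all(tf1.lower <= tf1.fit) and np.all(tf1.fit <= tf1.upper)
        np.testing.assert_array_equal(tf1.lower, tf2.lower)
        np.testing.assert_array_equal(tf1.upper, tf2.upper)

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(ValidationError):
            doseresponse.lowess_bootstrap(np.arange(4), np.arange(4), span=0.5)
        with pytest.raises(DegenerateFitError):
            doseresponse.lowess_bootstrap(np.ones(20), np.arange(20.0))


def _brute_force_window_stats(x, y, centers, sigma):
    means, variances = [], []
    for c in centers:
        w = np.array([np.exp(-((xi - c) ** 2) / (2 * sigma**2)) for xi in x])
        sw = w.sum()
        means.append(sum(wi * xi for wi, xi in zip(w, x)) / sw)
        ybar = sum(wi * yi for wi, yi in zip(w, y)) / sw
        variances.append(sum(wi * (yi - ybar) ** 2 for wi, yi in zip(w, y)) / sw)
    return np.array(means), np.array(variances)


class TestGaussianWindowStats:
    def test_constant_y_zero_variance(self):
        rng = np.random.default_rng(6)
        x = rng.uniform(0, 1, 50)
        ws = doseresponse.gaussian_window_stats(x, np.full(50, 2.0), n_boot=10, seed=0)
        np.testing.assert_allclose(ws.variance, 0.0, atol=1e-12)

    def test_matches_direct_summation_oracle(self):
        """20 random instances (n=50): weighted mean and variance agree with
        an independent direct-summation implementation to 1e-10."""
        for seed in range(20):
            rng = np.random.default_rng(seed)
            x = rng.uniform(0, 1, 50)
            y = rng.normal(0, 1, 50)
            grid = np.linspace(0, 1, 11)
            ws = doseresponse.gaussian_window_stats(x, y, h=0.1, grid=grid, n_boot=1, seed=0)
            m, v = _brute_force_window_stats(x, y, grid, 0.1)
            np.testing.assert_allclose(ws.mean_dosage, m, atol=1e-10)
            np.testing.assert_allclose(ws.variance, v, atol=1e-10)

    def test_wide_window_converges_to_global_variance(self):
        rng = np.random.default_rng(7)
        x = rng.uniform(0, 1, 100)
        y = rng.normal(0, 1, 100)
        ws = doseresponse.gaussian_window_stats(x, y, h=1e4, grid=np.array([0.5]), n_boot=1, seed=0)
        assert ws.variance[0] == pytest.approx(np.var(y), rel=1e-6)

    def test_narrow_window_at_a_data_point_vanishes(self):
        x = np.linspace(0, 1, 20)
        y = np.sin(x)
        ws = doseresponse.gaussian_window_stats(
            x, y, h=1e-4, grid=np.array([x[7]]), n_boot=1, seed=0
        )
        assert ws.variance[0] == pytest.approx(0.0, abs=1e-12)

    def test_variance_peaks_near_hill_inflection(self):
        """Rundown cohort with Hill(K=0.5, n=6) and constant measurement
        noise: the variance profile peaks within 0.1 of dosage 0.5."""
        spec = synthetic.CohortSpec(
            n_embryos=200,
            phenotypes={"asynchrony_s": synthetic.HillPhenotype(0.0, 120.0, 0.5, 6.0)},
            noise_sd={"asynchrony_s": 5.0},
            seed=17,
        )
        table, _ = synthetic.simulate_rundown_cohort(spec)
        x = table["dosage_true"].to_numpy()
        y = table["phenotype_asynchrony_s"].to_numpy()
        ws = doseresponse.gaussian_window_stats(x, y, h=0.1, n_boot=10, seed=0)
        interior = (ws.centers > 0.05) & (ws.centers < 0.95)
        peak = ws.centers[interior][np.nanargmax(ws.variance[interior])]
        assert abs(peak - 0.5) < 0.1

    def test_fwhm_interpretation_widens_sigma(self):
        x = np.linspace(0, 1, 30)
        y = x
        a = doseresponse.gaussian_window_stats(x, y, h=0.1, n_boot=1, seed=0)
        b = doseresponse.gaussian_window_stats(
            x, y, h=0.1, n_boot=1, seed=0, half_width_is_fwhm=True
        )
        assert b.sigma < a.sigma  # FWHM/2 = 0.1 implies sigma ~ 0.085

    def test_ci_brackets_estimate_and_reproducible(self):
        rng = np.random.default_rng(8)
        x = rng.uniform(0, 1, 60)
        y = rng.normal(0, 1, 60)
        w1 = doseresponse.gaussian_window_stats(x, y, n_boot=100, seed=9)
        w2 = doseresponse.gaussian_window_stats(x, y, n_boot=100, seed=9)
        ok = ~np.isnan(w1.variance)
        assert np.all(w1.ci_low[ok] <= w1.variance[ok] + 1e-12)
        assert np.all(w1.variance[ok] <= w1.ci_high[ok] + 1e-12)
        np.testing.assert_array_equal(w1.ci_low, w2.ci_low)


class TestNormalizeDosage:
    def test_controls_average_to_one(self):
        rng = np.random.default_rng(10)
        controls = rng.uniform(50, 70, 30)
        normed = doseresponse.normalize_dosage(controls, controls)
        assert normed.mean() == pytest.approx(1.0)

    def test_quarter_intensity(self):
        controls = np.full(10, 40.0)
        np.testing.assert_allclose(
            doseresponse.normalize_dosage(controls * 0.25, controls), 0.25
        )

    def test_empty_controls_rejected(self):
        with pytest.raises(ValidationError):
            doseresponse.normalize_dosage(np.ones(5), np.array([]))
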