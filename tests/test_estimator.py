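import numpy as np
import pytest

from mucal.estimator import (CalibrationSet, DEFAULT_MU_GRID, RateEstimate,
                             average_calibrations, combine_uncertainty, fit_mu,
                             per_year_rate, propagate_alpha_uncertainty,
                             smooth_variances, tmrca_of_het, weighted_jackknife)
from mucal.hs import CurveValues

D = (np.arange(60) + 0.5) * (0.1 / 60)
H0, HBAR = 7.5e-5, 5.5e-4


def family_curve(mu):
    """A smooth relaxation family: scale of the rise grows with mu (slower
    relaxation at higher mutation rate), heights linear in 1/mu between."""
    scale = 0.12 * (mu / 2.5e-8)
    return CurveValues(H0 + (HBAR - H0) * (1 - np.exp(-D / scale)), H0)


@pytest.fixture
def calib():
    return CalibrationSet(DEFAULT_MU_GRID,
                          [family_curve(m) for m in DEFAULT_MU_GRID])


class TestFit:
    def test_identity_at_every_grid_curve(self, calib):
        for mu in DEFAULT_MU_GRID:
            got = fit_mu(family_curve(mu), calib)
            assert got == pytest.approx(mu, rel=1e-6)

    def test_downward_shift_increases_fitted_rate(self, calib):
        base = family_curve(2e-8)
        shifted = CurveValues(H0 + (base.h - H0) * 0.9, H0)  # slower relaxation
        assert fit_mu(shifted, calib) > fit_mu(base, calib)

    def test_interpolation_recovers_intermediate_rates_within_one_percent(self):
        # synthetic field affine in 1/mu (the family's natural coordinate:
        # curve height tracks starting-point TMRCA ~ 1/mu at fixed theta)
        def field(mu):
            x = 1e-8 / mu
            rise = 1 - np.exp(-D / 0.15)
            return CurveValues(H0 + (HBAR - H0) * rise * (0.3 + 0.7 * x), H0)

        cs = CalibrationSet(DEFAULT_MU_GRID, [field(m) for m in DEFAULT_MU_GRID])
        for mu in (1.4e-8, 2.5e-8, 3.2e-8):
            got = fit_mu(field(mu), cs)
            assert got == pytest.approx(mu, rel=0.01)

    def test_exponential_family_interpolation_error_bounded(self, calib):
        # a family with curvature in 1/mu bounds the worst-case mid-gap error
        for mu in (1.4e-8, 2.5e-8, 3.2e-8):
            got = fit_mu(family_curve(mu), calib)
            assert got == pytest.approx(mu, rel=0.07)

    def test_spline_option_close_to_linear_on_smooth_family(self, calib):
        a = fit_mu(family_curve(2.5e-8), calib, interpolation="linear")
        b = fit_mu(family_curve(2.5e-8), calib, interpolation="spline")
        assert a == pytest.approx(b, rel=0.05)

    def test_one_sided_envelope_escape_raises(self, calib):
        below = CurveValues(family_curve(4e-8).h * 0.5, H0)
        with pytest.raises(ValueError, match="extrapolation"):
            fit_mu(below, calib)

    def test_symmetric_noise_excursions_tolerated(self, calib, rng):
        mid = family_curve(2e-8)
        noisy = CurveValues(mid.h * rng.normal(1.0, 0.08, size=60), H0)
        fit_mu(noisy, calib)  # must not raise

    def test_degenerate_variances_replaced_with_warning(self, calib):
        var = np.ones(60)
        var[5] = 0.0
        with pytest.warns(UserWarning, match="degenerate"):
            fit_mu(family_curve(2e-8), calib, var)

    def test_mismatched_bins_rejected(self):
        with pytest.raises(ValueError):
            CalibrationSet(DEFAULT_MU_GRID,
                           [family_curve(1e-8),
                            CurveValues(np.ones(30), H0),
                            family_curve(4e-8)])

    def test_needs_three_grid_points(self):
        with pytest.raises(ValueError):
            CalibrationSet((1e-8, 2e-8), [family_curve(1e-8), family_curve(2e-8)])


class TestAveragingAndJackknife:
    def test_single_fit_average(self):
        assert average_calibrations([2e-8]) == 2e-8

    def test_replicate_sd_shrinks_with_averaging(self, rng):
        draws = rng.normal(2e-8, 2e-9, size=(200, 25))
        single = draws[:, 0].std(ddof=1)
        averaged = draws.mean(axis=1).std(ddof=1)
        assert averaged < single / 3.5  # ~ 1/sqrt(25) = 1/5 with slack

    def test_identical_loo_estimates_give_zero_se(self):
        loo = np.full(8, 3.1e-8)
        assert weighted_jackknife(3.1e-8, loo, np.ones(8)) == 0.0

    def test_jackknife_matches_known_variance_of_mean(self, rng):
        # statistic = mean over g iid blocks; delete-one jackknife SE equals
        # the sample SE of the mean exactly, which approaches sigma/sqrt(g)
        g, sigma = 20, 0.7
        ses, truth = [], sigma / np.sqrt(g)
        for _ in range(300):
            x = rng.normal(0.0, sigma, size=g)
            full = x.mean()
            loo = np.array([np.delete(x, j).mean() for j in range(g)])
            se = weighted_jackknife(full, loo, np.ones(g))
            assert se == pytest.approx(np.std(x, ddof=1) / np.sqrt(g), rel=1e-9)
            ses.append(se)
        assert np.mean(ses) == pytest.approx(truth, rel=0.05)

    def test_unequal_weights_downweight_small_blocks(self, rng):
        x = rng.normal(0.0, 1.0, size=10)
        w = np.ones(10)
        w[0] = 20.0
        loo = np.array([np.delete(x, j).mean() for j in range(10)])
        se_eq = weighted_jackknife(x.mean(), loo, np.ones(10))
        se_w = weighted_jackknife(x.mean(), loo, w)
        assert se_w != se_eq and se_w > 0

    def test_minimum_blocks(self):
        with pytest.raises(ValueError):
            weighted_jackknife(1.0, np.array([1.0]), np.array([1.0]))


class TestUncertaintyPropagation:
    def test_alpha_regression_reproduces_reported_contribution(self):
        # slope 1.66e-4 (x1e-8 per inverse-Morgan) over alpha, SE 300 -> ~0.05e-8
        def fit_at_alpha(a):
            return 1.6e-8 + 1.66e-4 * 1e-8 * (a - 3100)
        se, fits = propagate_alpha_uncertainty(
            fit_at_alpha, [2500, 3000, 3500, 4000, 4500], 300.0)
        assert se == pytest.approx(0.05e-8, rel=0.01)
        assert len(fits) == 5

    def test_zero_alpha_se_contributes_nothing(self):
        se, _ = propagate_alpha_uncertainty(lambda a: 2e-8 + 1e-12 * a,
                                            [2500, 3500, 4500], 0.0)
        assert se == 0.0

    def test_needs_three_alphas(self):
        with pytest.raises(ValueError):
            propagate_alpha_uncertainty(lambda a: 2e-8, [3000, 3500], 300.0)

    def test_combination_is_root_sum_square(self):
        assert combine_uncertainty(0.3, 0.4) == pytest.approx(0.5)
        assert combine_uncertainty(0.7, 0.0, 0.0) == pytest.approx(0.7)
        assert combine_uncertainty(0.1, 0.2, 0.3) == pytest.approx(
            combine_uncertainty(0.3, 0.1, 0.2))

    def test_each_component_enters_once(self):
        est = RateEstimate(mu_raw=2e-8, mu_corrected=1.8e-8,
                           jackknife_se=1e-9,
                           parameter_se={"alpha": 5e-10, "epsilon": 3e-10})
        expected = np.sqrt(1e-18 + 25e-20 + 9e-20)
        assert est.combined_se == pytest.approx(expected)


class TestConversions:
    def test_per_year_rate_at_29y_generation(self):
        assert per_year_rate(1.61e-8) * 1e9 == pytest.approx(0.555, abs=0.001)

    def test_tmrca_of_typical_starting_heterozygosity(self):
        assert tmrca_of_het(5e-5, 1.61e-8) == pytest.approx(1553, abs=1)

    def test_degenerate_mu_rejected(self):
        with pytest.raises(ValueError):
            tmrca_of_het(5e-5, 0.0)
        with pytest.raises(ValueError):
            per_year_rate(1e-8, 0.0)


class TestVarianceSmoothing:
    def test_profile_preserved_noise_damped(self, rng):
        level = np.geomspace(1e-10, 1e-8, 60)
        noisy = level * rng.lognormal(0, 0.8, size=60)
        sm = smooth_variances(noisy)
        # follows the broad profile
        assert np.corrcoef(np.log(sm), np.log(level))[0, 1] > 0.9
        # local scatter reduced
        assert np.std(np.diff(np.log(sm))) < np.std(np.diff(np.log(noisy)))

    def test_all_bad_variances_fall_back_to_uniform(self):
        assert np.allclose(smooth_variances(np.zeros(10)), 1.0)
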