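"""Estimator correctness against independent oracles and invariants."""

import math

import numpy as np
import pytest
import statsmodels.api as sm

from mrmediate import (
    ivw, mr_egger, mvmr_ivw, to_odds_ratio, wald_ratios, weighted_median,
    weighted_mode,
)
from mrmediate.estimators import (
    EstimatorError, _mode_bandwidth, _mode_point, _weighted_median_point,
)
from conftest import make_iset


class TestWaldRatios:
    def test_definition_arithmetic(self):
        iset = make_iset([0.5], [0.05], [0.1], [0.02])
        (r,) = wald_ratios(iset)
        assert r.theta == pytest.approx(0.2)
        assert r.se_theta == pytest.approx(0.04)
        assert r.weight == pytest.approx(1 / 0.04**2)

    def test_sign_cancellation(self):
        a = wald_ratios(make_iset([0.5], [0.05], [0.1], [0.02]))[0]
        b = wald_ratios(make_iset([-0.5], [0.05], [-0.1], [0.02]))[0]
        assert a.theta == b.theta

    def test_elementwise_division_oracle(self):
        be, bo = [0.2, -0.4, 0.7], [0.05, 0.08, -0.21]
        iset = make_iset(be, [0.01] * 3, bo, [0.02] * 3)
        for r, x, y in zip(wald_ratios(iset), be, bo):
            assert r.theta == pytest.approx(y / x, rel=1e-15)
            assert r.se_theta == pytest.approx(0.02 / abs(x), rel=1e-15)

    def test_zero_exposure_beta_names_snp(self):
        iset = make_iset([0.0], [0.05], [0.1], [0.02])
        with pytest.raises(EstimatorError, match="rs1"):
            wald_ratios(iset)


class TestIVW:
    def test_single_instrument_equals_wald_ratio(self):
        iset = make_iset([0.5], [0.05], [0.1], [0.02])
        est = ivw(iset, model="fixed")
        assert est.beta == pytest.approx(0.2)
        assert est.se == pytest.approx(0.04)

    def test_equal_weights_give_mean(self):
        iset = make_iset([1.0, 1.0, 1.0], [0.1] * 3, [0.1, 0.2, 0.6], [0.05] * 3)
        assert ivw(iset, model="fixed").beta == pytest.approx(0.3)

    def test_equals_weighted_through_origin_regression(self, hand_iset):
        """IVW of Wald ratios == WLS of outcome on exposure betas with no
        intercept and weights 1/outcome_se^2 (independent statsmodels fit)."""
        be = np.array([p.exposure_beta for p in hand_iset.pairs])
        bo = np.array([p.outcome_beta for p in hand_iset.pairs])
        so = np.array([p.outcome_se for p in hand_iset.pairs])
        fit = sm.WLS(bo, be[:, None], weights=1 / so**2).fit()
        assert ivw(hand_iset, model="fixed").beta == pytest.approx(fit.params[0], abs=1e-10)

    def test_random_effects_never_narrower_than_fixed(self, hand_iset):
        assert ivw(hand_iset).se >= ivw(hand_iset, model="fixed").se

    def test_single_snp_random_falls_back_with_warning(self):
        iset = make_iset([0.5], [0.05], [0.1], [0.02])
        with pytest.warns(UserWarning, match="single instrument"):
            est = ivw(iset, model="multiplicative_random")
        assert est.se == pytest.approx(0.04)


class TestEgger:
    def test_weighted_normal_equations_oracle(self):
        iset = make_iset([0.2, 0.3, 0.4, 0.6], [0.01] * 4,
                         [0.09, 0.11, 0.17, 0.22], [0.02, 0.01, 0.03, 0.02])
        est = mr_egger(iset)
        x = np.array([0.2, 0.3, 0.4, 0.6])
        y = np.array([0.09, 0.11, 0.17, 0.22])
        w = 1 / np.array([0.02, 0.01, 0.03, 0.02]) ** 2
        fit = sm.WLS(y, sm.add_constant(x), weights=w).fit()
        assert est.beta == pytest.approx(fit.params[1], abs=1e-10)
        assert est.extras["intercept"] == pytest.approx(fit.params[0], abs=1e-10)

    def test_exact_fit_recovers_slope_and_zero_intercept(self):
        be = [0.2, 0.3, 0.5]
        c = 0.4
        iset = make_iset(be, [0.01] * 3, [c * b for b in be], [0.02] * 3)
        est = mr_egger(iset)
        assert est.beta == pytest.approx(c, abs=1e-12)
        assert est.extras["intercept"] == pytest.approx(0.0, abs=1e-12)

    def test_orientation_invariance_to_allele_coding(self):
        """Negating any instrument's exposure and outcome betas leaves the
        Egger fit unchanged (internal reorientation)."""
        be = [0.2, 0.3, 0.4, 0.6]
        bo = [0.09, 0.11, 0.17, 0.22]
        a = mr_egger(make_iset(be, [0.01] * 4, bo, [0.02] * 4))
        be2 = [-be[0]] + be[1:]
        bo2 = [-bo[0]] + bo[1:]
        b = mr_egger(make_iset(be2, [0.01] * 4, bo2, [0.02] * 4))
        assert a.beta == pytest.approx(b.beta, abs=1e-14)
        assert a.extras["intercept"] == pytest.approx(b.extras["intercept"], abs=1e-14)

    def test_requires_three_instruments(self):
        with pytest.raises(EstimatorError):
            mr_egger(make_iset([0.2, 0.3], [0.01] * 2, [0.1, 0.1], [0.02] * 2))


class TestWeightedMedian:
    def test_plain_median_under_equal_weights(self):
        iset = make_iset([1.0, 1.0, 1.0], [0.01] * 3, [1.0, 2.0, 9.0], [0.5] * 3)
        est = weighted_median(iset, n_boot=100, seed=1)
        assert est.beta == pytest.approx(2.0)

    def test_majority_weight_dominates(self):
        # >50% of weight on the rs1 ratio (small outcome se => big weight)
        iset = make_iset([1.0, 1.0, 1.0], [0.01] * 3,
                         [1.0, 5.0, 9.0], [0.01, 1.0, 1.0])
        est = weighted_median(iset, n_boot=100, seed=1)
        assert est.beta == pytest.approx(1.0, abs=0.05)

    def test_cumulative_weight_interpolation_oracle(self):
        """Point estimate equals a fine-grid scan of the weighted-quantile
        definition, recomputed independently."""
        rng = np.random.default_rng(2)
        theta = rng.normal(0.3, 0.2, 5)
        w = rng.uniform(0.5, 3.0, 5)
        # implementation path
        got = _weighted_median_point(theta, w)
        # oracle: scan a fine grid for the 50% crossing of the interpolant
        order = np.argsort(theta)
        th, ww = theta[order], w[order] / w.sum()
        s = np.cumsum(ww) - 0.5 * ww
        grid = np.linspace(th[0], th[-1], 100_001)
        cum = np.interp(grid, th, s)
        expect = grid[int(np.argmin(np.abs(cum - 0.5)))]
        assert got == pytest.approx(expect, abs=1e-4)

    def test_bootstrap_reproducible(self, hand_iset):
        a = weighted_median(hand_iset, n_boot=200, seed=42)
        b = weighted_median(hand_iset, n_boot=200, seed=42)
        assert a.se == b.se

    def test_small_bootstrap_warns(self, hand_iset):
        with pytest.warns(UserWarning, match="n_boot"):
            weighted_median(hand_iset, n_boot=50, seed=1)


class TestWeightedMode:
    def test_modal_cluster_beats_mean(self):
        iset = make_iset([1.0] * 3, [0.01] * 3, [1.0, 1.01, 5.0], [0.5] * 3)
        est = weighted_mode(iset, bandwidth_factor=0.5, n_boot=100, seed=1)
        assert abs(est.beta - 1.005) < 0.2
        assert abs(est.beta - np.mean([1.0, 1.01, 5.0])) > 0.5

    def test_degenerate_density_exact(self):
        iset = make_iset([1.0, 2.0, 0.5], [0.01] * 3, [0.3, 0.6, 0.15], [0.05] * 3)
        est = weighted_mode(iset, n_boot=100, seed=1)
        assert est.beta == 0.3  # all ratios identical

    def test_grid_search_oracle(self):
        """Maximizer matches a dense grid search over the same weighted KDE."""
        rng = np.random.default_rng(9)
        theta = np.concatenate([rng.normal(0.2, 0.02, 4), [0.8, 1.1]])
        w = rng.uniform(0.5, 2.0, 6)
        w = w / w.sum()
        h = _mode_bandwidth(theta, 1.0)
        got = _mode_point(theta, w, h)

        def kde(x):
            return float((w * np.exp(-0.5 * ((x - theta) / h) ** 2)).sum())

        grid = np.linspace(theta.min() - 3 * h, theta.max() + 3 * h, 100_000)
        dens = (w[None, :] * np.exp(-0.5 * ((grid[:, None] - theta[None, :]) / h) ** 2)).sum(axis=1)
        x0 = grid[int(np.argmax(dens))]
        # ternary-search refinement of the oracle, independent of scipy
        lo, hi = x0 - (grid[1] - grid[0]), x0 + (grid[1] - grid[0])
        for _ in range(200):
            m1, m2 = lo + (hi - lo) / 3, hi - (hi - lo) / 3
            if kde(m1) < kde(m2):
                lo = m1
            else:
                hi = m2
        # agreement is limited by float flatness of the KDE near its peak
        assert got == pytest.approx((lo + hi) / 2, abs=1e-8)
        assert kde(got) >= kde((lo + hi) / 2) - 1e-14

    def test_zero_bandwidth_error(self, hand_iset):
        with pytest.raises(EstimatorError, match="bandwidth"):
            weighted_mode(hand_iset, bandwidth_factor=0.0, n_boot=100, seed=1)


class TestMVMR:
    def test_zero_second_column_collapses_to_univariable(self, hand_iset):
        be = np.array([p.exposure_beta for p in hand_iset.pairs])
        bo = [p.outcome_beta for p in hand_iset.pairs]
        so = [p.outcome_se for p in hand_iset.pairs]
        ests = mvmr_ivw(bo, so, np.column_stack([be, np.zeros_like(be)]))
        assert ests[0].beta == pytest.approx(ivw(hand_iset, model="fixed").beta, abs=1e-12)
        assert ests[1].beta == 0.0

    def test_generalized_least_squares_oracle(self):
        X = np.array([[0.2, 0.05], [0.3, -0.1], [0.1, 0.2], [0.4, 0.15]])
        y = np.array([0.08, 0.05, 0.09, 0.17])
        so = np.array([0.02, 0.03, 0.02, 0.04])
        ests = mvmr_ivw(y, so, X)
        fit = sm.WLS(y, X, weights=1 / so**2).fit()
        for e, b in zip(ests, fit.params):
            assert e.beta == pytest.approx(b, abs=1e-10)

    def test_parameter_recovery_on_synthetic_data(self):
        rng = np.random.default_rng(22)
        g1 = rng.normal(0, 0.1, 50)
        g2 = rng.normal(0, 0.1, 50)
        so = np.full(50, 0.01)
        y = 0.3 * g1 - 0.2 * g2 + rng.normal(0, so)
        ests = mvmr_ivw(y, so, np.column_stack([g1, g2]))
        for e, truth in zip(ests, (0.3, -0.2)):
            assert abs(e.beta - truth) < 2 * e.se

    def test_collinear_exposures_error(self):
        X = np.array([[0.2, 0.4], [0.3, 0.6], [0.1, 0.2], [0.4, 0.8]])
        with pytest.raises(EstimatorError, match="collinear"):
            mvmr_ivw([0.1] * 4, [0.02] * 4, X)


class TestOddsRatio:
    @pytest.mark.parametrize("beta,expected", [(0.004, 1.004), (0.002, 1.002)])
    def test_published_scale_conversion(self, beta, expected):
        est = ivw(make_iset([1.0], [0.001], [beta], [0.001]), model="fixed")
        o, _, _ = to_odds_ratio(est)
        assert round(o, 3) == expected

    def test_null_effect(self):
        est = ivw(make_iset([1.0], [0.001], [0.0], [0.05]), model="fixed")
        o, lo, hi = to_odds_ratio(est)
        assert o == 1.0
        assert lo == pytest.approx(math.exp(-1.959964 * 0.05))
        assert hi == pytest.approx(math.exp(1.959964 * 0.05))


class TestScaleEquivariance:
    def test_all_point_estimates_scale_inversely_with_exposure(self, hand_iset):
        c = 2.5
        be = [p.exposure_beta * c for p in hand_iset.pairs]
        se_e = [p.exposure_se * c for p in hand_iset.pairs]
        bo = [p.outcome_beta for p in hand_iset.pairs]
        so = [p.outcome_se for p in hand_iset.pairs]
        scaled = make_iset(be, se_e, bo, so)
        assert ivw(scaled, model="fixed").beta * c == pytest.approx(
            ivw(hand_iset, model="fixed").beta, rel=1e-12)
        assert mr_egger(scaled).beta * c == pytest.approx(
            mr_egger(hand_iset).beta, rel=1e-12)
        th = np.array([p.outcome_beta / p.exposure_beta for p in hand_iset.pairs])
        w = np.array([p.exposure_beta**2 / p.outcome_se**2 for p in hand_iset.pairs])
        assert _weighted_median_point(th / c, w * c**2) * c == pytest.approx(
            _weighted_median_point(th, w), rel=1e-12)
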