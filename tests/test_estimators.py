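"""Causal-effect estimators against independent oracles and invariants."""

import numpy as np
import pytest

from mrkit.calibration import hset_from_arrays
from mrkit.estimators import egger, ivw, median_estimator, mvmr, wald_ratio


def wls_through_origin_oracle(bx, by, sy):
    """Independently coded weighted least squares with no intercept."""
    w = 1.0 / np.asarray(sy) ** 2
    X = np.asarray(bx)[:, None]
    y = np.asarray(by)
    beta = np.linalg.solve((X * w[:, None]).T @ X, (X * w[:, None]).T @ y)
    return float(beta[0])


def weighted_regression_oracle(bx, by, sy):
    """Independently coded weighted regression with intercept (via lstsq on
    rescaled variables)."""
    sw = 1.0 / np.asarray(sy)
    X = np.column_stack([np.ones_like(bx), bx]) * sw[:, None]
    y = np.asarray(by) * sw
    coef, *_ = np.linalg.lstsq(X, y, rcond=None)
    return float(coef[0]), float(coef[1])


def cumulative_weight_median_oracle(theta, weights):
    """Brute-force mid-cumulative-weight interpolation."""
    order = np.argsort(theta)
    t = np.asarray(theta)[order]
    w = np.asarray(weights)[order]
    s = np.cumsum(w)
    p = (s - w / 2) / s[-1]
    if 0.5 <= p[0]:
        return float(t[0])
    if 0.5 >= p[-1]:
        return float(t[-1])
    i = np.searchsorted(p, 0.5)
    return float(t[i - 1] + (0.5 - p[i - 1]) / (p[i] - p[i - 1]) * (t[i] - t[i - 1]))


class TestWaldRatio:
    def test_stated_formula(self):
        r = wald_ratio((0.10, 0.01), (0.05, 0.02))
        assert r.theta_j == pytest.approx(0.5)
        assert r.se_j == pytest.approx(0.2)

    def test_null_numerator(self):
        r = wald_ratio((0.10, 0.01), (0.0, 0.02))
        assert r.theta_j == 0.0 and r.se_j == pytest.approx(0.2)

    def test_negative_exposure_effect(self):
        r = wald_ratio((-0.2, 0.01), (0.04, 0.05))
        assert r.theta_j == pytest.approx(-0.2)
        assert r.se_j == pytest.approx(0.25)

    def test_zero_exposure_effect_is_error(self):
        with pytest.raises(ValueError):
            wald_ratio((0.0, 0.01), (0.05, 0.02))


class TestIVW:
    def test_single_snp_reduces_to_wald_ratio(self):
        h = hset_from_arrays([0.1], [0.01], [0.05], [0.02])
        res = ivw(h)
        w = wald_ratio((0.1, 0.01), (0.05, 0.02))
        assert res.estimate == pytest.approx(w.theta_j, abs=1e-12)
        assert res.se == pytest.approx(w.se_j, abs=1e-12)

    def test_homogeneous_ratios_give_zero_overdispersion(self):
        bx = np.array([0.1, 0.2, 0.4])
        h = hset_from_arrays(bx, 0.01 * np.ones(3), 0.5 * bx, [0.01, 0.02, 0.015])
        fe = ivw(h, model="fixed")
        mre = ivw(h, model="multiplicative_random")
        assert fe.estimate == pytest.approx(0.5, abs=1e-12)
        assert mre.se == pytest.approx(fe.se, abs=1e-15)  # Q = 0, floor at 1

    def test_matches_wls_oracle(self):
        bx = np.array([0.1, 0.2, 0.3])
        by = np.array([0.02, 0.06, 0.03])
        sy = np.array([0.01, 0.02, 0.015])
        h = hset_from_arrays(bx, 0.01 * np.ones(3), by, sy)
        assert ivw(h).estimate == pytest.approx(
            wls_through_origin_oracle(bx, by, sy), abs=1e-10
        )

    def test_mre_se_never_below_fixed(self, rng):
        for _ in range(20):
            J = int(rng.integers(2, 12))
            bx = rng.normal(0.1, 0.05, J)
            by = rng.normal(0.0, 0.05, J)
            sy = rng.uniform(0.005, 0.05, J)
            h = hset_from_arrays(bx, 0.01 * np.ones(J), by, sy)
            assert ivw(h).se >= ivw(h, model="fixed").se - 1e-15

    def test_binary_outcome_reports_odds_ratio(self):
        h = hset_from_arrays([0.1, 0.2], [0.01, 0.01], [0.05, 0.1], [0.02, 0.02],
                             outcome_type="binary")
        res = ivw(h)
        assert np.log(res.odds_ratio) == pytest.approx(res.estimate, abs=1e-12)
        assert res.or_ci_low < res.odds_ratio < res.or_ci_high

    def test_empty_set_is_error(self):
        with pytest.raises(ValueError):
            ivw(hset_from_arrays([], [], [], []))


class TestEgger:
    def test_exact_linear_fit_recovered(self):
        bx = np.array([0.05, 0.1, 0.15, 0.2, 0.3])
        by = 0.01 + 0.3 * bx
        h = hset_from_arrays(bx, 0.01 * np.ones(5), by, [0.01, 0.02, 0.01, 0.03, 0.02])
        res = egger(h)
        assert res.intercept == pytest.approx(0.01, abs=1e-12)
        assert res.slope.estimate == pytest.approx(0.3, abs=1e-12)

    def test_two_snps_is_degenerate(self):
        h = hset_from_arrays([0.1, 0.2], [0.01, 0.01], [0.05, 0.1], [0.02, 0.02])
        with pytest.raises(ValueError):
            egger(h)

    def test_matches_weighted_regression_oracle(self, rng):
        for _ in range(50):
            J = int(rng.integers(3, 11))
            bx = np.abs(rng.normal(0.1, 0.05, J)) + 0.01
            by = rng.normal(0.02, 0.05, J)
            sy = rng.uniform(0.005, 0.05, J)
            h = hset_from_arrays(bx, 0.01 * np.ones(J), by, sy)
            res = egger(h)
            oi, osl = weighted_regression_oracle(bx, by, sy)
            assert res.intercept == pytest.approx(oi, abs=1e-10)
            assert res.slope.estimate == pytest.approx(osl, abs=1e-10)

    def test_orientation_invariance(self):
        """Negating an instrument's pair of betas leaves Egger unchanged."""
        bx = np.array([0.05, -0.1, 0.15, -0.2])
        by = np.array([0.02, -0.04, 0.05, -0.07])
        sy = np.array([0.01, 0.02, 0.01, 0.03])
        h1 = hset_from_arrays(bx, 0.01 * np.ones(4), by, sy)
        h2 = hset_from_arrays(-bx, 0.01 * np.ones(4), -by, sy)
        r1, r2 = egger(h1), egger(h2)
        assert r1.slope.estimate == pytest.approx(r2.slope.estimate, abs=1e-12)
        assert r1.intercept == pytest.approx(r2.intercept, abs=1e-12)


class TestMedians:
    def test_odd_count_equal_weights_is_middle_ratio(self):
        h = hset_from_arrays([0.1, 0.1, 0.1], [0.01] * 3,
                             [0.01, 0.02, 0.09], [0.01] * 3)
        res = median_estimator(h, "simple", n_boot=100, seed=1)
        assert res.estimate == pytest.approx(0.2)

    def test_identical_ratios_degenerate_bootstrap(self):
        bx = np.array([0.1, 0.2, 0.3])
        h = hset_from_arrays(bx, 1e-6 * np.ones(3), 0.5 * bx, 1e-6 * np.ones(3))
        res = median_estimator(h, "simple", n_boot=100, seed=1)
        assert res.estimate == pytest.approx(0.5, abs=1e-3)
        assert res.se > 0

    def test_weighted_matches_interpolation_oracle(self):
        ratios = np.array([0.0, 0.1, 0.2, 0.9])
        weights = np.array([1.0, 1.0, 3.0, 1.0])
        bx = np.ones(4)
        by = ratios.copy()
        sy = 1.0 / np.sqrt(weights)  # se_j = sy/|bx| so w_j = 1/se_j^2 = weights
        h = hset_from_arrays(bx, 0.01 * np.ones(4), by, sy)
        res = median_estimator(h, "inverse_variance", n_boot=100, seed=2)
        assert res.estimate == pytest.approx(
            cumulative_weight_median_oracle(ratios, weights), abs=1e-12
        )

    def test_equal_weights_equivalent_to_simple(self, rng):
        J = 9
        bx = rng.normal(0.2, 0.02, J)
        by = rng.normal(0.04, 0.02, J)
        h_uniform = hset_from_arrays(bx, 0.01 * np.ones(J), by,
                                     0.02 * np.abs(bx))  # sy/|bx| constant
        simple = median_estimator(h_uniform, "simple", n_boot=100, seed=3)
        weighted = median_estimator(h_uniform, "inverse_variance", n_boot=100, seed=3)
        assert simple.estimate == pytest.approx(weighted.estimate, abs=1e-12)

    def test_too_few_snps_is_error(self):
        h = hset_from_arrays([0.1, 0.2], [0.01] * 2, [0.05, 0.1], [0.02] * 2)
        with pytest.raises(ValueError):
            median_estimator(h, "simple", n_boot=100, seed=1)


class TestMVMR:
    def test_single_exposure_reduces_to_ivw(self, rng):
        J = 8
        bx = rng.normal(0.15, 0.05, J)
        by = rng.normal(0.03, 0.03, J)
        sy = rng.uniform(0.01, 0.03, J)
        h = hset_from_arrays(bx, 0.01 * np.ones(J), by, sy)
        uni = ivw(h, model="multiplicative_random")
        [(name, mv)] = mvmr(bx[:, None], by, sy, binary_outcome=False)
        assert mv.estimate == pytest.approx(uni.estimate, abs=1e-10)
        assert mv.se == pytest.approx(uni.se, abs=1e-10)

    def test_orthogonal_exposures_decouple(self, rng):
        """With orthogonal exposure-effect columns, each joint estimate
        equals its own univariable IVW."""
        J = 10
        g1 = np.zeros(J); g1[:5] = rng.normal(0.2, 0.02, 5)
        g2 = np.zeros(J); g2[5:] = rng.normal(0.15, 0.02, 5)
        sy = np.full(J, 0.02)
        by = 0.3 * g1 - 0.2 * g2 + rng.normal(0, 0.002, J)
        results = mvmr(np.column_stack([g1, g2]), by, sy, binary_outcome=False)
        for k, g in enumerate((g1, g2)):
            nz = g != 0
            h = hset_from_arrays(g[nz], 0.01 * np.ones(nz.sum()), by[nz], sy[nz])
            uni = ivw(h)
            assert results[k][1].estimate == pytest.approx(uni.estimate, abs=1e-10)

    def test_duplicated_exposure_column_is_error(self):
        g = np.linspace(0.1, 0.5, 6)
        with pytest.raises(ValueError, match="rank"):
            mvmr(np.column_stack([g, g]), 0.3 * g, np.full(6, 0.02))

    def test_more_exposures_than_snps_is_error(self):
        with pytest.raises(ValueError):
            mvmr(np.ones((2, 2)), np.ones(2), np.ones(2))

    def test_recovers_joint_effects(self, rng):
        J = 200
        G = rng.normal(0, 0.1, size=(J, 2))
        by = G @ np.array([0.3, -0.2]) + rng.normal(0, 0.005, J)
        results = mvmr(G, by, np.full(J, 0.005), binary_outcome=False)
        assert results[0][1].estimate == pytest.approx(0.3, abs=0.01)
        assert results[1][1].estimate == pytest.approx(-0.2, abs=0.01)


class TestScaleEquivariance:
    def test_rescaling_exposure_divides_estimates(self, rng):
        J = 12
        bx = rng.normal(0.15, 0.05, J)
        sx = np.full(J, 0.01)
        by = 0.4 * bx + rng.normal(0, 0.01, J)
        sy = rng.uniform(0.01, 0.03, J)
        c = 2.5
        h1 = hset_from_arrays(bx, sx, by, sy)
        h2 = hset_from_arrays(c * bx, c * sx, by, sy)
        assert ivw(h2).estimate == pytest.approx(ivw(h1).estimate / c, abs=1e-12)
        assert egger(h2).slope.estimate == pytest.approx(
            egger(h1).slope.estimate / c, abs=1e-12
        )
        m1 = median_estimator(h1, "inverse_variance", n_boot=100, seed=4)
        m2 = median_estimator(h2, "inverse_variance", n_boot=100, seed=4)
        assert m2.estimate == pytest.approx(m1.estimate / c, abs=1e-12)
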