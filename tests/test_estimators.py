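"""MR estimators against closed-form and brute-force oracles."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mrpipe.estimators import (
    EstimatorError,
    egger,
    i2_gx,
    ivw,
    mode_bandwidth,
    mr_raps,
    wald_ratio,
    weighted_median,
    weighted_mode,
)
from mrpipe.synthetic import SimConfig, simulate_instruments

from conftest import make_pairs


class TestWaldRatio:
    def test_arithmetic(self):
        p = make_pairs([0.1], [0.01], [0.02], [0.01])[0]
        est = wald_ratio(p)
        assert est.ratio == pytest.approx(0.2)
        assert est.se_ratio == pytest.approx(0.1)
        assert est.weight == pytest.approx(1 / 0.1**2)

    def test_sign_symmetry(self):
        p1 = make_pairs([0.1], [0.01], [0.02], [0.01])[0]
        p2 = make_pairs([-0.1], [0.01], [-0.02], [0.01])[0]
        assert wald_ratio(p1).ratio == pytest.approx(wald_ratio(p2).ratio)

    def test_zero_exposure_effect_errors(self):
        p = make_pairs([0.0], [0.01], [0.02], [0.01])[0]
        with pytest.raises(EstimatorError, match="beta_exp"):
            wald_ratio(p)


class TestIvw:
    def test_single_pair_equals_wald_exactly(self):
        p = make_pairs([0.13], [0.01], [0.021], [0.013])
        assert ivw(p, mode="fixed").beta == wald_ratio(p[0]).ratio

    def test_symmetric_average(self):
        pairs = make_pairs([0.1, 0.1], [0.01, 0.01], [0.01, 0.03], [0.02, 0.02])
        assert ivw(pairs, mode="fixed").beta == pytest.approx(0.2)

    def test_matches_wls_through_origin_oracle(self, eight_pairs):
        import statsmodels.api as sm

        bx = np.array([p.beta_exp for p in eight_pairs])
        by = np.array([p.beta_out for p in eight_pairs])
        sy = np.array([p.se_out for p in eight_pairs])
        oracle = sm.WLS(by, bx[:, None], weights=1 / sy**2).fit().params[0]
        assert ivw(eight_pairs, mode="fixed").beta == pytest.approx(oracle, abs=1e-10)

    def test_mre_se_equals_fe_se_when_homogeneous(self):
        # exact proportionality => Q = 0 <= J - 1
        bx = np.array([0.1, 0.2, 0.3])
        pairs = make_pairs(bx, [0.01] * 3, 0.5 * bx, [0.02] * 3)
        assert ivw(pairs, "multiplicative_random").se == pytest.approx(
            ivw(pairs, "fixed").se
        )

    def test_mre_never_deflates_se(self):
        rng = np.random.default_rng(3)
        for seed in range(10):
            pairs, _ = simulate_instruments(
                SimConfig(n_snp=20, seed=seed, exposure_effect_sd=0.1)
            )
            assert ivw(pairs, "multiplicative_random").se >= ivw(pairs, "fixed").se

    def test_j1_mre_falls_back_to_fixed_with_warning(self):
        p = make_pairs([0.1], [0.01], [0.02], [0.01])
        with pytest.warns(UserWarning, match="J >= 2"):
            est = ivw(p, mode="multiplicative_random")
        assert est.method == "ivw_fe"

    def test_empty_errors(self):
        with pytest.raises(EstimatorError):
            ivw([])


class TestEgger:
    def test_exact_line_recovers_intercept_and_slope(self):
        bx = np.array([0.05, 0.1, 0.2, 0.3])
        by = 0.01 + 0.5 * bx
        pairs = make_pairs(bx, [0.01] * 4, by, [0.02] * 4)
        slope, intercept = egger(pairs)
        assert slope.beta == pytest.approx(0.5, abs=1e-12)
        assert intercept.beta == pytest.approx(0.01, abs=1e-12)

    def test_matches_normal_equations_oracle(self, eight_pairs):
        bx = np.array([p.beta_exp for p in eight_pairs])
        by = np.array([p.beta_out for p in eight_pairs])
        sy = np.array([p.se_out for p in eight_pairs])
        sign = np.where(bx < 0, -1, 1)
        bx, by = bx * sign, by * sign
        W = np.diag(1 / sy**2)
        X = np.column_stack([np.ones_like(bx), bx])
        coef = np.linalg.solve(X.T @ W @ X, X.T @ W @ by)
        resid = by - X @ coef
        q = float(resid @ W @ resid)
        cov = np.linalg.inv(X.T @ W @ X) * max(1.0, q / (len(bx) - 2))
        slope, intercept = egger(eight_pairs)
        assert intercept.beta == pytest.approx(coef[0], abs=1e-10)
        assert slope.beta == pytest.approx(coef[1], abs=1e-10)
        assert intercept.se == pytest.approx(np.sqrt(cov[0, 0]), abs=1e-10)
        assert slope.se == pytest.approx(np.sqrt(cov[1, 1]), abs=1e-10)

    def test_directional_pleiotropy_intercept_recovery(self):
        """InSIDE holding, all-invalid instruments with mean direct effect 0.02."""
        intercepts = []
        for seed in range(40):
            pairs, _ = simulate_instruments(
                SimConfig(
                    n_snp=200, true_beta=0.1, exposure_effect_sd=0.2,
                    invalid_fraction=1.0, pleiotropy_mean=0.02, pleiotropy_sd=0.005,
                    seed=seed,
                )
            )
            intercepts.append(egger(pairs)[1].beta)
        mean = np.mean(intercepts)
        mc_se = np.std(intercepts, ddof=1) / np.sqrt(len(intercepts))
        assert mean == pytest.approx(0.02, abs=4 * mc_se + 1e-4)

    def test_too_few_instruments_errors(self):
        pairs = make_pairs([0.1, 0.2], [0.01] * 2, [0.05, 0.1], [0.02] * 2)
        with pytest.raises(EstimatorError, match="J >= 3"):
            egger(pairs)

    def test_collinear_exposure_effects_error(self):
        pairs = make_pairs([0.1] * 4, [0.01] * 4, [0.05] * 4, [0.02] * 4)
        with pytest.raises(EstimatorError, match="variance"):
            egger(pairs)


class TestI2Gx:
    def test_tiny_se_drives_value_to_one(self):
        pairs = make_pairs([0.1, 0.2, 0.3], [1e-6] * 3, [0.0] * 3, [0.01] * 3)
        assert i2_gx(pairs).value > 0.999

    def test_identical_exposure_effects_give_zero_and_flag(self):
        pairs = make_pairs([0.1] * 3, [0.01] * 3, [0.0] * 3, [0.01] * 3)
        res = i2_gx(pairs)
        assert res.value == 0.0
        assert res.needs_correction

    def test_j1_errors(self):
        with pytest.raises(EstimatorError):
            i2_gx(make_pairs([0.1], [0.01], [0.0], [0.01]))


def median_oracle(ratios, weights):
    """Brute-force scan of the cumulative weight for the interpolated median."""
    order = np.argsort(ratios)
    r = np.asarray(ratios, float)[order]
    w = np.asarray(weights, float)[order]
    w = w / w.sum()
    cum = 0.0
    centers = []
    for wi in w:
        centers.append(cum + wi / 2)
        cum += wi
    centers = np.array(centers)
    if 0.5 <= centers[0]:
        return r[0]
    if 0.5 >= centers[-1]:
        return r[-1]
    k = int(np.searchsorted(centers, 0.5)) - 1
    frac = (0.5 - centers[k]) / (centers[k + 1] - centers[k])
    return r[k] + frac * (r[k + 1] - r[k])


class TestWeightedMedian:
    def test_equal_weights_is_plain_interpolated_median(self):
        pairs = make_pairs([0.1] * 3, [0.01] * 3, [0.01, 0.02, 0.09], [0.01] * 3)
        est = weighted_median(pairs, n_boot=0)
        assert est.beta == pytest.approx(0.2)

    def test_majority_valid_weight_recovers_truth(self):
        # 3 instruments at ratio 0.2 hold 60% of weight, 2 outliers at 5.0
        bx = np.array([0.1] * 5)
        by = np.array([0.02, 0.02, 0.02, 0.5, 0.5])
        sy = np.array([0.01, 0.01, 0.01, 0.0111, 0.0112])
        pairs = make_pairs(bx, [0.005] * 5, by, sy)
        est = weighted_median(pairs, n_boot=0)
        assert est.beta == pytest.approx(0.2, abs=0.05)

    def test_matches_brute_force_oracle_on_unequal_weights(self):
        rng = np.random.default_rng(8)
        bx = rng.uniform(0.05, 0.3, 7)
        sy = rng.uniform(0.005, 0.05, 7)
        by = rng.normal(0.3 * bx, 0.02)
        pairs = make_pairs(bx, [0.01] * 7, by, sy)
        ratios = by / bx
        weights = bx**2 / sy**2
        est = weighted_median(pairs, n_boot=0)
        assert est.beta == pytest.approx(median_oracle(ratios, weights), abs=1e-12)

    def test_bootstrap_se_is_seed_reproducible(self, eight_pairs):
        a = weighted_median(eight_pairs, n_boot=200, seed=5)
        b = weighted_median(eight_pairs, n_boot=200, seed=5)
        assert a.se == b.se and a.se > 0

    def test_requires_seed_for_bootstrap(self, eight_pairs):
        with pytest.raises(EstimatorError, match="seed"):
            weighted_median(eight_pairs, n_boot=100)


class TestWeightedMode:
    def test_degenerate_density_returns_shared_ratio(self):
        bx = np.array([0.1, 0.2, 0.4])
        pairs = make_pairs(bx, [0.01] * 3, 0.3 * bx, [0.02] * 3)
        assert weighted_mode(pairs, n_boot=0).beta == pytest.approx(0.3, abs=1e-9)

    def test_majority_cluster_wins(self):
        rng = np.random.default_rng(4)
        bx = np.full(8, 0.1)
        ratios = np.array([0.2 + e for e in rng.normal(0, 0.005, 6)] + [5.0, 5.01])
        by = ratios * bx
        pairs = make_pairs(bx, [0.01] * 8, by, [0.01] * 8)
        assert weighted_mode(pairs, n_boot=0).beta == pytest.approx(0.2, abs=0.02)

    def test_matches_dense_grid_argmax_oracle(self):
        rng = np.random.default_rng(9)
        bx = rng.uniform(0.05, 0.3, 9)
        sy = rng.uniform(0.01, 0.04, 9)
        by = rng.normal(0.25 * bx, 0.03)
        pairs = make_pairs(bx, [0.01] * 9, by, sy)
        ratios = by / bx
        weights = bx**2 / sy**2
        w = weights / weights.sum()
        h = mode_bandwidth(ratios, 1.0)
        grid = np.linspace(ratios.min() - 3 * h, ratios.max() + 3 * h, 200_001)
        dens = (w[None, :] * np.exp(-0.5 * ((grid[:, None] - ratios[None, :]) / h) ** 2)).sum(1)
        oracle = grid[int(np.argmax(dens))]
        step = grid[1] - grid[0]
        est = weighted_mode(pairs, n_boot=0)
        assert est.beta == pytest.approx(oracle, abs=2 * step)

    def test_invalid_phi_errors(self, eight_pairs):
        with pytest.raises(EstimatorError, match="phi"):
            weighted_mode(eight_pairs, phi=0.0, n_boot=0)


class TestMrRaps:
    def test_reduces_to_fixed_effect_ivw_without_noise_terms(self, eight_pairs):
        # negligible exposure-side error and overdispersion off
        pairs = make_pairs(
            [p.beta_exp for p in eight_pairs],
            [1e-9] * 8,
            [p.beta_out for p in eight_pairs],
            [p.se_out for p in eight_pairs],
        )
        raps = mr_raps(pairs, overdispersion=False)
        fe = ivw(pairs, mode="fixed")
        assert raps.beta == pytest.approx(fe.beta, abs=1e-6)
        assert raps.tau2 == 0.0

    def test_too_few_instruments_errors(self):
        with pytest.raises(EstimatorError):
            mr_raps(make_pairs([0.1, 0.2], [0.01] * 2, [0.0] * 2, [0.01] * 2))


class TestEquivariance:
    @given(st.floats(min_value=0.2, max_value=5.0))
    @settings(max_examples=20)
    def test_scaling_exposure_divides_estimates(self, c):
        pairs, _ = simulate_instruments(
            SimConfig(n_snp=20, true_beta=0.1, exposure_effect_sd=0.2, seed=6)
        )
        scaled = make_pairs(
            [c * p.beta_exp for p in pairs],
            [c * p.se_exp for p in pairs],
            [p.beta_out for p in pairs],
            [p.se_out for p in pairs],
        )
        base = ivw(pairs, "fixed").beta
        assert ivw(scaled, "fixed").beta == pytest.approx(base / c, rel=1e-9)
        assert egger(scaled)[0].beta == pytest.approx(egger(pairs)[0].beta / c, rel=1e-6)
        assert weighted_median(scaled, n_boot=0).beta == pytest.approx(
            weighted_median(pairs, n_boot=0).beta / c, rel=1e-9
        )

    def test_negating_outcome_negates_estimates(self):
        pairs, _ = simulate_instruments(
            SimConfig(n_snp=20, true_beta=0.1, exposure_effect_sd=0.2, seed=7)
        )
        neg = make_pairs(
            [p.beta_exp for p in pairs], [p.se_exp for p in pairs],
            [-p.beta_out for p in pairs], [p.se_out for p in pairs],
        )
        assert ivw(neg, "fixed").beta == pytest.approx(-ivw(pairs, "fixed").beta)
        assert weighted_median(neg, n_boot=0).beta == pytest.approx(
            -weighted_median(pairs, n_boot=0).beta
        )

    def test_or_equals_exp_beta_and_ci_ordering(self, eight_pairs):
        est = ivw(eight_pairs)
        assert est.or_ == pytest.approx(np.exp(est.beta))
        assert est.ci_low < est.or_ < est.ci_high
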