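import numpy as np
import pytest
from scipy.stats import boxcox_llf, norm

from augbin import (
    NormalFit,
    PSAChangeDataset,
    SyntheticArmConfig,
    augmented_analysis,
    augmented_response_estimate,
    boxcox_transform,
    classify_responders,
    delta_method_ci,
    delta_method_se,
    fit_normal,
    generate_arm,
    select_lambda,
    to_positive_scale,
    true_response_probability,
)
from augbin.augmented_analysis import DegenerateDataError, boxcox_profile_llf


class TestPositiveScale:
    def test_ratio_algebra(self):
        ds = PSAChangeDataset(values=np.array([50.0, -40.0, 0.0]), threshold=50.0)
        ratios, r_d, direction, n_floored = to_positive_scale(ds)
        np.testing.assert_allclose(ratios, [0.5, 1.4, 1.0])
        assert r_d == pytest.approx(0.5)
        assert direction == "below"
        assert n_floored == 0

    def test_complete_response_is_floored_not_rejected(self):
        ds = PSAChangeDataset(values=np.array([100.0, 20.0, 60.0]), threshold=50.0)
        ratios, r_d, _, n_floored = to_positive_scale(ds)
        assert ratios[0] == pytest.approx(1e-4)
        assert n_floored == 1
        # flooring keeps the complete responder on the response side
        assert ratios[0] < r_d

    def test_classification_preserved_on_ratio_scale(self, small_arm):
        ratios, r_d, _, _ = to_positive_scale(small_arm)
        expected = classify_responders(small_arm).indicators
        np.testing.assert_array_equal((ratios < r_d).astype(int), expected)


class TestSelectLambda:
    def test_log_normal_data_selects_log(self):
        rng = np.random.default_rng(100)
        r = np.exp(rng.normal(0.0, 0.7, size=500))
        assert abs(select_lambda(r) - 0.0) <= 0.25

    def test_shifted_normal_data_selects_identity(self):
        rng = np.random.default_rng(101)
        r = rng.normal(20.0, 2.0, size=500)
        assert abs(select_lambda(r) - 1.0) <= 0.35

    def test_constant_input_rejected(self):
        with pytest.raises(DegenerateDataError):
            select_lambda(np.full(30, 0.7))

    def test_profile_llf_matches_scipy_pointwise(self):
        rng = np.random.default_rng(102)
        r = np.exp(rng.normal(0.0, 0.5, size=80))
        for lam in (-2.0, -0.5, 0.0, 0.5, 2.0):
            ours = boxcox_profile_llf(np.array([lam]), r)[0]
            theirs = boxcox_llf(lam, r)
            assert ours == pytest.approx(theirs, rel=1e-10)


class TestBoxCoxTransform:
    def test_identity_lambda_is_affine_shift(self):
        fit = boxcox_transform(np.array([0.5, 1.4]), 0.5, 1.0)
        np.testing.assert_allclose(fit.transformed_values, [-0.5, 0.4])
        assert fit.transformed_threshold == pytest.approx(-0.5)

    def test_zero_lambda_is_log(self):
        fit = boxcox_transform(np.array([1.0, np.e]), 1.0, 0.0)
        np.testing.assert_allclose(fit.transformed_values, [0.0, 1.0])
        assert fit.transformed_threshold == pytest.approx(0.0)

    @pytest.mark.parametrize("lam", [-2.0, -0.5, 0.0, 0.5, 2.0])
    def test_classification_equivalence_across_lambdas(self, lam, small_arm):
        ratios, r_d, _, _ = to_positive_scale(small_arm)
        fit = boxcox_transform(ratios, r_d, lam)
        before = (ratios < r_d).astype(int)
        after = (fit.transformed_values < fit.transformed_threshold).astype(int)
        np.testing.assert_array_equal(before, after)

    def test_non_positive_input_rejected(self):
        with pytest.raises(ValueError):
            boxcox_transform(np.array([0.0, 1.0]), 0.5, 1.0)


class TestFitNormal:
    def test_closed_form(self):
        fit = fit_normal(np.array([-1.0, 0.0, 1.0]))
        assert fit.mu == pytest.approx(0.0)
        assert fit.sigma == pytest.approx(np.sqrt(2.0 / 3.0))

    def test_constant_data_rejected(self):
        with pytest.raises(DegenerateDataError):
            fit_normal(np.array([5.0, 5.0, 5.0]))

    def test_too_few_values_rejected(self):
        with pytest.raises(DegenerateDataError):
            fit_normal(np.array([1.0, 2.0]))

    def test_parameter_recovery(self):
        rng = np.random.default_rng(0)
        z = rng.normal(2.0, 3.0, size=10_000)
        fit = fit_normal(z)
        se_mu = 3.0 / np.sqrt(z.size)
        se_sigma = 3.0 / np.sqrt(2 * z.size)
        assert abs(fit.mu - 2.0) <= 2 * se_mu
        assert abs(fit.sigma - 3.0) <= 2 * se_sigma


class TestResponseEstimate:
    def test_threshold_at_mean_gives_half(self):
        fit = NormalFit(mu=1.0, sigma=2.0, n=10)
        assert augmented_response_estimate(fit, 1.0, "above") == pytest.approx(0.5)
        assert augmented_response_estimate(fit, 1.0, "below") == pytest.approx(0.5)

    def test_standard_normal_quantile(self):
        fit = NormalFit(mu=0.0, sigma=1.0, n=10)
        p = augmented_response_estimate(fit, 1.6448536, "above")
        assert p == pytest.approx(0.05, abs=1e-6)

    def test_consistency_against_generator_truth(self):
        cfg = SyntheticArmConfig(
            n=10_000, mu_log=-0.6, sigma_log=0.9, threshold=50.0, seed=17
        )
        res = augmented_analysis(generate_arm(cfg))
        truth = true_response_probability(cfg)
        mc_se = np.sqrt(truth * (1 - truth) / cfg.n)
        assert abs(res.p_hat - truth) <= 2 * mc_se


class TestDeltaMethod:
    def test_closed_form_at_u_zero(self):
        fit = NormalFit(mu=0.0, sigma=1.0, n=100)
        assert delta_method_se(fit, 0.0) == pytest.approx(norm.pdf(0) / 10, abs=1e-9)

    def test_se_matches_numerical_delta_method(self):
        """Cross-check against numerical differentiation of p(μ, σ) combined
        with the numerical Fisher information of the normal likelihood."""
        mu, sigma, n, d = 0.4, 1.3, 250, 1.1
        fit = NormalFit(mu=mu, sigma=sigma, n=n)
        p = lambda m, s: norm.cdf((d - m) / s)
        eps = 1e-6
        dp_dmu = (p(mu + eps, sigma) - p(mu - eps, sigma)) / (2 * eps)
        dp_dsigma = (p(mu, sigma + eps) - p(mu, sigma - eps)) / (2 * eps)
        # numerical Fisher information of N(mu, sigma^2) per observation
        ll = lambda m, s, x: -0.5 * np.log(2 * np.pi * s**2) - (x - m) ** 2 / (2 * s**2)
        rng = np.random.default_rng(104)
        x = rng.normal(mu, sigma, 400_000)
        h = 1e-4
        d2_mu = (ll(mu + h, sigma, x) - 2 * ll(mu, sigma, x) + ll(mu - h, sigma, x)) / h**2
        d2_sig = (ll(mu, sigma + h, x) - 2 * ll(mu, sigma, x) + ll(mu, sigma - h, x)) / h**2
        var_mu = -1 / (n * d2_mu.mean())
        var_sigma = -1 / (n * d2_sig.mean())
        se_num = np.sqrt(dp_dmu**2 * var_mu + dp_dsigma**2 * var_sigma)
        assert delta_method_se(fit, d) == pytest.approx(se_num, rel=0.02)

    def test_se_agrees_with_parametric_bootstrap(self):
        rng = np.random.default_rng(12345)
        z = rng.normal(0.3, 1.2, size=50)
        fit = fit_normal(z)
        se = delta_method_se(fit, 0.0)
        boot_rng = np.random.default_rng(999)
        boot = [
            augmented_response_estimate(
                fit_normal(boot_rng.normal(fit.mu, fit.sigma, 50)), 0.0, "below"
            )
            for _ in range(2000)
        ]
        assert np.std(boot) == pytest.approx(se, rel=0.15)

    def test_upper_bound_truncated_at_one(self):
        fit = NormalFit(mu=0.0, sigma=1.0, n=5)
        lo, hi = delta_method_ci(fit, 3.0, "below")
        assert hi == 1.0

    def test_logit_scale_interval_stays_interior(self):
        fit = NormalFit(mu=0.0, sigma=1.0, n=5)
        lo, hi = delta_method_ci(fit, 3.0, "below", logit_scale=True)
        assert 0.0 < lo < hi < 1.0


class TestAugmentedAnalysis:
    def test_permutation_invariance(self, small_arm):
        rng = np.random.default_rng(6)
        shuffled = small_arm.with_values(rng.permutation(small_arm.values))
        a, b = augmented_analysis(small_arm), augmented_analysis(shuffled)
        assert a.p_hat == pytest.approx(b.p_hat)
        assert a.ci_lower == pytest.approx(b.ci_lower)
        assert a.metadata["lambda"] == b.metadata["lambda"]

    def test_metadata_records_pipeline_state(self, small_arm):
        res = augmented_analysis(small_arm)
        assert res.method == "augmented"
        assert -3.0 <= res.metadata["lambda"] <= 3.0
        assert res.metadata["scale_used"] == "ratio"
        assert res.metadata["floored_count"] == 0

    def test_raising_threshold_never_raises_estimate(self, small_arm):
        """Stricter response definitions shrink the estimated rate (fixed λ:
        the fitted normal is unchanged, only the threshold moves)."""
        ratios, _, direction, _ = to_positive_scale(small_arm)
        lam = select_lambda(ratios)
        estimates = []
        for d in (20.0, 35.0, 50.0, 65.0, 80.0):
            fit_bc = boxcox_transform(ratios, 1.0 - d / 100.0, lam)
            fit = fit_normal(fit_bc.transformed_values)
            estimates.append(
                augmented_response_estimate(fit, fit_bc.transformed_threshold, direction)
            )
        assert all(a >= b for a, b in zip(estimates, estimates[1:]))

    def test_degenerate_arm_reports_stage(self):
        ds = PSAChangeDataset(values=np.full(10, 30.0), threshold=50.0)
        with pytest.raises(DegenerateDataError, match="lambda selection"):
            augmented_analysis(ds)

    def test_too_small_arm_rejected(self):
        ds = PSAChangeDataset(values=np.array([10.0, 20.0]), threshold=50.0)
        with pytest.raises(DegenerateDataError):
            augmented_analysis(ds)
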