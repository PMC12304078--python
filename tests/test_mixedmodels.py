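import numpy as np
import pandas as pd
import patsy
import pytest
import statsmodels.api as sm
from scipy.stats import kstest

from scorpcam.mixedmodels import (
    FitError,
    ModelSpec,
    PosteriorSummary,
    fit_glmm,
    posterior_draws,
    predict_levels,
    quantile_residuals,
    r_squared,
    response_ratio,
)


def gamma_glm_data(seed=0, n=200):
    rng = np.random.default_rng(seed)
    g = rng.choice(["a", "b", "c"], n)
    eta = 0.5 + 0.7 * (g == "b") - 0.3 * (g == "c")
    y = rng.gamma(3.0, np.exp(eta) / 3.0)
    return pd.DataFrame({"y": y, "g": g})


def binomial_glm_data(seed=0, n=300):
    rng = np.random.default_rng(seed)
    g = rng.choice(["a", "b"], n)
    eta = -0.4 + 1.1 * (g == "b")
    y = rng.binomial(1, 1.0 / (1.0 + np.exp(-eta)))
    return pd.DataFrame({"y": y.astype(float), "g": g})


def mixed_gamma_data(seed=1, n_groups=24, n_per=5, sd=0.4, shape=4.0, effect=0.7):
    rng = np.random.default_rng(seed)
    gid = np.repeat(np.arange(n_groups), n_per)
    b = rng.normal(0.0, sd, n_groups)
    grp = rng.choice(["a", "b"], n_groups * n_per)
    eta = 1.0 + effect * (grp == "b") + b[gid]
    y = rng.gamma(shape, np.exp(eta) / shape)
    return pd.DataFrame({"y": y, "grp": grp, "id": gid})


class TestGlmOracleEquivalence:
    """With no random term the engine must reproduce an IRLS GLM exactly."""

    def test_gamma_log_link(self):
        df = gamma_glm_data()
        fit = fit_glmm(df, ModelSpec("y", "gamma_log", ("g",)))
        X = np.asarray(patsy.dmatrix("1 + g", df))
        oracle = sm.GLM(df["y"], X, family=sm.families.Gamma(sm.families.links.Log())).fit()
        np.testing.assert_allclose(fit.coefficients, oracle.params, atol=1e-6)

    def test_binomial_logit(self):
        df = binomial_glm_data()
        fit = fit_glmm(df, ModelSpec("y", "binomial_logit", ("g",)))
        X = np.asarray(patsy.dmatrix("1 + g", df))
        oracle = sm.GLM(df["y"], X, family=sm.families.Binomial()).fit()
        np.testing.assert_allclose(fit.coefficients, oracle.params, atol=1e-6)
        np.testing.assert_allclose(
            fit.covariance, oracle.cov_params(), rtol=0.02, atol=1e-4
        )


class TestFitValidation:
    def test_gamma_requires_positive_response(self):
        df = pd.DataFrame({"y": [1.0, -1.0, 2.0, 1.0], "g": ["a", "a", "b", "b"]})
        with pytest.raises(ValueError, match="positive"):
            fit_glmm(df, ModelSpec("y", "gamma_log", ("g",)))

    def test_binomial_requires_binary_response(self):
        df = pd.DataFrame({"y": [0.0, 0.5, 1.0, 1.0], "g": ["a", "a", "b", "b"]})
        with pytest.raises(ValueError, match="0/1"):
            fit_glmm(df, ModelSpec("y", "binomial_logit", ("g",)))

    def test_single_level_factor_rejected(self):
        df = pd.DataFrame({"y": [1.0, 2.0, 3.0], "g": ["a", "a", "a"]})
        with pytest.raises(ValueError, match="levels"):
            fit_glmm(df, ModelSpec("y", "gamma_log", ("g",)))

    def test_unknown_family_rejected(self):
        with pytest.raises(ValueError):
            ModelSpec("y", "poisson_log", ("g",))


class TestMixedFit:
    def test_recovers_known_gamma_effect_within_own_ci(self):
        df = mixed_gamma_data(seed=7, n_groups=40, n_per=5)
        fit = fit_glmm(df, ModelSpec("y", "gamma_log", ("grp",), "id"))
        est = fit.coefficients[1]
        se = np.sqrt(fit.covariance[1, 1])
        assert est - 1.96 * se < 0.7 < est + 1.96 * se
        assert 0.1 < fit.random_sd < 0.9

    def test_balanced_binomial_intercept_near_zero(self):
        rng = np.random.default_rng(3)
        n = 300
        df = pd.DataFrame(
            {"y": rng.binomial(1, 0.5, n).astype(float), "id": np.arange(n) % 50}
        )
        fit = fit_glmm(df, ModelSpec("y", "binomial_logit", (), "id"))
        assert abs(fit.coefficients[0]) < 0.2

    def test_complete_separation_handled_by_ridge(self):
        df = pd.DataFrame(
            {
                "y": [1.0] * 12 + [0.0] * 12,
                "g": ["a"] * 12 + ["b"] * 12,
                "id": list(range(6)) * 4,
            }
        )
        fit = fit_glmm(df, ModelSpec("y", "binomial_logit", ("g",), "id"))
        assert fit.penalized
        assert np.all(np.isfinite(fit.coefficients))
        assert np.all(np.isfinite(np.diag(fit.covariance)))


@pytest.fixture(scope="module")
def mixed_fit():
    return fit_glmm(mixed_gamma_data(), ModelSpec("y", "gamma_log", ("grp",), "id"))


@pytest.fixture(scope="module")
def residual_fit():
    return fit_glmm(
        mixed_gamma_data(seed=5, n_groups=30, n_per=6),
        ModelSpec("y", "gamma_log", ("grp",), "id"),
    )


class TestPosteriorDraws:
    @pytest.fixture
    def fit(self, mixed_fit):
        return mixed_fit

    def test_same_seed_reproducible(self, fit):
        d1 = posterior_draws(fit, 500, seed=42)
        d2 = posterior_draws(fit, 500, seed=42)
        np.testing.assert_array_equal(d1, d2)

    def test_zero_covariance_collapses_to_point(self, fit):
        frozen = type(fit)(**{**fit.__dict__, "covariance": np.zeros_like(fit.covariance)})
        draws = posterior_draws(frozen, 100, seed=0)
        np.testing.assert_allclose(draws, np.tile(fit.coefficients, (100, 1)))

    def test_medians_stable_across_seeds(self, fit):
        levels = pd.DataFrame({"grp": ["a", "b"]})
        med = []
        for seed in (1, 2, 3):
            draws = posterior_draws(fit, 10000, seed=seed)
            med.append([s.median for s in predict_levels(fit, draws, levels)])
        med = np.array(med)
        assert np.max(np.abs(np.log(med / med[0]))) < 0.005

    def test_non_psd_covariance_repaired(self, fit):
        bad = fit.covariance.copy()
        bad[0, 0] = -0.01
        frozen = type(fit)(**{**fit.__dict__, "covariance": bad})
        with pytest.warns(UserWarning, match="eigen"):
            draws = posterior_draws(frozen, 100, seed=0)
        assert np.all(np.isfinite(draws))


class TestPredictionsAndRatios:
    def make_point_fit(self, family, coef):
        """Intercept-only fit with zero covariance at a chosen coefficient."""
        if family == "gamma_log":
            df = pd.DataFrame({"y": [1.0, 2.0, 3.0, 2.0]})
        else:
            df = pd.DataFrame({"y": [0.0, 1.0, 0.0, 1.0]})
        fit = fit_glmm(df, ModelSpec("y", family))
        return type(fit)(
            **{
                **fit.__dict__,
                "coefficients": np.array([coef]),
                "covariance": np.zeros((1, 1)),
            }
        )

    def test_binomial_logit_zero_predicts_half(self):
        fit = self.make_point_fit("binomial_logit", 0.0)
        draws = posterior_draws(fit, 100, seed=0)
        (summary,) = predict_levels(fit, draws, pd.DataFrame(index=[0]))
        assert summary.median == pytest.approx(0.5)
        assert summary.ci_high - summary.ci_low == pytest.approx(0.0)

    def test_gamma_log_inverse_link(self):
        fit = self.make_point_fit("gamma_log", np.log(2.0))
        draws = posterior_draws(fit, 100, seed=0)
        (summary,) = predict_levels(fit, draws, pd.DataFrame(index=[0]))
        assert summary.median == pytest.approx(2.0)

    def test_identical_levels_give_unit_ratio(self):
        df = mixed_gamma_data()
        fit = fit_glmm(df, ModelSpec("y", "gamma_log", ("grp",), "id"))
        frozen = type(fit)(**{**fit.__dict__, "covariance": np.zeros_like(fit.covariance)})
        draws = posterior_draws(frozen, 100, seed=0)
        s = response_ratio(frozen, draws, pd.DataFrame({"grp": ["a"]}), pd.DataFrame({"grp": ["a"]}))
        assert s.median == pytest.approx(1.0)
        assert s.ci_low == pytest.approx(1.0) and s.ci_high == pytest.approx(1.0)
        assert not s.excludes(1.0)

    def test_ratio_recovers_simulated_effect(self):
        df = mixed_gamma_data(seed=11, n_groups=50, n_per=8, effect=np.log(0.8))
        fit = fit_glmm(df, ModelSpec("y", "gamma_log", ("grp",), "id"))
        draws = posterior_draws(fit, 10000, seed=5)
        s = response_ratio(fit, draws, pd.DataFrame({"grp": ["b"]}), pd.DataFrame({"grp": ["a"]}))
        assert 0.7 < s.median < 0.9
        assert s.excludes(1.0) == (not s.ci_low <= 1.0 <= s.ci_high)

    def test_unseen_level_rejected(self):
        fit = fit_glmm(mixed_gamma_data(), ModelSpec("y", "gamma_log", ("grp",), "id"))
        draws = posterior_draws(fit, 50, seed=0)
        with pytest.raises(ValueError, match="level"):
            predict_levels(fit, draws, pd.DataFrame({"grp": ["z"]}))


class TestRSquared:
    def test_no_random_term_marginal_equals_conditional(self):
        fit = fit_glmm(gamma_glm_data(), ModelSpec("y", "gamma_log", ("g",)))
        marg, cond = r_squared(fit)
        assert marg == pytest.approx(cond)

    def test_null_model_marginal_zero(self):
        df = mixed_gamma_data()
        fit = fit_glmm(df, ModelSpec("y", "gamma_log", (), "id"))
        marg, cond = r_squared(fit)
        assert marg == pytest.approx(0.0, abs=1e-12)
        assert cond > 0

    def test_marginal_grows_with_effect_size(self):
        r2 = []
        for effect in (0.0, 1.0, 2.5):
            rng = np.random.default_rng(17)
            g = rng.choice(["a", "b"], 400)
            y = rng.binomial(1, 1 / (1 + np.exp(-effect * (g == "b")))).astype(float)
            df = pd.DataFrame({"y": y, "g": g})
            fit = fit_glmm(df, ModelSpec("y", "binomial_logit", ("g",)))
            r2.append(r_squared(fit)[0])
        assert r2[0] < r2[1] < r2[2]


class TestQuantileResiduals:
    @pytest.fixture
    def fit(self, residual_fit):
        return residual_fit

    def test_small_n_sim_rejected(self, fit):
        with pytest.raises(ValueError):
            quantile_residuals(fit, n_sim=10, seed=0)

    def test_same_seed_reproducible(self, fit):
        np.testing.assert_array_equal(
            quantile_residuals(fit, n_sim=50, seed=9),
            quantile_residuals(fit, n_sim=50, seed=9),
        )

    def test_extreme_observation_near_one(self, fit):
        df = pd.DataFrame({"y": np.full(fit.n_obs, 1e6), "grp": "a", "id": 0})
        u = quantile_residuals(fit, data=df, n_sim=100, seed=0)
        assert np.all(u > 0.98)

    def test_uniform_under_correct_model(self, fit):
        u = quantile_residuals(fit, n_sim=300, seed=21)
        assert kstest(u, "uniform").pvalue > 0.01
        assert np.all((u > 0) & (u < 1))
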