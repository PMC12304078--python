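"""Gamma and binomial GLMMs with one random intercept, fitted by maximum
likelihood with adaptive Gauss-Hermite quadrature, plus posterior simulation.

This is the statistical engine behind every analysis stage. All models share
one shape: a categorical fixed-effect design (with interactions), a log or
logit link, and a single random intercept grouping factor (photo ID or fish
ID). The marginal likelihood integrates the random intercept out with an
adaptive Gauss-Hermite rule (15 nodes, recentred at each group's posterior
mode and rescaled by its curvature); with one node this reduces to the
Laplace approximation, and with the random term absent the likelihood is an
ordinary GLM's.

Inference mirrors common mixed-model practice in ecology:

* fixed-effect uncertainty via the Wald covariance (inverse observed
  information at the optimum);
* predictions and contrasts as medians and 95% compatibility intervals over
  multivariate-normal "posterior" draws of the fixed effects (10,000 by
  default); random-effect uncertainty is not propagated;
* marginal / conditional R^2 in the Nakagawa-Schielzeth latent-scale form
  (logit residual variance pi^2/3; Gamma log-link trigamma(shape));
* randomised quantile residuals by simulating from the fitted model,
  uniform on (0, 1) when the model is well specified.

Complete separation in binomial fits (some cell entirely successes or
failures) is detected and handled with a weak Gaussian ridge on the
coefficients (variance 25 on the logit scale) so estimates and intervals
stay finite.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
import patsy
from scipy import optimize, special
from scipy.special import expit, gammaln, logsumexp

__all__ = [
    "ModelSpec",
    "ModelFit",
    "PosteriorSummary",
    "FitError",
    "fit_glmm",
    "posterior_draws",
    "predict_levels",
    "response_ratio",
    "r_squared",
    "quantile_residuals",
    "simulate_response",
]

_N_QUAD = 15
_RIDGE_VARIANCE = 25.0  # weak prior on logit scale, separation repair only
_SEPARATION_CUTOFF = 8.0


class FitError(RuntimeError):
    """Raised when a model fit does not converge."""


@dataclass(frozen=True)
class ModelSpec:
    """What to fit: response, family, fixed-effect terms, grouping factor."""

    response: str
    family: str  # "gamma_log" | "binomial_logit"
    fixed: tuple[str, ...] = ()
    random_group: str | None = None

    def __post_init__(self) -> None:
        if self.family not in {"gamma_log", "binomial_logit"}:
            raise ValueError(f"unknown family {self.family!r}")
        object.__setattr__(self, "fixed", tuple(self.fixed))

    @property
    def formula(self) -> str:
        return "1" if not self.fixed else "1 + " + " + ".join(self.fixed)


@dataclass(frozen=True)
class PosteriorSummary:
    """Median and 95% compatibility interval of one simulated quantity."""

    level: str
    median: float
    ci_low: float
    ci_high: float
    n_draws: int

    def excludes(self, value: float) -> bool:
        """True when ``value`` lies outside the compatibility interval."""
        return not (self.ci_low <= value <= self.ci_high)


@dataclass
class ModelFit:
    """A converged GLMM fit with everything needed for post-processing."""

    spec: ModelSpec
    coefficients: np.ndarray
    coef_names: list[str]
    covariance: np.ndarray
    dispersion_or_shape: float  # Gamma shape; 1 for binomial
    random_sd: float
    loglik: float
    n_obs: int
    n_groups: int
    converged: bool
    penalized: bool
    design_info: object
    X: np.ndarray = field(repr=False)
    y: np.ndarray = field(repr=False)
    group_index: np.ndarray | None = field(repr=False, default=None)

    def summary_dict(self) -> dict:
        return {
            "family": self.spec.family,
            "formula": self.spec.formula,
            "random_group": self.spec.random_group,
            "coefficients": dict(zip(self.coef_names, map(float, self.coefficients))),
            "dispersion_or_shape": float(self.dispersion_or_shape),
            "random_sd": float(self.random_sd),
            "loglik": float(self.loglik),
            "n_obs": int(self.n_obs),
            "n_groups": int(self.n_groups),
            "penalized": bool(self.penalized),
        }


# ---------------------------------------------------------------------------
# Family log-likelihoods and derivatives w.r.t. the linear predictor


def _ll_binomial(y: np.ndarray, eta: np.ndarray, k: float) -> np.ndarray:
    return y * eta - np.logaddexp(0.0, eta)


def _d1_binomial(y, eta, k):
    return y - expit(eta)


def _d2_binomial(y, eta, k):
    p = expit(eta)
    return -p * (1.0 - p)


def _ll_gamma(y: np.ndarray, eta: np.ndarray, k: float) -> np.ndarray:
    # shape k, mean exp(eta): logpdf = k log(k) - k eta + (k-1) log y - k y e^-eta - lgamma(k)
    return k * (np.log(k) - eta) + (k - 1.0) * np.log(y) - k * y * np.exp(-eta) - gammaln(k)


def _d1_gamma(y, eta, k):
    return k * (y * np.exp(-eta) - 1.0)


def _d2_gamma(y, eta, k):
    return -k * y * np.exp(-eta)


_FAMILIES = {
    "binomial_logit": (_ll_binomial, _d1_binomial, _d2_binomial),
    "gamma_log": (_ll_gamma, _d1_gamma, _d2_gamma),
}


def _invlink(family: str, eta: np.ndarray) -> np.ndarray:
    return expit(eta) if family == "binomial_logit" else np.exp(eta)


# ---------------------------------------------------------------------------
# Marginal log-likelihood


def _agq_loglik(
    y: np.ndarray,
    eta0: np.ndarray,
    gidx: np.ndarray,
    n_groups: int,
    sigma: float,
    family: str,
    shape: float,
    nodes: np.ndarray,
    log_weights: np.ndarray,
) -> float:
    """Adaptive Gauss-Hermite marginal log-likelihood over all groups."""
    ll, d1, d2 = _FAMILIES[family]
    sig2 = sigma * sigma
    b = np.zeros(n_groups)
    # inner Newton for the per-group posterior modes (vectorised over groups)
    for _ in range(100):
        eta = eta0 + b[gidx]
        grad = np.bincount(gidx, weights=d1(y, eta, shape), minlength=n_groups) - b / sig2
        curv = 1.0 / sig2 - np.bincount(gidx, weights=d2(y, eta, shape), minlength=n_groups)
        step = np.clip(grad / curv, -2.0, 2.0)
        b = b + step
        if np.max(np.abs(step)) < 1e-11:
            break
    eta = eta0 + b[gidx]
    curv = 1.0 / sig2 - np.bincount(gidx, weights=d2(y, eta, shape), minlength=n_groups)
    s = 1.0 / np.sqrt(curv)
    # evaluate the joint density at shifted/scaled nodes
    bk = b[None, :] + np.sqrt(2.0) * s[None, :] * nodes[:, None]  # (K, G)
    eta_k = eta0[None, :] + bk[:, gidx]  # (K, n)
    ll_obs = ll(y[None, :], eta_k, shape)
    ll_grp = np.stack(
        [np.bincount(gidx, weights=ll_obs[i], minlength=n_groups) for i in range(len(nodes))]
    )
    log_prior = -0.5 * (bk / sigma) ** 2 - 0.5 * np.log(2.0 * np.pi) - np.log(sigma)
    log_joint = ll_grp + log_prior + log_weights[:, None] + nodes[:, None] ** 2
    log_int = logsumexp(log_joint, axis=0) + 0.5 * np.log(2.0) + np.log(s)
    return float(np.sum(log_int))


def _make_nll(y, X, gidx, n_groups, family, has_random, ridge):
    ll_fn = _FAMILIES[family][0]
    nodes, weights = np.polynomial.hermite.hermgauss(_N_QUAD)
    log_weights = np.log(weights)
    p = X.shape[1]
    # the ridge prior lives on the linear-predictor (cell-logit) scale: one
    # Gaussian per distinct design row, so separated cells shrink directly
    cells = np.unique(X, axis=0) if ridge is not None else None

    def nll(params: np.ndarray) -> float:
        beta = params[:p]
        shape = np.exp(params[p]) if family == "gamma_log" else 1.0
        eta0 = X @ beta
        if has_random:
            sigma = np.exp(params[-1])
            total = _agq_loglik(
                y, eta0, gidx, n_groups, sigma, family, shape, nodes, log_weights
            )
        else:
            total = float(np.sum(ll_fn(y, eta0, shape)))
        if ridge is not None:
            total -= float(np.sum((cells @ beta) ** 2)) / (2.0 * ridge)
        return -total

    return nll


def _irls_start(y: np.ndarray, X: np.ndarray, family: str) -> np.ndarray:
    """Crude iteratively-reweighted start values for the fixed effects."""
    n, p = X.shape
    if family == "binomial_logit":
        mu = np.clip(y, 0.02, 0.98) * 0.0 + np.clip(np.mean(y), 0.05, 0.95)
        beta = np.zeros(p)
        beta[0] = np.log(mu[0] / (1 - mu[0]))
        for _ in range(25):
            eta = X @ beta
            m = expit(eta)
            w = np.clip(m * (1 - m), 1e-6, None)
            z = eta + (y - m) / w
            beta_new, *_ = np.linalg.lstsq(X * w[:, None] ** 0.5, z * w**0.5, rcond=None)
            if np.max(np.abs(beta_new - beta)) < 1e-8:
                beta = beta_new
                break
            beta = np.clip(beta_new, -15.0, 15.0)
        return beta
    # gamma log link: OLS on log responses is consistent for the mean structure
    beta, *_ = np.linalg.lstsq(X, np.log(y), rcond=None)
    return beta


def _numeric_hessian(f, x: np.ndarray, rel_step: float = 1e-4) -> np.ndarray:
    """Central-difference Hessian (small parameter vectors only)."""
    d = len(x)
    h = rel_step * np.maximum(1.0, np.abs(x))
    H = np.empty((d, d))
    for i in range(d):
        for j in range(i, d):
            ei = np.zeros(d)
            ej = np.zeros(d)
            ei[i] = h[i]
            ej[j] = h[j]
            fpp = f(x + ei + ej)
            fpm = f(x + ei - ej)
            fmp = f(x - ei + ej)
            fmm = f(x - ei - ej)
            H[i, j] = H[j, i] = (fpp - fpm - fmp + fmm) / (4.0 * h[i] * h[j])
    return H


def _build_design(data: pd.DataFrame, spec: ModelSpec, design_info=None):
    if design_info is not None:
        (mat,) = patsy.build_design_matrices([design_info], data)
    else:
        mat = patsy.dmatrix(spec.formula, data)
    return np.asarray(mat), mat.design_info


def fit_glmm(data: pd.DataFrame, spec: ModelSpec, *, ridge: float | None = None) -> ModelFit:
    """Fit a Gamma(log) or binomial(logit) mixed model by maximum likelihood.

    Parameters
    ----------
    data:
        Long-format table containing the response, fixed-effect factor
        columns and (if any) the grouping column.
    spec:
        Model description. With ``random_group=None`` the fit is an ordinary
        GLM (same likelihood, no integral).
    ridge:
        Gaussian prior variance on the coefficients. Normally ``None``;
        binomial fits that show complete separation are automatically
        refitted with variance 25.

    Raises
    ------
    FitError
        If the optimiser does not converge (diagnostics in the message).
    """
    y = np.asarray(data[spec.response], dtype=float)
    if spec.family == "gamma_log" and np.any(y <= 0):
        raise ValueError("Gamma response must be strictly positive")
    if spec.family == "binomial_logit" and not np.all(np.isin(y, (0.0, 1.0))):
        raise ValueError("binomial response must be 0/1")
    X, design_info = _build_design(data, spec)
    for term in spec.fixed:
        if ":" in term or "*" in term:
            continue
        if data[term].nunique() < 2:
            raise ValueError(f"fixed factor {term!r} has fewer than 2 observed levels")

    has_random = spec.random_group is not None
    if has_random:
        codes, levels = pd.factorize(data[spec.random_group])
        gidx = codes.astype(np.intp)
        n_groups = len(levels)
    else:
        gidx, n_groups = None, 0

    nll = _make_nll(y, X, gidx, n_groups, spec.family, has_random, ridge)
    p = X.shape[1]
    x0 = list(_irls_start(y, X, spec.family))
    bounds: list[tuple[float | None, float | None]] = [(None, None)] * p
    if spec.family == "gamma_log":
        resid = np.log(y) - X @ np.asarray(x0)
        v = max(float(np.var(resid)), 1e-3)
        x0.append(float(np.clip(np.log(1.0 / v), -3.0, 6.0)))
        bounds.append((-4.0, 10.0))
    if has_random:
        x0.append(np.log(0.3))
        bounds.append((-8.0, 3.0))
    x0 = np.asarray(x0, dtype=float)

    res = optimize.minimize(
        nll,
        x0,
        method="L-BFGS-B",
        bounds=bounds,
        options={"maxiter": 500, "ftol": 1e-11, "gtol": 1e-7, "maxfun": 20000},
    )
    grad_ok = res.jac is not None and np.max(np.abs(res.jac)) < 5e-3
    if not (res.success or grad_ok):
        raise FitError(
            f"GLMM fit did not converge: {res.message} "
            f"(nit={res.nit}, |grad|max={np.max(np.abs(res.jac)):.3g})"
        )

    # separation repair for binomial fits
    if spec.family == "binomial_logit" and ridge is None:
        if np.max(np.abs(res.x[:p])) > _SEPARATION_CUTOFF:
            return fit_glmm(data, spec, ridge=_RIDGE_VARIANCE)

    beta = res.x[:p]
    shape = float(np.exp(res.x[p])) if spec.family == "gamma_log" else 1.0
    sigma = float(np.exp(res.x[-1])) if has_random else 0.0
    if has_random and res.x[-1] <= bounds[-1][0] + 1e-6:
        sigma = 0.0  # boundary: random variance estimated at zero

    H = _numeric_hessian(nll, res.x)
    Hb = H[:p, :p]
    try:
        cov = np.linalg.inv(H)[:p, :p]
        if not np.all(np.isfinite(cov)) or np.any(np.diag(cov) <= 0):
            raise np.linalg.LinAlgError
    except np.linalg.LinAlgError:
        cov = np.linalg.pinv(Hb)
        warnings.warn("observed information was singular; using pseudo-inverse Wald covariance")
    cov = 0.5 * (cov + cov.T)

    return ModelFit(
        spec=spec,
        coefficients=beta,
        coef_names=list(design_info.column_names),
        covariance=cov,
        dispersion_or_shape=shape,
        random_sd=sigma,
        loglik=float(-res.fun),
        n_obs=len(y),
        n_groups=n_groups,
        converged=True,
        penalized=ridge is not None,
        design_info=design_info,
        X=X,
        y=y,
        group_index=gidx,
    )


# ---------------------------------------------------------------------------
# Posterior simulation and summaries


def posterior_draws(fit: ModelFit, n: int = 10000, seed: int | None = None) -> np.ndarray:
    """Multivariate-normal draws of the fixed effects (n_draws x n_coef).

    Non-positive-definite covariances are repaired by clipping negative
    eigenvalues to zero (with a warning) before sampling.
    """
    cov = fit.covariance
    w, v = np.linalg.eigh(cov)
    if np.any(w < -1e-10 * max(1.0, w.max())):
        warnings.warn("covariance not positive semi-definite; clipping negative eigenvalues")
    w = np.clip(w, 0.0, None)
    root = v * np.sqrt(w)
    rng = np.random.default_rng(seed)
    z = rng.standard_normal((n, len(fit.coefficients)))
    return fit.coefficients + z @ root.T


def _level_design(fit: ModelFit, levels: pd.DataFrame) -> np.ndarray:
    try:
        (mat,) = patsy.build_design_matrices([fit.design_info], levels)
    except Exception as exc:  # patsy raises its own error type for unseen levels
        raise ValueError(f"level not in the fitted design: {exc}") from exc
    return np.asarray(mat)


def _level_label(row: pd.Series) -> str:
    return ", ".join(f"{k}={v}" for k, v in row.items())


def predict_levels(
    fit: ModelFit,
    draws: np.ndarray,
    levels: pd.DataFrame,
) -> list[PosteriorSummary]:
    """Median and 95% CI of the response-scale prediction per factor level.

    ``levels`` holds one row per factor combination (columns named like the
    model's factors). Each prediction is the inverse link of the linear
    predictor across the posterior draws.
    """
    Xnew = _level_design(fit, levels)
    eta = Xnew @ draws.T  # (n_levels, n_draws)
    pred = _invlink(fit.spec.family, eta)
    lo, med, hi = np.percentile(pred, [2.5, 50.0, 97.5], axis=1)
    return [
        PosteriorSummary(_level_label(levels.iloc[i]), float(med[i]), float(lo[i]), float(hi[i]), draws.shape[0])
        for i in range(len(levels))
    ]


def response_ratio(
    fit: ModelFit,
    draws: np.ndarray,
    level_a: pd.DataFrame,
    level_b: pd.DataFrame,
) -> PosteriorSummary:
    """Ratio of response-scale predictions a/b with its 95% CI.

    For the log link this is ``exp(linpred_a - linpred_b)`` per draw. A CI
    excluding one flags a credible difference (``summary.excludes(1.0)``).
    """
    Xa = _level_design(fit, level_a)
    Xb = _level_design(fit, level_b)
    if fit.spec.family == "gamma_log":
        ratio = np.exp((Xa - Xb) @ draws.T)[0]
    else:
        eta_a, eta_b = Xa @ draws.T, Xb @ draws.T
        ratio = (_invlink(fit.spec.family, eta_a) / _invlink(fit.spec.family, eta_b))[0]
    lo, med, hi = np.percentile(ratio, [2.5, 50.0, 97.5])
    label = f"({_level_label(level_a.iloc[0])}) / ({_level_label(level_b.iloc[0])})"
    return PosteriorSummary(label, float(med), float(lo), float(hi), draws.shape[0])


def r_squared(fit: ModelFit) -> tuple[float, float]:
    """Marginal and conditional R^2 on the latent scale.

    ``marginal = var_f / (var_f + var_r + var_e)`` and ``conditional =
    (var_f + var_r) / (...)`` where var_f is the variance of the fixed-effect
    linear predictor, var_r the random-intercept variance, and var_e the
    family-specific latent residual variance (logit: pi^2/3; Gamma log link:
    trigamma of the shape).
    """
    var_fixed = float(np.var(fit.X @ fit.coefficients))
    var_random = fit.random_sd**2
    if fit.spec.family == "binomial_logit":
        var_resid = np.pi**2 / 3.0
    else:
        var_resid = float(special.polygamma(1, fit.dispersion_or_shape))
    denom = var_fixed + var_random + var_resid
    return var_fixed / denom, (var_fixed + var_random) / denom


def simulate_response(
    fit: ModelFit,
    rng: np.random.Generator,
    *,
    n_sim: int = 1,
) -> np.ndarray:
    """Simulate ``n_sim`` response vectors from the fitted model.

    Fresh random intercepts are drawn per simulation (unconditional
    simulation, as used for quantile residuals).
    """
    eta0 = fit.X @ fit.coefficients
    out = np.empty((n_sim, fit.n_obs))
    for s in range(n_sim):
        eta = eta0.copy()
        if fit.group_index is not None and fit.random_sd > 0:
            b = rng.normal(0.0, fit.random_sd, fit.n_groups)
            eta = eta + b[fit.group_index]
        mu = _invlink(fit.spec.family, eta)
        if fit.spec.family == "binomial_logit":
            out[s] = rng.binomial(1, mu)
        else:
            k = fit.dispersion_or_shape
            out[s] = rng.gamma(k, mu / k)
    return out


def quantile_residuals(
    fit: ModelFit,
    data: pd.DataFrame | None = None,
    n_sim: int = 250,
    seed: int | None = None,
) -> np.ndarray:
    """Randomised quantile residuals, Uniform(0,1) under a correct model.

    Each observation's residual is its rank position among ``n_sim``
    simulated responses from the fitted model, with ties broken by uniform
    jitter: ``u_i = (#{sims < y_i} + U * (#{sims == y_i} + 1)) / (n_sim + 1)``.
    """
    if n_sim < 20:
        raise ValueError("n_sim must be >= 20 for usable residual resolution")
    if data is not None:
        y = np.asarray(data[fit.spec.response], dtype=float)
        if len(y) != fit.n_obs:
            raise ValueError("data does not match the fitted model's observations")
    else:
        y = fit.y
    rng = np.random.default_rng(seed)
    sims = simulate_response(fit, rng, n_sim=n_sim)
    less = np.sum(sims < y[None, :], axis=0)
    equal = np.sum(sims == y[None, :], axis=0)
    u = rng.uniform(size=fit.n_obs)
    return (less + u * (equal + 1)) / (n_sim + 1.0)
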