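"""Exact log-densities for the three mixed models.

These are pure functions of (parameters, data arrays, subject effects):
the outcome likelihood conditional on effects, the Bernoulli-logistic
missingness likelihood, the random-effects density, and their sum — the
unnormalized joint used by the sampler.  The variance-share decomposition
of the shared-parameter structure also lives here.
"""

from __future__ import annotations

import numpy as np
from scipy.special import expit

from .data import ModelArrays
from .params import MELSParams, RILMParams, SPMELSParams, SubjectEffects

__all__ = [
    "ws_variance",
    "missingness_prob",
    "conditional_moments",
    "pointwise_loglik_y",
    "loglik_y",
    "loglik_missing",
    "effects_log_density",
    "joint_log_density",
    "variance_share",
]

_LOG2PI = float(np.log(2.0 * np.pi))


def _scalar_effect(effects_row, name: str) -> float:
    """Pull a scalar effect out of a SubjectEffects row or plain namespace."""
    val = getattr(effects_row, name)
    arr = np.asarray(val, dtype=float)
    if arr.size != 1:
        raise ValueError(f"effects_row.{name} must be a scalar (one subject)")
    return float(arr.reshape(()))


def ws_variance(params, x_row=None, effects_row=None) -> float:
    """Within-subject variance for one occasion.

    RILM: ``exp(alpha0)`` regardless of covariates/effects.
    MELS: ``exp(alpha0 + x'alpha + v1)``.
    SPMELS: ``exp(alpha0 + x'alpha + eta1 + delta*lam)``.
    """
    if isinstance(params, RILMParams):
        return float(np.exp(params.alpha0))
    x = np.zeros(params.alpha.size) if x_row is None else np.asarray(x_row, dtype=float)
    if x.size != params.alpha.size:
        raise ValueError(
            f"covariate length {x.size} != alpha length {params.alpha.size}"
        )
    lp = params.alpha0 + float(x @ params.alpha)
    if isinstance(params, MELSParams):
        lp += _scalar_effect(effects_row, "v1")
    elif isinstance(params, SPMELSParams):
        lp += _scalar_effect(effects_row, "eta1") + params.delta * _scalar_effect(
            effects_row, "lam"
        )
    else:
        raise TypeError(f"unsupported params type {type(params)!r}")
    return float(np.exp(lp))


def missingness_prob(tau0: float, tau, t_row, lam_i: float) -> float:
    """P(m = 1) under the random-intercept logistic missingness model."""
    tau = np.atleast_1d(np.asarray(tau, dtype=float))
    t_row = np.atleast_1d(np.asarray(t_row, dtype=float)) if tau.size else np.empty(0)
    if t_row.size != tau.size:
        raise ValueError(f"covariate length {t_row.size} != tau length {tau.size}")
    return float(expit(tau0 + float(t_row @ tau) + lam_i))


# ---------------------------------------------------------------------------
# vectorized linear predictors


def _conditional_mean(params, arrays: ModelArrays, effects: SubjectEffects):
    s = arrays.subject
    mu = params.beta0 + (arrays.X_loc @ params.beta if params.beta.size else 0.0)
    if isinstance(params, SPMELSParams):
        mu = mu + effects.eta0[s] + params.gamma * effects.lam[s]
    else:
        mu = mu + effects.v0[s]
    return np.broadcast_to(np.asarray(mu, dtype=float), s.shape)


def _log_ws_variance(params, arrays: ModelArrays, effects: SubjectEffects):
    s = arrays.subject
    if isinstance(params, RILMParams):
        return np.full(s.shape, params.alpha0)
    lv = params.alpha0 + (
        arrays.X_scale @ params.alpha if params.alpha.size else 0.0
    )
    if isinstance(params, SPMELSParams):
        lv = lv + effects.eta1[s] + params.delta * effects.lam[s]
    else:
        lv = lv + effects.v1[s]
    return np.broadcast_to(np.asarray(lv, dtype=float), s.shape)


def conditional_moments(params, arrays: ModelArrays, effects: SubjectEffects):
    """Conditional mean and log WS variance for every scheduled row."""
    mu = _conditional_mean(params, arrays, effects)
    lv = _log_ws_variance(params, arrays, effects)
    return mu, lv


def pointwise_loglik_y(params, arrays: ModelArrays, effects: SubjectEffects):
    """Per-row conditional log-density of the outcome at observed rows."""
    obs = arrays.observed
    mu = _conditional_mean(params, arrays, effects)[obs]
    lv = _log_ws_variance(params, arrays, effects)[obs]
    r2 = (arrays.y[obs] - mu) ** 2
    return -0.5 * (_LOG2PI + lv + r2 * np.exp(-lv))


def loglik_y(params, arrays: ModelArrays, effects: SubjectEffects) -> float:
    """Sum over observed rows of the conditional normal log-density."""
    obs = arrays.observed
    y = arrays.y[obs]
    if not np.isfinite(y).all():
        raise ValueError("non-finite outcome among observed rows")
    mu = _conditional_mean(params, arrays, effects)[obs]
    lv = _log_ws_variance(params, arrays, effects)[obs]
    r2 = (y - mu) ** 2
    return float(-0.5 * np.sum(_LOG2PI + lv + r2 * np.exp(-lv)))


def loglik_missing(params: SPMELSParams, arrays: ModelArrays, effects) -> float:
    """Bernoulli log-likelihood of m over ALL scheduled occasions."""
    m = arrays.m
    if not np.isin(m, [0.0, 1.0]).all():
        raise ValueError("m values must be 0/1")
    s = arrays.subject
    c = params.tau0 + (arrays.T @ params.tau if params.tau.size else 0.0) + effects.lam[s]
    # log Bernoulli(m | logistic(c)) = m*c - log(1 + e^c), computed stably
    return float(np.sum(m * c - np.logaddexp(0.0, c)))


def effects_log_density(params, effects: SubjectEffects) -> float:
    """Log-density of the subject random effects under the model's prior."""
    if isinstance(params, RILMParams):
        v = effects.v0
        return float(
            -0.5 * np.sum(_LOG2PI + 2 * np.log(params.sigma_v0) + (v / params.sigma_v0) ** 2)
        )
    if isinstance(params, MELSParams):
        return _bivariate_normal_logpdf(
            effects.v0, effects.v1, params.sigma_v0, params.sigma_v1, params.rho_v0v1
        )
    if isinstance(params, SPMELSParams):
        out = _bivariate_normal_logpdf(
            effects.eta0,
            effects.eta1,
            params.sigma_eta0,
            params.sigma_eta1,
            params.rho_eta0eta1,
        )
        sl = params.sigma_lambda
        out += float(
            -0.5 * np.sum(_LOG2PI + 2 * np.log(sl) + (effects.lam / sl) ** 2)
        )
        return out
    raise TypeError(f"unsupported params type {type(params)!r}")


def _bivariate_normal_logpdf(a, b, sa, sb, rho) -> float:
    za, zb = a / sa, b / sb
    q = (za**2 - 2 * rho * za * zb + zb**2) / (1 - rho**2)
    n = np.asarray(a).size
    return float(
        -0.5 * np.sum(q)
        - n * (_LOG2PI + np.log(sa) + np.log(sb) + 0.5 * np.log1p(-(rho**2)))
    )


def joint_log_density(params, arrays: ModelArrays, effects: SubjectEffects) -> float:
    """Unnormalized conditional-on-effects joint log-density.

    Outcome likelihood + (SPMELS) missingness likelihood + random-effects
    density.  This is the quantity the sampler targets, up to log-priors.
    """
    out = loglik_y(params, arrays, effects) + effects_log_density(params, effects)
    if isinstance(params, SPMELSParams):
        out += loglik_missing(params, arrays, effects)
    return out


def variance_share(loading: float, sigma_lambda: float, sigma_resid: float) -> float:
    """Fraction of a composite random effect's variance due to missingness.

    Under the shared-parameter decomposition the composite effect is
    ``loading * lam + eta`` with independent components, so the share is
    ``(loading*sigma_lambda)^2 / ((loading*sigma_lambda)^2 + sigma_resid^2)``.
    """
    if not sigma_lambda > 0:
        raise ValueError("sigma_lambda must be positive")
    if sigma_resid < 0:
        raise ValueError("sigma_resid must be nonnegative")
    num = (loading * sigma_lambda) ** 2
    den = num + sigma_resid**2
    if den == 0:
        raise ValueError("variance share undefined: both components are zero")
    return float(num / den)
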