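"""Unconstrained log-posteriors with analytic gradients for the sampler.

Each posterior maps an unconstrained vector ``z`` to the log joint
density (outcome likelihood + missingness likelihood where applicable +
random-effects density + priors + transform Jacobians) and its gradient.
Parameterization choices:

* SDs sampled on the log scale (half-normal prior on the SD itself);
* correlations via ``rho = tanh(u)`` with a uniform(-1, 1) prior;
* subject effects non-centered: ``eta = L(sigma, rho) @ z_std`` with
  standard-normal ``z_std``, which removes the funnel between SDs and
  effects in the hierarchical posterior;
* the log WS-variance linear predictor is clipped to [-30, 30] inside the
  sampler (gradient zeroed where clipped) to prevent overflow during
  warmup; the public density functions are unclipped.

Priors (reconstructed; widths configurable): normal(0, coef_scale) on all
regression/loading coefficients, half-normal(sd_scale) on SDs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import expit

from .data import ModelArrays
from .params import MELSParams, RILMParams, SPMELSParams, SubjectEffects

__all__ = ["PriorConfig", "build_posterior"]

_LOG2PI = float(np.log(2.0 * np.pi))
_CLIP = 30.0


@dataclass
class PriorConfig:
    coef_scale: float = 5.0
    sd_scale: float = 3.0


def build_posterior(kind: str, arrays: ModelArrays, prior: PriorConfig | None = None):
    prior = prior or PriorConfig()
    kind = kind.lower()
    if kind == "rilm":
        return RILMPosterior(arrays, prior)
    if kind == "mels":
        return MELSPosterior(arrays, prior)
    if kind == "spmels":
        return SPMELSPosterior(arrays, prior)
    raise ValueError(f"unknown model kind {kind!r}")


class _BasePosterior:
    """Shared precomputation over observed rows and subject sums."""

    def __init__(self, arrays: ModelArrays, prior: PriorConfig):
        self.arrays = arrays
        self.prior = prior
        obs = arrays.observed
        self.N = arrays.n_subjects
        self.y_o = arrays.y[obs]
        self.X_o = arrays.X_loc[obs]
        self.Xs_o = arrays.X_scale[obs]
        self.s_o = arrays.subject[obs]
        self.s_all = arrays.subject
        self.n_obs = int(obs.sum())
        if self.n_obs == 0:
            raise ValueError("no observed outcomes: cannot fit")
        self.p = arrays.X_loc.shape[1]
        self.ps = arrays.X_scale.shape[1]

    def _sum_by_subject(self, values, s):
        return np.bincount(s, weights=values, minlength=self.N)

    def _ols_init(self):
        X1 = np.column_stack([np.ones(self.n_obs), self.X_o])
        coef, *_ = np.linalg.lstsq(X1, self.y_o, rcond=None)
        resid = self.y_o - X1 @ coef
        var = max(float(np.var(resid)), 1e-6)
        return coef, var

    def initial(self, rng) -> np.ndarray:
        z = 0.01 * rng.standard_normal(self.dim)
        coef, var = self._ols_init()
        z[0] = coef[0]
        z[1 : 1 + self.p] = coef[1:]
        z[1 + self.p] = np.log(0.75 * var)  # alpha0; rest of var goes to v0
        return z


class RILMPosterior(_BasePosterior):
    """Unconstrained z = [beta0, beta(p), alpha0, log s0, z0(N)]."""

    kind = "rilm"

    def __init__(self, arrays, prior):
        super().__init__(arrays, prior)
        self.dim = 1 + self.p + 1 + 1 + self.N
        self._i_a0 = 1 + self.p
        self._i_l0 = self._i_a0 + 1
        self._i_z0 = self._i_l0 + 1

    def logp_grad(self, z):
        p, N = self.p, self.N
        beta0 = z[0]
        beta = z[1 : 1 + p]
        alpha0 = float(np.clip(z[self._i_a0], -_CLIP, _CLIP))
        a_unclipped = z[self._i_a0]
        l0 = z[self._i_l0]
        z0 = z[self._i_z0 :]
        s0 = np.exp(np.clip(l0, -_CLIP, _CLIP))
        v0 = s0 * z0

        mu = beta0 + (self.X_o @ beta if p else 0.0) + v0[self.s_o]
        r = self.y_o - mu
        w = np.exp(-alpha0)
        logp = -0.5 * np.sum(_LOG2PI + alpha0 + r * r * w)
        dmu = r * w
        a_mask = float(abs(a_unclipped) < _CLIP)
        g_alpha0 = -0.5 * np.sum(1.0 - r * r * w) * a_mask

        Gm = self._sum_by_subject(dmu, self.s_o)
        cs2 = self.prior.coef_scale**2
        ws2 = self.prior.sd_scale**2

        logp += -0.5 * np.sum(z0 * z0)
        logp += -(beta0**2 + np.sum(beta**2) + a_unclipped**2) / (2 * cs2)
        logp += -(s0**2) / (2 * ws2) + l0

        grad = np.empty_like(z)
        grad[0] = np.sum(dmu) - beta0 / cs2
        grad[1 : 1 + p] = (self.X_o.T @ dmu if p else np.empty(0)) - beta / cs2
        grad[self._i_a0] = g_alpha0 - a_unclipped / cs2
        grad[self._i_l0] = np.sum(v0 * Gm) + 1.0 - s0**2 / ws2
        grad[self._i_z0 :] = s0 * Gm - z0
        return float(logp), grad

    def unpack(self, z):
        p = self.p
        s0 = float(np.exp(z[self._i_l0]))
        params = RILMParams(
            beta0=float(z[0]),
            beta=z[1 : 1 + p].copy(),
            alpha0=float(z[self._i_a0]),
            sigma_v0=s0,
        )
        effects = SubjectEffects(v0=s0 * z[self._i_z0 :])
        return params, effects

    def param_names(self):
        return (
            ["beta0"]
            + [f"beta[{n}]" for n in self.arrays.loc_names]
            + ["alpha0", "sigma_v0"]
        )

    def scalar_values(self, params):
        return np.concatenate(
            [[params.beta0], params.beta, [params.alpha0, params.sigma_v0]]
        )


class MELSPosterior(_BasePosterior):
    """z = [beta0, beta(p), alpha0, alpha(ps), l0, l1, u, z0(N), z1(N)]."""

    kind = "mels"

    def __init__(self, arrays, prior):
        super().__init__(arrays, prior)
        p, ps, N = self.p, self.ps, self.N
        self._i_a0 = 1 + p
        self._i_al = self._i_a0 + 1
        self._i_l0 = self._i_al + ps
        self._i_l1 = self._i_l0 + 1
        self._i_u = self._i_l1 + 1
        self._i_z0 = self._i_u + 1
        self._i_z1 = self._i_z0 + N
        self.dim = self._i_z1 + N

    def logp_grad(self, z):
        p, ps, N = self.p, self.ps, self.N
        beta0 = z[0]
        beta = z[1 : 1 + p]
        alpha0 = z[self._i_a0]
        alphav = z[self._i_al : self._i_al + ps]
        l0, l1, u = z[self._i_l0], z[self._i_l1], z[self._i_u]
        z0 = z[self._i_z0 : self._i_z0 + N]
        z1 = z[self._i_z1 :]
        s0 = np.exp(np.clip(l0, -_CLIP, _CLIP))
        s1 = np.exp(np.clip(l1, -_CLIP, _CLIP))
        rho = np.tanh(u)
        qq = np.sqrt(max(1.0 - rho * rho, 1e-24))
        v0 = s0 * z0
        v1 = s1 * (rho * z0 + qq * z1)

        mu = beta0 + (self.X_o @ beta if p else 0.0) + v0[self.s_o]
        a = alpha0 + (self.Xs_o @ alphav if ps else 0.0) + v1[self.s_o]
        a_mask = (np.abs(a) < _CLIP).astype(float)
        a = np.clip(a, -_CLIP, _CLIP)
        r = self.y_o - mu
        w = np.exp(-a)
        logp = -0.5 * np.sum(_LOG2PI + a + r * r * w)
        dmu = r * w
        da = -0.5 * (1.0 - r * r * w) * a_mask

        Gm = self._sum_by_subject(dmu, self.s_o)
        Ga = self._sum_by_subject(da, self.s_o)

        cs2 = self.prior.coef_scale**2
        ws2 = self.prior.sd_scale**2
        logp += -0.5 * np.sum(z0 * z0) - 0.5 * np.sum(z1 * z1)
        logp += -(
            beta0**2 + np.sum(beta**2) + alpha0**2 + np.sum(alphav**2)
        ) / (2 * cs2)
        logp += -(s0**2 + s1**2) / (2 * ws2) + l0 + l1
        logp += np.log1p(-(rho * rho))  # tanh Jacobian; uniform prior on rho

        grad = np.empty_like(z)
        grad[0] = np.sum(dmu) - beta0 / cs2
        grad[1 : 1 + p] = (self.X_o.T @ dmu if p else np.empty(0)) - beta / cs2
        grad[self._i_a0] = np.sum(da) - alpha0 / cs2
        grad[self._i_al : self._i_al + ps] = (
            self.Xs_o.T @ da if ps else np.empty(0)
        ) - alphav / cs2
        grad[self._i_l0] = np.sum(v0 * Gm) + 1.0 - s0**2 / ws2
        grad[self._i_l1] = np.sum(v1 * Ga) + 1.0 - s1**2 / ws2
        grad[self._i_u] = (1.0 - rho * rho) * s1 * np.sum(
            Ga * (z0 - rho / qq * z1)
        ) - 2.0 * rho
        grad[self._i_z0 : self._i_z0 + N] = s0 * Gm + s1 * rho * Ga - z0
        grad[self._i_z1 :] = s1 * qq * Ga - z1
        return float(logp), grad

    def unpack(self, z):
        p, ps, N = self.p, self.ps, self.N
        s0 = float(np.exp(z[self._i_l0]))
        s1 = float(np.exp(z[self._i_l1]))
        rho = float(np.tanh(z[self._i_u]))
        z0 = z[self._i_z0 : self._i_z0 + N]
        z1 = z[self._i_z1 :]
        params = MELSParams(
            beta0=float(z[0]),
            beta=z[1 : 1 + p].copy(),
            alpha0=float(z[self._i_a0]),
            alpha=z[self._i_al : self._i_al + ps].copy(),
            sigma_v0=s0,
            sigma_v1=s1,
            rho_v0v1=rho,
        )
        effects = SubjectEffects(
            v0=s0 * z0, v1=s1 * (rho * z0 + np.sqrt(1 - rho**2) * z1)
        )
        return params, effects

    def param_names(self):
        return (
            ["beta0"]
            + [f"beta[{n}]" for n in self.arrays.loc_names]
            + ["alpha0"]
            + [f"alpha[{n}]" for n in self.arrays.scale_names]
            + ["sigma_v0", "sigma_v1", "rho_v0v1"]
        )

    def scalar_values(self, params):
        return np.concatenate(
            [
                [params.beta0],
                params.beta,
                [params.alpha0],
                params.alpha,
                [params.sigma_v0, params.sigma_v1, params.rho_v0v1],
            ]
        )


class SPMELSPosterior(_BasePosterior):
    """z = [beta0, beta, alpha0, alpha, tau0, tau, gamma, delta,
    l0, l1, u, llam, z0(N), z1(N), zl(N)]."""

    kind = "spmels"

    def __init__(self, arrays, prior):
        super().__init__(arrays, prior)
        if arrays.m is None:
            raise ValueError("SPMELS requires a missingness indicator")
        p, ps, N = self.p, self.ps, self.N
        self.q = arrays.T.shape[1]
        q = self.q
        self.T_all = arrays.T
        self.m_all = arrays.m
        self._i_a0 = 1 + p
        self._i_al = self._i_a0 + 1
        self._i_t0 = self._i_al + ps
        self._i_tau = self._i_t0 + 1
        self._i_g = self._i_tau + q
        self._i_d = self._i_g + 1
        self._i_l0 = self._i_d + 1
        self._i_l1 = self._i_l0 + 1
        self._i_u = self._i_l1 + 1
        self._i_ll = self._i_u + 1
        self._i_z0 = self._i_ll + 1
        self._i_z1 = self._i_z0 + N
        self._i_zl = self._i_z1 + N
        self.dim = self._i_zl + N

    def initial(self, rng) -> np.ndarray:
        z = super().initial(rng)
        mbar = float(np.clip(np.mean(self.m_all), 1e-3, 1 - 1e-3))
        z[self._i_t0] = np.log(mbar / (1 - mbar))
        return z

    def logp_grad(self, z):
        p, ps, q, N = self.p, self.ps, self.q, self.N
        beta0 = z[0]
        beta = z[1 : 1 + p]
        alpha0 = z[self._i_a0]
        alphav = z[self._i_al : self._i_al + ps]
        tau0 = z[self._i_t0]
        tau = z[self._i_tau : self._i_tau + q]
        gamma, delta = z[self._i_g], z[self._i_d]
        l0, l1, u, llam = z[self._i_l0], z[self._i_l1], z[self._i_u], z[self._i_ll]
        z0 = z[self._i_z0 : self._i_z0 + N]
        z1 = z[self._i_z1 : self._i_z1 + N]
        zl = z[self._i_zl :]
        s0 = np.exp(np.clip(l0, -_CLIP, _CLIP))
        s1 = np.exp(np.clip(l1, -_CLIP, _CLIP))
        sl = np.exp(np.clip(llam, -_CLIP, _CLIP))
        rho = np.tanh(u)
        qq = np.sqrt(max(1.0 - rho * rho, 1e-24))
        eta0 = s0 * z0
        eta1 = s1 * (rho * z0 + qq * z1)
        lam = sl * zl

        # outcome likelihood over observed rows
        mu = (
            beta0
            + (self.X_o @ beta if p else 0.0)
            + eta0[self.s_o]
            + gamma * lam[self.s_o]
        )
        a = (
            alpha0
            + (self.Xs_o @ alphav if ps else 0.0)
            + eta1[self.s_o]
            + delta * lam[self.s_o]
        )
        a_mask = (np.abs(a) < _CLIP).astype(float)
        a = np.clip(a, -_CLIP, _CLIP)
        r = self.y_o - mu
        w = np.exp(-a)
        logp = -0.5 * np.sum(_LOG2PI + a + r * r * w)
        dmu = r * w
        da = -0.5 * (1.0 - r * r * w) * a_mask

        # missingness likelihood over all scheduled rows
        c = tau0 + (self.T_all @ tau if q else 0.0) + lam[self.s_all]
        logp += np.sum(self.m_all * c - np.logaddexp(0.0, c))
        dc = self.m_all - expit(c)

        Gm = self._sum_by_subject(dmu, self.s_o)
        Ga = self._sum_by_subject(da, self.s_o)
        Gc = self._sum_by_subject(dc, self.s_all)
        glam = gamma * Gm + delta * Ga + Gc

        cs2 = self.prior.coef_scale**2
        ws2 = self.prior.sd_scale**2
        logp += -0.5 * (np.sum(z0 * z0) + np.sum(z1 * z1) + np.sum(zl * zl))
        logp += -(
            beta0**2
            + np.sum(beta**2)
            + alpha0**2
            + np.sum(alphav**2)
            + tau0**2
            + np.sum(tau**2)
            + gamma**2
            + delta**2
        ) / (2 * cs2)
        logp += -(s0**2 + s1**2 + sl**2) / (2 * ws2) + l0 + l1 + llam
        logp += np.log1p(-(rho * rho))

        grad = np.empty_like(z)
        grad[0] = np.sum(dmu) - beta0 / cs2
        grad[1 : 1 + p] = (self.X_o.T @ dmu if p else np.empty(0)) - beta / cs2
        grad[self._i_a0] = np.sum(da) - alpha0 / cs2
        grad[self._i_al : self._i_al + ps] = (
            self.Xs_o.T @ da if ps else np.empty(0)
        ) - alphav / cs2
        grad[self._i_t0] = np.sum(dc) - tau0 / cs2
        grad[self._i_tau : self._i_tau + q] = (
            self.T_all.T @ dc if q else np.empty(0)
        ) - tau / cs2
        grad[self._i_g] = np.sum(lam * Gm) - gamma / cs2
        grad[self._i_d] = np.sum(lam * Ga) - delta / cs2
        grad[self._i_l0] = np.sum(eta0 * Gm) + 1.0 - s0**2 / ws2
        grad[self._i_l1] = np.sum(eta1 * Ga) + 1.0 - s1**2 / ws2
        grad[self._i_ll] = np.sum(lam * glam) + 1.0 - sl**2 / ws2
        grad[self._i_u] = (1.0 - rho * rho) * s1 * np.sum(
            Ga * (z0 - rho / qq * z1)
        ) - 2.0 * rho
        grad[self._i_z0 : self._i_z0 + N] = s0 * Gm + s1 * rho * Ga - z0
        grad[self._i_z1 : self._i_z1 + N] = s1 * qq * Ga - z1
        grad[self._i_zl :] = sl * glam - zl
        return float(logp), grad

    def unpack(self, z):
        p, ps, q, N = self.p, self.ps, self.q, self.N
        s0 = float(np.exp(z[self._i_l0]))
        s1 = float(np.exp(z[self._i_l1]))
        sl = float(np.exp(z[self._i_ll]))
        rho = float(np.tanh(z[self._i_u]))
        z0 = z[self._i_z0 : self._i_z0 + N]
        z1 = z[self._i_z1 : self._i_z1 + N]
        zl = z[self._i_zl :]
        params = SPMELSParams(
            beta0=float(z[0]),
            beta=z[1 : 1 + p].copy(),
            alpha0=float(z[self._i_a0]),
            alpha=z[self._i_al : self._i_al + ps].copy(),
            tau0=float(z[self._i_t0]),
            tau=z[self._i_tau : self._i_tau + q].copy(),
            gamma=float(z[self._i_g]),
            delta=float(z[self._i_d]),
            sigma_eta0=s0,
            sigma_eta1=s1,
            rho_eta0eta1=rho,
            sigma_lambda=sl,
        )
        eta0 = s0 * z0
        eta1 = s1 * (rho * z0 + np.sqrt(1 - rho**2) * z1)
        effects = SubjectEffects.from_shared(
            params.gamma, params.delta, sl * zl, eta0, eta1
        )
        return params, effects

    def param_names(self):
        return (
            ["beta0"]
            + [f"beta[{n}]" for n in self.arrays.loc_names]
            + ["alpha0"]
            + [f"alpha[{n}]" for n in self.arrays.scale_names]
            + ["tau0"]
            + [f"tau[{n}]" for n in self.arrays.miss_names]
            + [
                "gamma",
                "delta",
                "sigma_eta0",
                "sigma_eta1",
                "rho_eta0eta1",
                "sigma_lambda",
            ]
        )

    def scalar_values(self, params):
        return np.concatenate(
            [
                [params.beta0],
                params.beta,
                [params.alpha0],
                params.alpha,
                [params.tau0],
                params.tau,
                [
                    params.gamma,
                    params.delta,
                    params.sigma_eta0,
                    params.sigma_eta1,
                    params.rho_eta0eta1,
                    params.sigma_lambda,
                ],
            ]
        )
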