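"""Model and Results classes for the three mixed models.

The surface follows the statsmodels convention: a model object is built
from data plus a column specification, ``fit()`` returns a results object
carrying estimates, uncertainties, convergence diagnostics and a
``summary()`` table, and Step-1 posterior draws for the two-step
imputation hang off the results via ``draw_step1``.

Example
-------
>>> model = SPMELS(data, response="y", loc_covariates=["x1", "x2"],
...                missing="m", missing_covariates=["day", "beep1", "beep6"])
>>> res = model.fit(seed=1, mcmc=MCMCConfig(chains=2, warmup=500, draws=500))
>>> res.summary()
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import arviz as az
import numpy as np
import pandas as pd
from scipy.optimize import minimize
from statsmodels.tools import numdiff

from .data import EMADataset, ModelArrays
from .densities import pointwise_loglik_y
from .nuts import nuts_sample
from .params import RILMParams, SubjectEffects
from .posteriors import PriorConfig, build_posterior

logger = logging.getLogger("melsimpute")

__all__ = [
    "MCMCConfig",
    "RILM",
    "MELS",
    "SPMELS",
    "MCMCResults",
    "RILMMLResults",
]


@dataclass
class MCMCConfig:
    chains: int = 4
    warmup: int = 1000
    draws: int = 1000
    target_accept: float = 0.8
    max_depth: int = 10
    rhat_threshold: float = 1.05
    prior: PriorConfig = field(default_factory=PriorConfig)


class _BaseModel:
    kind: str = ""

    def __init__(
        self,
        data,
        response: str = "y",
        loc_covariates=("x1", "x2"),
        scale_covariates=None,
        missing: str | None = None,
        missing_covariates=(),
    ):
        if isinstance(data, EMADataset):
            self.data = data
        else:
            self.data = EMADataset(data, validate=False)
        self.response = response
        self.arrays = ModelArrays.build(
            self.data,
            response=response,
            loc_covariates=loc_covariates,
            scale_covariates=scale_covariates,
            missing=missing,
            missing_covariates=missing_covariates,
        )
        counts = np.bincount(
            self.arrays.subject[self.arrays.observed],
            minlength=self.arrays.n_subjects,
        )
        if (counts > 0).sum() < 2:
            raise ValueError("need at least 2 subjects with observed outcomes")

    def _fit_mcmc(self, mcmc: MCMCConfig, seed) -> "MCMCResults":
        posterior = build_posterior(self.kind, self.arrays, mcmc.prior)
        seq = np.random.SeedSequence(seed)
        chain_seeds = seq.spawn(mcmc.chains)
        z_chains, logp_chains = [], []
        n_div = 0
        for c in range(mcmc.chains):
            rng = np.random.default_rng(chain_seeds[c])
            z0 = posterior.initial(rng)
            draws, stats = nuts_sample(
                posterior.logp_grad,
                z0,
                n_warmup=mcmc.warmup,
                n_draws=mcmc.draws,
                seed=chain_seeds[c].spawn(1)[0],
                target_accept=mcmc.target_accept,
                max_depth=mcmc.max_depth,
            )
            z_chains.append(draws)
            logp_chains.append(stats.logp)
            n_div += stats.n_divergent
        z = np.stack(z_chains)  # (chains, draws, dim)
        return MCMCResults(
            model=self,
            posterior=posterior,
            z=z,
            logp=np.stack(logp_chains),
            config=mcmc,
            n_divergent=n_div,
        )


class RILM(_BaseModel):
    """Random-intercept linear mixed model."""

    kind = "rilm"

    def fit(self, method: str = "ml", mcmc: MCMCConfig | None = None, seed=0):
        if method == "ml":
            return _fit_rilm_ml(self)
        if method == "nuts":
            return self._fit_mcmc(mcmc or MCMCConfig(), seed)
        raise ValueError(f"unknown method {method!r}")


class MELS(_BaseModel):
    """Mixed-effects location-scale model (NUTS-fitted)."""

    kind = "mels"

    def fit(self, mcmc: MCMCConfig | None = None, seed=0, method: str = "nuts"):
        if method != "nuts":
            raise ValueError("MELS is fitted by MCMC (marginal ML is out of scope)")
        return self._fit_mcmc(mcmc or MCMCConfig(), seed)


class SPMELS(_BaseModel):
    """Shared-parameter MELS with the logistic missingness submodel."""

    kind = "spmels"

    def __init__(
        self,
        data,
        response: str = "y",
        loc_covariates=("x1", "x2"),
        scale_covariates=None,
        missing: str = "m",
        missing_covariates=("day", "beep1", "beep6"),
    ):
        super().__init__(
            data,
            response=response,
            loc_covariates=loc_covariates,
            scale_covariates=scale_covariates,
            missing=missing,
            missing_covariates=missing_covariates,
        )

    def fit(self, mcmc: MCMCConfig | None = None, seed=0, method: str = "nuts"):
        if method != "nuts":
            raise ValueError("SPMELS is fitted by MCMC")
        return self._fit_mcmc(mcmc or MCMCConfig(), seed)


class MCMCResults:
    """Retained NUTS draws with summaries and Step-1 access.

    Draw-level access: ``params_at(l)`` returns the parameter container
    and subject-effect draw for flattened draw index ``l``.
    """

    def __init__(self, model, posterior, z, logp, config, n_divergent):
        self.model = model
        self.posterior = posterior
        self.z = z
        self.logp = logp
        self.config = config
        self.n_divergent = n_divergent
        self.param_names = posterior.param_names()
        chains, draws, _ = z.shape
        k = len(self.param_names)
        scal = np.empty((chains, draws, k))
        for c in range(chains):
            for d in range(draws):
                params, _ = posterior.unpack(z[c, d])
                scal[c, d] = posterior.scalar_values(params)
        self.scalars = scal
        self._rhat = None

    # -- diagnostics -----------------------------------------------------
    @property
    def n_draws(self) -> int:
        return self.z.shape[0] * self.z.shape[1]

    def rhat(self) -> pd.Series:
        if self._rhat is None:
            vals = {}
            for j, name in enumerate(self.param_names):
                arr = self.scalars[:, :, j]
                if arr.shape[0] == 1:
                    # split the single chain so Rhat remains informative
                    half = arr.shape[1] // 2
                    arr = np.stack([arr[0, :half], arr[0, half : 2 * half]])
                vals[name] = float(az.rhat(arr))
            self._rhat = pd.Series(vals)
        return self._rhat

    def ess(self) -> pd.Series:
        vals = {}
        for j, name in enumerate(self.param_names):
            vals[name] = float(az.ess(self.scalars[:, :, j]))
        return pd.Series(vals)

    @property
    def converged(self) -> bool:
        return bool(self.rhat().max() <= self.config.rhat_threshold)

    # -- summaries -------------------------------------------------------
    def summary(self) -> pd.DataFrame:
        flat = self.scalars.reshape(-1, self.scalars.shape[-1])
        rh = self.rhat()
        out = pd.DataFrame(
            {
                "mean": flat.mean(axis=0),
                "sd": flat.std(axis=0, ddof=1),
                "q2.5": np.quantile(flat, 0.025, axis=0),
                "q97.5": np.quantile(flat, 0.975, axis=0),
                "rhat": [rh[n] for n in self.param_names],
            },
            index=self.param_names,
        )
        return out

    def posterior_mean(self, name: str) -> float:
        j = self.param_names.index(name)
        return float(self.scalars[:, :, j].mean())

    def posterior_sd(self, name: str) -> float:
        j = self.param_names.index(name)
        return float(self.scalars[:, :, j].std(ddof=1))

    def ci(self, name: str, level: float = 0.95):
        j = self.param_names.index(name)
        flat = self.scalars[:, :, j].ravel()
        a = (1 - level) / 2
        return float(np.quantile(flat, a)), float(np.quantile(flat, 1 - a))

    # -- draw access -----------------------------------------------------
    def params_at(self, l: int):
        chains, draws, _ = self.z.shape
        c, d = divmod(int(l), draws)
        return self.posterior.unpack(self.z[c, d])

    def draw_step1(self, L: int, seed=0):
        """L approximately independent Step-1 draws by stratified thinning.

        Indices are evenly spaced across the chain-concatenated retained
        draws; the seed only shifts the phase, so the selection is
        deterministic.
        """
        total = self.n_draws
        if L > total:
            raise ValueError(f"L={L} exceeds {total} retained draws")
        stride = total / L
        offset = int(np.random.default_rng(seed).integers(0, max(int(stride), 1)))
        idx = (offset + np.arange(L) * stride).astype(int) % total
        return [self.params_at(i) for i in idx]

    # -- pointwise log-likelihood (for ELPD) -----------------------------
    def pointwise_loglik(self) -> np.ndarray:
        """(chains, draws, n_obs) conditional log-density at observed rows."""
        chains, draws, _ = self.z.shape
        n_obs = int(self.model.arrays.observed.sum())
        out = np.empty((chains, draws, n_obs))
        for c in range(chains):
            for d in range(draws):
                params, effects = self.posterior.unpack(self.z[c, d])
                out[c, d] = pointwise_loglik_y(params, self.model.arrays, effects)
        return out

    def to_inference_data(self, log_likelihood: bool = False) -> az.InferenceData:
        post = {
            name: self.scalars[:, :, j] for j, name in enumerate(self.param_names)
        }
        groups = {"posterior": post}
        if log_likelihood:
            groups["log_likelihood"] = {self.model.response: self.pointwise_loglik()}
        return az.from_dict(**groups)

    def save(self, draws_path, summary_path=None):
        """Plain-CSV draws plus an optional summary (JSON for .json paths)."""
        flat = self.scalars.reshape(-1, self.scalars.shape[-1])
        pd.DataFrame(flat, columns=self.param_names).to_csv(draws_path, index=False)
        if summary_path is not None:
            summary = self.summary()
            if str(summary_path).endswith(".json"):
                payload = {
                    "params": summary.to_dict(orient="index"),
                    "converged": self.converged,
                    "n_divergent": int(self.n_divergent),
                    "chains": int(self.z.shape[0]),
                    "draws_per_chain": int(self.z.shape[1]),
                }
                import json

                with open(summary_path, "w") as fh:
                    json.dump(payload, fh, indent=2)
            else:
                summary.to_csv(summary_path)


# ---------------------------------------------------------------------------
# RILM maximum likelihood


def _rilm_negloglik(theta, arrays: ModelArrays):
    """Negative marginal log-likelihood on the unconstrained scale.

    theta = (beta0, beta, alpha0, log sigma_v0); the random intercept is
    integrated out analytically per subject (compound-symmetry marginal).
    """
    p = arrays.X_loc.shape[1]
    beta0 = theta[0]
    beta = theta[1 : 1 + p]
    alpha0 = np.clip(theta[1 + p], -30, 30)
    tau2 = np.exp(2 * np.clip(theta[2 + p], -30, 30))
    s2 = np.exp(alpha0)
    obs = arrays.observed
    r = arrays.y[obs] - beta0 - (arrays.X_loc[obs] @ beta if p else 0.0)
    s = arrays.subject[obs]
    N = arrays.n_subjects
    n_i = np.bincount(s, minlength=N).astype(float)
    sum_r = np.bincount(s, weights=r, minlength=N)
    sum_r2 = np.bincount(s, weights=r * r, minlength=N)
    denom = s2 + n_i * tau2
    quad = (sum_r2 - tau2 * sum_r**2 / denom) / s2
    logdet = (n_i - 1) * alpha0 + np.log(denom)
    keep = n_i > 0
    n_obs = n_i[keep].sum()
    return 0.5 * float(
        n_obs * np.log(2 * np.pi) + logdet[keep].sum() + quad[keep].sum()
    )


def _fit_rilm_ml(model: RILM) -> "RILMMLResults":
    arrays = model.arrays
    p = arrays.X_loc.shape[1]
    post = build_posterior("rilm", arrays, PriorConfig())
    coef, var = post._ols_init()
    x0 = np.concatenate([coef, [np.log(0.75 * var)], [0.5 * np.log(0.25 * var + 1e-8)]])
    bounds = [(None, None)] * (1 + p) + [(-30, 30), (-10, 10)]
    res = minimize(
        _rilm_negloglik,
        x0,
        args=(arrays,),
        method="L-BFGS-B",
        bounds=bounds,
        options={"maxiter": 500, "ftol": 1e-12, "gtol": 1e-9},
    )
    theta = res.x
    sigma_v0_floor = bool(theta[-1] <= -10 + 1e-6)
    if sigma_v0_floor:
        logger.warning("RILM ML: estimated sigma_v0 at zero boundary")
    hess = numdiff.approx_hess(theta, _rilm_negloglik, args=(arrays,))
    try:
        cov = np.linalg.inv(hess)
        # symmetrize and clip tiny negative eigenvalues from numerical noise
        cov = 0.5 * (cov + cov.T)
        w, v = np.linalg.eigh(cov)
        cov = (v * np.clip(w, 0.0, None)) @ v.T
    except np.linalg.LinAlgError:
        logger.warning("RILM ML: singular information matrix; zero covariance")
        cov = np.zeros((theta.size, theta.size))
    return RILMMLResults(model=model, theta=theta, cov=cov, optim=res,
                         sigma_v0_floor=sigma_v0_floor)


class RILMMLResults:
    """Maximum-likelihood RILM fit with an asymptotic-normal Step-1 surrogate.

    ``theta`` lives on the unconstrained scale (beta0, beta, alpha0,
    log sigma_v0), so normal draws preserve positivity; empirical-Bayes
    conditional normals supply the subject intercepts per draw.
    """

    def __init__(self, model, theta, cov, optim, sigma_v0_floor=False):
        self.model = model
        self.theta = theta
        self.cov = cov
        self.optim = optim
        self.sigma_v0_floor = sigma_v0_floor
        self.p = model.arrays.X_loc.shape[1]
        self.param_names = (
            ["beta0"]
            + [f"beta[{n}]" for n in model.arrays.loc_names]
            + ["alpha0", "sigma_v0"]
        )

    # -- parameter access ------------------------------------------------
    def params(self, theta=None) -> RILMParams:
        t = self.theta if theta is None else theta
        return RILMParams(
            beta0=float(t[0]),
            beta=t[1 : 1 + self.p].copy(),
            alpha0=float(t[1 + self.p]),
            sigma_v0=float(np.exp(t[2 + self.p])),
        )

    def _eb_moments(self, params: RILMParams):
        """Empirical-Bayes conditional mean/var of v0 per subject."""
        arrays = self.model.arrays
        obs = arrays.observed
        r = arrays.y[obs] - params.beta0 - (
            arrays.X_loc[obs] @ params.beta if self.p else 0.0
        )
        s = arrays.subject[obs]
        N = arrays.n_subjects
        n_i = np.bincount(s, minlength=N).astype(float)
        sum_r = np.bincount(s, weights=r, minlength=N)
        s2 = np.exp(params.alpha0)
        tau2 = params.sigma_v0**2
        mean = tau2 * sum_r / (s2 + n_i * tau2)
        var = tau2 * s2 / (s2 + n_i * tau2)  # equals tau2 when n_i = 0
        return mean, var

    def eb_effects(self) -> SubjectEffects:
        mean, _ = self._eb_moments(self.params())
        return SubjectEffects(v0=mean)

    # -- summaries -------------------------------------------------------
    def se(self) -> np.ndarray:
        return np.sqrt(np.diag(self.cov))

    def summary(self) -> pd.DataFrame:
        est = np.concatenate(
            [self.theta[: 2 + self.p], [np.exp(self.theta[2 + self.p])]]
        )
        se = self.se()
        # delta method for sigma_v0 = exp(log sigma_v0)
        se_nat = np.concatenate([se[: 2 + self.p], [se[2 + self.p] * est[-1]]])
        lo, hi = zip(*(self.ci(n) for n in self.param_names))
        return pd.DataFrame(
            {"estimate": est, "se": se_nat, "q2.5": lo, "q97.5": hi},
            index=self.param_names,
        )

    def ci(self, name: str, level: float = 0.95):
        from scipy.stats import norm

        zq = norm.ppf(0.5 + level / 2)
        j = self.param_names.index(name)
        se = self.se()
        if name == "sigma_v0":
            lo = self.theta[j] - zq * se[j]
            hi = self.theta[j] + zq * se[j]
            return float(np.exp(lo)), float(np.exp(hi))
        return (
            float(self.theta[j] - zq * se[j]),
            float(self.theta[j] + zq * se[j]),
        )

    def posterior_mean(self, name: str) -> float:
        j = self.param_names.index(name)
        if name == "sigma_v0":
            return float(np.exp(self.theta[j]))
        return float(self.theta[j])

    # -- Step 1 ----------------------------------------------------------
    def draw_step1(self, L: int, seed=0):
        """Draw (theta, v0) L times from the asymptotic-normal surrogate."""
        rng = np.random.default_rng(seed)
        w, v = np.linalg.eigh(0.5 * (self.cov + self.cov.T))
        root = v * np.sqrt(np.clip(w, 0.0, None))
        out = []
        for _ in range(int(L)):
            theta = self.theta + root @ rng.standard_normal(self.theta.size)
            params = self.params(theta)
            mean, var = self._eb_moments(params)
            v0 = rng.normal(mean, np.sqrt(var))
            out.append((params, SubjectEffects(v0=v0)))
        return out
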