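"""Imputation-model checking: completed-data PPC and ELPD comparison.

The posterior predictive check uses a completed-data discrepancy: for
each posterior draw the missing outcomes are imputed, a full replicate of
the schedule is simulated from the model at the same draw (with fresh
subject effects, since the replicate integrates over the fitted
hierarchy), and the per-subject discrepancy — by default the
within-subject sample variance — is compared between replicate and
completed series.  The per-subject p-value is the proportion of draws in
which the replicate discrepancy is at least the completed one (ties count
as satisfying the inequality).

ELPD model comparison goes through PSIS-LOO (arviz) on pointwise
log-likelihoods conditional on the subject-effect draws.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import arviz as az
import numpy as np
import pandas as pd

from .densities import conditional_moments
from .models import MCMCResults, RILMMLResults
from .params import MELSParams, RILMParams, SPMELSParams, SubjectEffects

logger = logging.getLogger("melsimpute")

__all__ = [
    "ws_variance_statistic",
    "PPCResult",
    "ppc_pvalue",
    "elpd_compare",
    "elpd_insample",
    "plot_ppc",
]


def ws_variance_statistic(series) -> float:
    """Sample variance of one subject's completed series (denominator n-1)."""
    x = np.asarray(series, dtype=float)
    if x.size < 2:
        raise ValueError("within-subject variance needs at least 2 values")
    return float(np.var(x, ddof=1))


@dataclass
class PPCResult:
    subjects: np.ndarray
    p_com: np.ndarray
    Lppc: int
    discrepancy: str = "ws_variance"

    def to_frame(self, model: str = "") -> pd.DataFrame:
        return pd.DataFrame(
            {"subject": self.subjects, "model": model, "p_com": self.p_com}
        )


def _fresh_effects(params, n_subjects: int, rng) -> SubjectEffects:
    """Draw new subject effects from the fitted hierarchy at one draw."""
    if isinstance(params, RILMParams):
        return SubjectEffects(v0=rng.normal(0.0, params.sigma_v0, n_subjects))
    if isinstance(params, MELSParams):
        z = rng.standard_normal((2, n_subjects))
        v0 = params.sigma_v0 * z[0]
        v1 = params.sigma_v1 * (
            params.rho_v0v1 * z[0] + np.sqrt(1 - params.rho_v0v1**2) * z[1]
        )
        return SubjectEffects(v0=v0, v1=v1)
    if isinstance(params, SPMELSParams):
        z = rng.standard_normal((3, n_subjects))
        eta0 = params.sigma_eta0 * z[0]
        eta1 = params.sigma_eta1 * (
            params.rho_eta0eta1 * z[0] + np.sqrt(1 - params.rho_eta0eta1**2) * z[1]
        )
        lam = params.sigma_lambda * z[2]
        return SubjectEffects.from_shared(params.gamma, params.delta, lam, eta0, eta1)
    raise TypeError(f"unsupported params type {type(params)!r}")


def _subject_variances(values: np.ndarray, subject: np.ndarray, N: int):
    """Per-subject sample variance (ddof=1) via group sums."""
    n = np.bincount(subject, minlength=N).astype(float)
    s1 = np.bincount(subject, weights=values, minlength=N)
    s2 = np.bincount(subject, weights=values * values, minlength=N)
    with np.errstate(invalid="ignore", divide="ignore"):
        var = (s2 - s1 * s1 / n) / (n - 1)
    return var, n


def ppc_pvalue(fit, Lppc: int = 1000, seed: int = 0, Q: str = "ws_variance") -> PPCResult:
    """Per-subject completed-data posterior predictive p-values.

    ``fit`` is a fitted results object (NUTS draws or the RILM ML
    surrogate); its model carries the data/design.  For each of ``Lppc``
    posterior draws the missing outcomes are imputed and a full replicate
    is simulated at that draw; ``p_com`` is the per-subject proportion of
    draws with replicate discrepancy >= completed discrepancy.
    """
    if Q != "ws_variance":
        raise ValueError("only the within-subject variance discrepancy is provided")
    arrays = fit.model.arrays
    N = arrays.n_subjects
    subject = arrays.subject
    rng = np.random.default_rng(seed)
    miss = np.isnan(arrays.y)

    if isinstance(fit, MCMCResults):
        idx = rng.integers(0, fit.n_draws, size=Lppc)
        draws = (fit.params_at(i) for i in idx)
    elif isinstance(fit, RILMMLResults):
        draws = iter(fit.draw_step1(Lppc, seed=rng.integers(0, 2**31)))
    else:
        raise TypeError(f"unsupported fit type {type(fit)!r}")

    # subjects need >= 2 scheduled occasions for a variance
    n_per = np.bincount(subject, minlength=N)
    ok = n_per >= 2
    if (~ok).any():
        logger.info("PPC: excluding %d subject(s) with < 2 occasions", int((~ok).sum()))

    ge_count = np.zeros(N)
    for _ in range(Lppc):
        params, effects = next(draws)
        mu, lv = conditional_moments(params, arrays, effects)
        completed = arrays.y.copy()
        if miss.any():
            completed[miss] = rng.normal(mu[miss], np.exp(0.5 * lv[miss]))
        eff_rep = _fresh_effects(params, N, rng)
        mu_r, lv_r = conditional_moments(params, arrays, eff_rep)
        rep = rng.normal(mu_r, np.exp(0.5 * lv_r))
        q_com, _ = _subject_variances(completed, subject, N)
        q_rep, _ = _subject_variances(rep, subject, N)
        ge_count += (q_rep >= q_com) & ok

    p_com = ge_count[ok] / Lppc
    subjects = fit.model.data.subjects[ok]
    return PPCResult(subjects=subjects, p_com=p_com, Lppc=Lppc)


def elpd_compare(fits: dict) -> pd.DataFrame:
    """PSIS-LOO ELPD per model with pairwise differences.

    ``fits`` maps model names to NUTS results fitted on identical observed
    rows.  Returns one row per model (elpd_loo, se, p_loo, Pareto-k
    diagnostics) plus ``elpd_diff``/``diff_se`` relative to the best model.
    """
    masks = [f.model.arrays.observed for f in fits.values()]
    for m in masks[1:]:
        if not np.array_equal(m, masks[0]):
            raise ValueError("fits must share identical observed rows")
    idatas, loos = {}, {}
    for name, fit in fits.items():
        idatas[name] = fit.to_inference_data(log_likelihood=True)
        loos[name] = az.loo(idatas[name], pointwise=True)
    comp = az.compare(idatas, ic="loo")
    rows = []
    for name, loo in loos.items():
        k = np.asarray(loo.pareto_k)
        rows.append(
            {
                "model": name,
                "elpd_loo": float(loo.elpd_loo),
                "se": float(loo.se),
                "p_loo": float(loo.p_loo),
                "n_bad_k": int((k > 0.7).sum()),
                "elpd_diff": float(comp.loc[name, "elpd_diff"]),
                "diff_se": float(comp.loc[name, "dse"]),
            }
        )
    out = pd.DataFrame(rows).set_index("model")
    if (out["n_bad_k"] > 0).any():
        logger.warning(
            "PSIS-LOO: %d pointwise terms with Pareto k > 0.7",
            int(out["n_bad_k"].sum()),
        )
    return out.sort_values("elpd_loo", ascending=False)


def elpd_insample(fit: MCMCResults) -> float:
    """In-sample ELPD: sum over points of log mean posterior density."""
    ll = fit.pointwise_loglik().reshape(-1, int(fit.model.arrays.observed.sum()))
    from scipy.special import logsumexp

    return float(np.sum(logsumexp(ll, axis=0) - np.log(ll.shape[0])))


def plot_ppc(results: dict, ax=None):
    """Boxplot of per-subject PPC p-values, one box per model."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(5, 4))
    names = list(results)
    ax.boxplot([results[n].p_com for n in names], tick_labels=names)
    ax.axhline(0.5, color="grey", lw=0.8, ls="--")
    ax.set_ylabel("completed-data PPC p-value")
    ax.set_ylim(-0.02, 1.02)
    return ax
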