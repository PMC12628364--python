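"""Simulation-study driver: generate → fit → impute → summarize.

Replicates the repeated-measures experimental design: for each replicate
a dataset is generated under the shared-parameter process, the three
models are fitted to the outcome for bias/coverage of the generating
parameters, and the sequential two-variable imputation is run for the
configured (x1-model, y-model) pairs in single- and multiple-imputation
arms.  Summaries are the per-parameter bias and 95%-interval coverage,
mean squared imputation error per model pair, and the best/worst
difference ratio.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .data import EMADataset
from .imputation import fit_imputation_model, pool_mean, sequential_impute
from .models import MCMCConfig, MELS, RILM, SPMELS
from .simulate import GeneratedData, Scenario, calibrate_tau0, generate_dataset

logger = logging.getLogger("melsimpute")

__all__ = [
    "bias",
    "coverage",
    "imputation_error",
    "difference_ratio",
    "run_study",
    "StudyResult",
]

MODEL_ORDER = ("rilm", "mels", "spmels")


def bias(estimates, truth: float) -> float:
    """Mean deviation of the replicate estimates from the true value."""
    est = np.asarray(estimates, dtype=float)
    if est.size == 0:
        raise ValueError("no estimates")
    return float(np.mean(est - truth))


def coverage(intervals, truth: float) -> float:
    """Percentage of intervals strictly containing the truth.

    Boundary equality counts as non-coverage (strict inequalities).
    """
    intervals = list(intervals)
    if not intervals:
        raise ValueError("no intervals")
    hits = 0
    for lo, hi in intervals:
        if not lo < hi:
            raise ValueError(f"malformed interval ({lo}, {hi})")
        hits += lo < truth < hi
    return 100.0 * hits / len(intervals)


def imputation_error(completed: pd.DataFrame, truth: EMADataset, column: str = "y") -> float:
    """Mean squared imputation error over all scheduled cells.

    Observed cells contribute zero; the denominator is the total cell
    count, so the statistic is the masked squared error spread over the
    whole schedule.
    """
    true_col = f"true_{column}"
    if true_col not in truth.frame.columns:
        raise ValueError(f"truth dataset lacks {true_col!r}")
    y_true = truth.frame[true_col].to_numpy(dtype=float)
    masked = truth.frame[column].isna().to_numpy()
    if np.isnan(y_true[masked]).any():
        raise ValueError("truth missing for a masked cell")
    y_hat = completed[column].to_numpy(dtype=float)
    diff2 = np.zeros(y_true.size)
    diff2[masked] = (y_hat[masked] - y_true[masked]) ** 2
    return float(diff2.sum() / y_true.size)


def difference_ratio(errors_by_y_model: dict):
    """(best model, worst model, 100*(worst-best)/worst) over y-models.

    Ties are broken by the fixed model order (rilm, mels, spmels).
    """
    if len(errors_by_y_model) < 2:
        raise ValueError("need at least two models")
    ordered = sorted(
        errors_by_y_model,
        key=lambda k: (errors_by_y_model[k], MODEL_ORDER.index(k) if k in MODEL_ORDER else 99),
    )
    best, worst = ordered[0], ordered[-1]
    eb, ew = errors_by_y_model[best], errors_by_y_model[worst]
    if ew == 0:
        raise ValueError("all errors zero: ratio undefined")
    return best, worst, 100.0 * (ew - eb) / ew


# ---------------------------------------------------------------------------
# replicate-level machinery


def _true_values(scenario: Scenario, tau0: float) -> dict:
    """Map summary parameter names to their generating values (y block)."""
    blk = scenario.y_params
    p = scenario.spmels_params("y", tau0)
    sv0 = p.implied_sigma_v0()
    sv1 = p.implied_sigma_v1()
    rho_v = (
        blk.gamma * blk.delta * scenario.sigma_lambda**2
        + blk.rho * blk.sigma_eta0 * blk.sigma_eta1
    ) / (sv0 * sv1)
    return {
        "beta0": blk.beta0,
        "beta[x1]": blk.beta[0],
        "beta[x2]": blk.beta[1],
        "alpha0": blk.alpha0,
        "alpha[x1]": blk.alpha[0],
        "alpha[x2]": blk.alpha[1],
        "sigma_v0": sv0,
        "sigma_v1": sv1,
        "rho_v0v1": rho_v,
        "tau0": tau0,
        "tau[day]": scenario.tau[0],
        "tau[beep1]": scenario.tau[1],
        "tau[beep6]": scenario.tau[2],
        "gamma": blk.gamma,
        "delta": blk.delta,
        "sigma_eta0": blk.sigma_eta0,
        "sigma_eta1": blk.sigma_eta1,
        "rho_eta0eta1": blk.rho,
        "sigma_lambda": scenario.sigma_lambda,
    }


def _fit_estimation_model(kind, data, mcmc, seed):
    """Fit one model to the outcome with the generating covariates."""
    if kind == "rilm":
        return RILM(data, response="y", loc_covariates=("x1", "x2")).fit("ml")
    if kind == "mels":
        return MELS(data, response="y", loc_covariates=("x1", "x2")).fit(mcmc, seed=seed)
    return SPMELS(
        data,
        response="y",
        loc_covariates=("x1", "x2"),
        missing="m",
        missing_covariates=("day", "beep1", "beep6"),
    ).fit(mcmc, seed=seed)


def _estimation_records(kind, fit, replicate):
    rows = []
    for name in fit.param_names:
        lo, hi = fit.ci(name)
        rows.append(
            {
                "replicate": replicate,
                "model": kind,
                "parameter": name,
                "estimate": fit.posterior_mean(name),
                "lo": lo,
                "hi": hi,
            }
        )
    return rows


@dataclass
class StudyResult:
    """Tidy per-replicate outputs plus summary builders."""

    scenario: Scenario
    tau0: float
    estimates: pd.DataFrame  # replicate, model, parameter, estimate, lo, hi
    errors: pd.DataFrame     # replicate, x1_model, y_model, arm, error
    n_failures: int = 0
    truth: dict = field(default_factory=dict)

    def bias_table(self) -> pd.DataFrame:
        rows = []
        if self.estimates.empty:
            return pd.DataFrame(columns=["model", "parameter", "bias", "coverage"])
        for (model, param), g in self.estimates.groupby(["model", "parameter"]):
            if param not in self.truth:
                continue
            rows.append(
                {
                    "model": model,
                    "parameter": param,
                    "bias": bias(g["estimate"], self.truth[param]),
                    "coverage": coverage(zip(g["lo"], g["hi"]), self.truth[param]),
                }
            )
        return pd.DataFrame(rows)

    def error_table(self) -> pd.DataFrame:
        if self.errors.empty:
            return pd.DataFrame(columns=["x1_model", "y_model", "arm", "error"])
        return (
            self.errors.groupby(["x1_model", "y_model", "arm"], as_index=False)["error"]
            .mean()
        )

    def difference_ratios(self, arm: str = "multiple") -> pd.DataFrame:
        tab = self.error_table()
        rows = []
        for x1m, g in tab[tab["arm"] == arm].groupby("x1_model"):
            errs = dict(zip(g["y_model"], g["error"]))
            if len(errs) >= 2:
                best, worst, ratio = difference_ratio(errs)
                rows.append(
                    {
                        "x1_model": x1m,
                        "best": best,
                        "worst": worst,
                        "ratio_pct": ratio,
                    }
                )
        return pd.DataFrame(rows)

    def to_tidy(self) -> pd.DataFrame:
        """One long table: scenario-invariant metric rows."""
        bt = self.bias_table()
        out = []
        for _, r in bt.iterrows():
            out.append(("estimation", r["model"], "", r["parameter"], "bias", r["bias"]))
            out.append(
                ("estimation", r["model"], "", r["parameter"], "coverage", r["coverage"])
            )
        for _, r in self.error_table().iterrows():
            out.append(
                ("imputation", r["x1_model"], r["y_model"], r["arm"], "error", r["error"])
            )
        return pd.DataFrame(
            out, columns=["stage", "model_x1", "model_y", "detail", "metric", "value"]
        )


def run_study(
    scenario: Scenario,
    K: int = 100,
    L: int = 10,
    seed: int = 0,
    mcmc: MCMCConfig | None = None,
    x1_models=MODEL_ORDER,
    y_models=MODEL_ORDER,
    mode: str = "fast",
    estimation: bool = True,
) -> StudyResult:
    """Run K independent generate→fit→impute replicates.

    Per-replicate seeds derive deterministically from the master seed, so
    replicates are order-independent and could run concurrently.  A
    replicate whose MCMC fit misses the convergence threshold is retried
    once with a derived seed and excluded (with a log record) if it fails
    again.
    """
    if K < 1:
        raise ValueError("K must be >= 1")
    mcmc = mcmc or MCMCConfig()
    tau0 = calibrate_tau0(scenario)
    truth = _true_values(scenario, tau0)
    rep_seeds = np.random.SeedSequence(seed).spawn(K)

    est_rows, err_rows = [], []
    n_failures = 0
    for k in range(K):
        states = rep_seeds[k].generate_state(8) % 2**31
        gen = generate_dataset(scenario, seed=int(states[0]), tau0=tau0)
        try:
            est_rows_k, err_rows_k = _run_replicate(
                gen, k, states, mcmc, x1_models, y_models, L, mode, estimation
            )
        except Exception as exc:  # noqa: BLE001 - failures are recorded, not raised
            logger.warning("replicate %d failed and was excluded: %s", k, exc)
            n_failures += 1
            continue
        est_rows.extend(est_rows_k)
        err_rows.extend(err_rows_k)

    return StudyResult(
        scenario=scenario,
        tau0=tau0,
        estimates=pd.DataFrame(est_rows),
        errors=pd.DataFrame(err_rows),
        n_failures=n_failures,
        truth=truth,
    )


def _run_replicate(gen: GeneratedData, k, states, mcmc, x1_models, y_models, L, mode, estimation):
    est_rows, err_rows = [], []
    data = gen.data

    if estimation:
        for j, kind in enumerate(MODEL_ORDER):
            fit = _fit_estimation_model(kind, data, mcmc, seed=int(states[1]) + j)
            if kind != "rilm" and not fit.converged:
                logger.info("replicate %d %s estimation retry", k, kind)
                fit = _fit_estimation_model(kind, data, mcmc, seed=int(states[2]) + j)
                if not fit.converged:
                    raise RuntimeError(f"{kind} estimation did not converge")
            est_rows.extend(_estimation_records(kind, fit, k))

    for ix, x1_kind in enumerate(x1_models):
        x1_fit = fit_imputation_model(
            x1_kind,
            data,
            "x1",
            ("x2", "day", "beep1", "beep6"),
            mcmc=mcmc,
            seed=int(states[3]) + ix,
        )
        for iy, y_kind in enumerate(y_models):
            imps = sequential_impute(
                data,
                {"x1": x1_kind, "y": y_kind},
                L=L,
                seed=int(states[4]) + 10 * ix + iy,
                mode=mode,
                mcmc=mcmc,
                x1_fit=x1_fit,
            )
            pooled = pool_mean(imps)
            err_multi = imputation_error(pooled, data)
            err_single = imputation_error(imps.frames[0], data)
            err_rows.append(
                {
                    "replicate": k,
                    "x1_model": x1_kind,
                    "y_model": y_kind,
                    "arm": "multiple",
                    "error": err_multi,
                }
            )
            err_rows.append(
                {
                    "replicate": k,
                    "x1_model": x1_kind,
                    "y_model": y_kind,
                    "arm": "single",
                    "error": err_single,
                }
            )
    return est_rows, err_rows
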