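"""Step 2 of the two-step procedure: drawing the missing values.

For each Step-1 draw (parameters + subject effects) the missing cells of
a target variable are sampled from their conditional normal distribution
under the fitted model; observed cells are never touched.  The sequential
scheme imputes the time-varying covariate first and the outcome second,
carrying the pairing of draws by copy index, as required when two
variables are missing together.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .data import EMADataset, ModelArrays
from .densities import conditional_moments
from .models import MCMCConfig, MELS, RILM, SPMELS

logger = logging.getLogger("melsimpute")

__all__ = [
    "ImputationSet",
    "fit_imputation_model",
    "impute_variable",
    "sequential_impute",
    "pool_mean",
    "rubin_pool",
]

DEFAULT_MISS_COVARIATES = ("day", "beep1", "beep6")


@dataclass
class ImputationSet:
    """L completed copies of a dataset.

    ``frames`` hold full completed copies; ``targets`` lists the imputed
    columns (no missing values remain there, observed cells are identical
    across copies).
    """

    frames: list
    targets: list
    mode: str
    provenance: dict = field(default_factory=dict)

    @property
    def L(self) -> int:
        return len(self.frames)

    def validate(self) -> None:
        if not self.frames:
            raise ValueError("empty imputation set")
        for col in self.targets:
            for f in self.frames:
                if f[col].isna().any():
                    raise ValueError(f"imputed column {col!r} still has missing cells")

    def column_stack(self, col: str) -> np.ndarray:
        """(L, n) stack of one completed column."""
        return np.stack([f[col].to_numpy(dtype=float) for f in self.frames])


def fit_imputation_model(
    kind: str,
    data: EMADataset,
    response: str,
    covariates,
    mcmc: MCMCConfig | None = None,
    seed=0,
    missing_covariates=DEFAULT_MISS_COVARIATES,
):
    """Fit one of the three models for use as an imputation model.

    RILM is fitted by maximum likelihood (its Step-1 surrogate is the
    asymptotic normal); MELS and SPMELS by NUTS.
    """
    kind = kind.lower()
    if kind == "rilm":
        return RILM(data, response=response, loc_covariates=covariates).fit("ml")
    if kind == "mels":
        return MELS(data, response=response, loc_covariates=covariates).fit(
            mcmc or MCMCConfig(), seed=seed
        )
    if kind == "spmels":
        return SPMELS(
            data,
            response=response,
            loc_covariates=covariates,
            missing="m",
            missing_covariates=missing_covariates,
        ).fit(mcmc or MCMCConfig(), seed=seed)
    raise ValueError(f"unknown model kind {kind!r}")


def _draw_completed_column(params, effects, arrays: ModelArrays, rng) -> np.ndarray:
    """One completed copy of the response column of ``arrays``."""
    y = arrays.y.copy()
    miss = np.isnan(y)
    if not miss.any():
        return y
    if arrays.X_loc.size and np.isnan(arrays.X_loc[miss]).any():
        raise ValueError(
            "covariates missing at rows to impute; impute them first "
            "(sequential_impute)"
        )
    mu, lv = conditional_moments(params, arrays, effects)
    y[miss] = rng.normal(mu[miss], np.exp(0.5 * lv[miss]))
    return y


def impute_variable(
    data: EMADataset, step1_draws, model, target: str, seed=0
) -> ImputationSet:
    """Impute one variable once per Step-1 draw.

    ``model`` is the fitted model's *model* object (it carries the design
    arrays aligned with ``data``); ``step1_draws`` the list of
    (params, effects) pairs from ``draw_step1``.
    """
    arrays = model.arrays
    rng = np.random.default_rng(seed)
    frames = []
    for params, effects in step1_draws:
        col = _draw_completed_column(params, effects, arrays, rng)
        f = data.frame.copy()
        f[target] = col
        frames.append(f)
    out = ImputationSet(
        frames=frames,
        targets=[target],
        mode="multiple" if len(frames) > 1 else "single",
        provenance={"model_kind": model.kind, "target": target, "seed": seed},
    )
    out.validate()
    return out


def sequential_impute(
    data: EMADataset,
    models: dict,
    L: int = 10,
    seed=0,
    mode: str = "proper",
    mcmc: MCMCConfig | None = None,
    covariates: dict | None = None,
    x1_fit=None,
) -> ImputationSet:
    """Impute x1 then y, pairing draws by copy index.

    Parameters
    ----------
    models : dict
        ``{"x1": kind, "y": kind}`` with kinds in {rilm, mels, spmels}.
    mode : {"proper", "fast"}
        proper — refit the y model on each completed-x1 copy (one Step-1
        draw per refit); fast — fit the y model once on copy 1 and reuse
        its L Step-1 draws across copies.
    x1_fit : optional
        A pre-fitted x1-model results object to reuse across y-model arms
        on the same replicate.
    """
    if mode not in ("proper", "fast"):
        raise ValueError("mode must be 'proper' or 'fast'")
    covariates = covariates or {
        "x1": ("x2", "day", "beep1", "beep6"),
        "y": ("x1", "x2", "day", "beep1", "beep6"),
    }
    seq = np.random.SeedSequence(seed)
    s_x1, s_y = seq.spawn(2)

    if x1_fit is None:
        x1_fit = fit_imputation_model(
            models["x1"], data, "x1", covariates["x1"], mcmc=mcmc,
            seed=s_x1.generate_state(1)[0] % 2**31,
        )
    x1_draws = x1_fit.draw_step1(L, seed=s_x1.generate_state(2)[1] % 2**31)
    x1_model = x1_fit.model
    rng_x1 = np.random.default_rng(s_x1.spawn(1)[0])
    completed = []
    for params, effects in x1_draws:
        col = _draw_completed_column(params, effects, x1_model.arrays, rng_x1)
        f = data.frame.copy()
        f["x1"] = col
        completed.append(f)

    y_kind = models["y"]
    y_seeds = s_y.spawn(L + 1)
    rng_y = np.random.default_rng(y_seeds[-1])
    if mode == "fast":
        fit_y = fit_imputation_model(
            y_kind,
            EMADataset(completed[0], validate=False),
            "y",
            covariates["y"],
            mcmc=mcmc,
            seed=y_seeds[0].generate_state(1)[0] % 2**31,
        )
        y_draws = fit_y.draw_step1(L, seed=y_seeds[0].generate_state(2)[1] % 2**31)
    frames = []
    for l in range(L):
        d_l = EMADataset(completed[l], validate=False)
        if mode == "proper":
            fit_l = fit_imputation_model(
                y_kind, d_l, "y", covariates["y"], mcmc=mcmc,
                seed=y_seeds[l].generate_state(1)[0] % 2**31,
            )
            params, effects = fit_l.draw_step1(
                1, seed=y_seeds[l].generate_state(2)[1] % 2**31
            )[0]
            arrays_l = fit_l.model.arrays
        else:
            params, effects = y_draws[l]
            arrays_l = ModelArrays.build(
                d_l,
                response="y",
                loc_covariates=covariates["y"],
                missing="m" if y_kind == "spmels" else None,
                missing_covariates=DEFAULT_MISS_COVARIATES if y_kind == "spmels" else (),
            )
        ycol = _draw_completed_column(params, effects, arrays_l, rng_y)
        f = completed[l].copy()
        f["y"] = ycol
        frames.append(f)

    out = ImputationSet(
        frames=frames,
        targets=["x1", "y"],
        mode="multiple" if L > 1 else "single",
        provenance={"models": dict(models), "mode": mode, "seed": seed, "L": L},
    )
    out.validate()
    return out


def rubin_pool(estimates, variances) -> dict:
    """Rubin's rules for an estimate computed on each completed copy.

    Combines L per-copy point estimates and their sampling variances into
    the pooled estimate, total variance (within + (1 + 1/L) * between),
    and the small-sample degrees of freedom.  This pools *downstream
    analysis* results; the imputation-error metric of the simulation
    study instead pools imputed values cellwise via :func:`pool_mean`.
    """
    q = np.asarray(estimates, dtype=float)
    u = np.asarray(variances, dtype=float)
    if q.size < 2:
        raise ValueError("Rubin's rules need at least 2 imputations")
    L = q.size
    qbar = q.mean()
    ubar = u.mean()
    b = q.var(ddof=1)
    total = ubar + (1 + 1 / L) * b
    if b > 0:
        df = (L - 1) * (1 + ubar / ((1 + 1 / L) * b)) ** 2
    else:
        df = np.inf
    return {"estimate": float(qbar), "variance": float(total), "df": float(df),
            "between": float(b), "within": float(ubar)}


def pool_mean(imps: ImputationSet, base: EMADataset | None = None) -> pd.DataFrame:
    """Cellwise mean of the L copies at imputed cells; observed passthrough.

    Averaging only touches the imputed target columns, so for observed
    cells (identical across copies) the mean reproduces them exactly.
    """
    if imps.L == 0:
        raise ValueError("empty imputation set")
    pooled = imps.frames[0].copy()
    for col in imps.targets:
        pooled[col] = imps.column_stack(col).mean(axis=0)
    return pooled
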