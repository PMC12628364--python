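"""Synthetic EMA data generator with informative missingness.

The generator follows a shared-parameter location-scale process: a
subject-constant baseline covariate ``x2``; a random missing effect
``lam`` driving a logistic missingness model with a day trend and
first/last-beep effects; a time-varying covariate ``x1`` generated from a
shared-parameter location-scale block given ``x2`` and ``lam``; and the
outcome ``y`` generated from a second block given ``x1``, ``x2``, ``lam``.
Where the missingness indicator is 1, ``x1`` and ``y`` are masked
*together* (non-response hides the whole report); the pre-masking values
are retained in ``true_x1`` / ``true_y`` for error computation.

The missingness intercept ``tau0`` is calibrated deterministically per
scenario so that the *expected* missing fraction — averaged over the
day/beep design and the ``lam`` distribution by Gauss–Hermite quadrature
— equals the target rate (default 20%).
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field, replace

import numpy as np
import pandas as pd
import yaml
from scipy.optimize import brentq
from scipy.special import expit

from .data import EMADataset
from .params import SPMELSParams, SubjectEffects

__all__ = [
    "GenBlock",
    "Scenario",
    "GeneratedData",
    "calibrate_tau0",
    "expected_missing_rate",
    "generate_dataset",
]


@dataclass
class GenBlock:
    """Shared-parameter location-scale generative block for one variable."""

    beta0: float
    beta: tuple
    alpha0: float
    alpha: tuple
    gamma: float
    delta: float
    sigma_eta0: float
    sigma_eta1: float
    rho: float

    def validate(self) -> None:
        if not (self.sigma_eta0 > 0 and self.sigma_eta1 > 0):
            raise ValueError("block SDs must be positive")
        if not abs(self.rho) < 1:
            raise ValueError("|rho| must be < 1")


@dataclass
class Scenario:
    """Study design and true parameters for one simulated condition."""

    n_subjects: int = 20
    n_days: int = 5
    n_beeps: int = 6
    mu_x2: float = 0.0
    sigma_x2: float = 1.0
    tau: tuple = (0.2, 0.5, 0.5)  # (day trend, beep1, beep6)
    sigma_lambda: float = 1.0
    x1_params: GenBlock = field(
        default_factory=lambda: GenBlock(
            beta0=0.0,
            beta=(0.5,),
            alpha0=0.0,
            alpha=(0.2,),
            gamma=-0.5,
            delta=0.5,
            sigma_eta0=1.0,
            sigma_eta1=0.5,
            rho=-0.20,
        )
    )
    y_params: GenBlock = field(
        default_factory=lambda: GenBlock(
            beta0=0.0,
            beta=(0.5, 0.5),  # coefficients on (x1, x2)
            alpha0=0.0,
            alpha=(0.2, 0.2),
            gamma=-0.5,
            delta=0.5,
            sigma_eta0=1.0,
            sigma_eta1=0.5,
            rho=-0.20,
        )
    )
    target_missing_rate: float = 0.20

    def __post_init__(self) -> None:
        if min(self.n_subjects, self.n_days, self.n_beeps) < 1:
            raise ValueError("n_subjects, n_days, n_beeps must be >= 1")
        if not 0 < self.target_missing_rate < 1:
            raise ValueError("target_missing_rate must be in (0,1)")
        if self.sigma_x2 <= 0 or self.sigma_lambda < 0:
            raise ValueError("sigma_x2 must be > 0 and sigma_lambda >= 0")
        if len(self.tau) != 3:
            raise ValueError("tau must be (day, beep1, beep6)")
        self.x1_params.validate()
        self.y_params.validate()

    @classmethod
    def base(cls, **overrides) -> "Scenario":
        """The base study condition; field overrides produce grid variants."""
        scn = cls()
        block_keys = {k: v for k, v in overrides.items() if k in ("x1_params", "y_params")}
        plain = {k: v for k, v in overrides.items() if k not in block_keys}
        scn = replace(scn, **plain)
        for key, blk in block_keys.items():
            if isinstance(blk, dict):
                blk = replace(getattr(scn, key), **blk)
            scn = replace(scn, **{key: blk})
        return scn

    # -- (de)serialization ----------------------------------------------
    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "Scenario":
        d = dict(d)
        for key in ("x1_params", "y_params"):
            if key in d and isinstance(d[key], dict):
                blk = dict(d[key])
                blk["beta"] = tuple(blk["beta"])
                blk["alpha"] = tuple(blk["alpha"])
                d[key] = GenBlock(**blk)
        if "tau" in d:
            d["tau"] = tuple(d["tau"])
        return cls(**d)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def from_file(cls, path) -> "Scenario":
        text = open(path).read()
        try:
            d = json.loads(text)
        except json.JSONDecodeError:
            d = yaml.safe_load(text)
        return cls.from_dict(d)

    def spmels_params(self, which: str, tau0: float) -> SPMELSParams:
        """True-parameter container for one block, as an SPMELS parameter set."""
        blk = self.x1_params if which == "x1" else self.y_params
        return SPMELSParams(
            beta0=blk.beta0,
            beta=np.asarray(blk.beta),
            alpha0=blk.alpha0,
            alpha=np.asarray(blk.alpha),
            tau0=tau0,
            tau=np.asarray(self.tau),
            gamma=blk.gamma,
            delta=blk.delta,
            sigma_eta0=blk.sigma_eta0,
            sigma_eta1=blk.sigma_eta1,
            rho_eta0eta1=blk.rho,
            sigma_lambda=max(self.sigma_lambda, 1e-12),
        )


def _design_cells(scenario: Scenario):
    """Linear-predictor offsets tau1*day + tau2*beep1 + tau3*beep6 per cell."""
    t1, t2, t3 = scenario.tau
    days = np.arange(1, scenario.n_days + 1)
    beeps = np.arange(1, scenario.n_beeps + 1)
    d, b = np.meshgrid(days, beeps, indexing="ij")
    off = t1 * d + t2 * (b == 1) + t3 * (b == scenario.n_beeps)
    return off.ravel()


def expected_missing_rate(scenario: Scenario, tau0: float, gh_order: int = 60) -> float:
    """Expected missing fraction over the design and lam ~ N(0, sigma_lambda^2)."""
    offsets = _design_cells(scenario)
    if scenario.sigma_lambda == 0:
        return float(np.mean(expit(tau0 + offsets)))
    nodes, weights = np.polynomial.hermite.hermgauss(gh_order)
    lam = np.sqrt(2.0) * scenario.sigma_lambda * nodes
    w = weights / np.sqrt(np.pi)
    probs = expit(tau0 + offsets[:, None] + lam[None, :])
    return float(np.mean(probs @ w))


def calibrate_tau0(scenario: Scenario, tol: float = 1e-10) -> float:
    """Missingness intercept whose expected missing rate hits the target.

    The expected rate is strictly increasing in tau0, so a bracketed root
    always exists for targets in (0,1).
    """
    target = scenario.target_missing_rate

    def f(t0):
        return expected_missing_rate(scenario, t0) - target

    lo, hi = -10.0, 10.0
    while f(lo) > 0:
        lo *= 2
    while f(hi) < 0:
        hi *= 2
    return float(brentq(f, lo, hi, xtol=tol))


@dataclass
class GeneratedData:
    """A generated replicate with its ground truth."""

    data: EMADataset
    tau0: float
    lam: np.ndarray
    effects_x1: SubjectEffects
    effects_y: SubjectEffects
    scenario: Scenario


def generate_dataset(
    scenario: Scenario, seed: int, tau0: float | None = None
) -> GeneratedData:
    """Generate one EMA replicate under the shared-parameter process.

    Deterministic given (scenario, seed).  ``tau0`` may be passed to avoid
    re-running the calibration for repeated replicates of one scenario.
    """
    rng = np.random.default_rng(seed)
    if tau0 is None:
        tau0 = calibrate_tau0(scenario)
    N, D, B = scenario.n_subjects, scenario.n_days, scenario.n_beeps
    n = N * D * B

    subject = np.repeat(np.arange(1, N + 1), D * B)
    day = np.tile(np.repeat(np.arange(1, D + 1), B), N)
    beep = np.tile(np.arange(1, B + 1), N * D)
    beep1 = (beep == 1).astype(float)
    beep6 = (beep == B).astype(float)
    s = subject - 1  # 0-based codes

    # step 1: subject-constant baseline covariate
    x2_i = rng.normal(scenario.mu_x2, scenario.sigma_x2, size=N)

    # step 2: random missing effect and missingness indicator
    lam = rng.normal(0.0, scenario.sigma_lambda, size=N) if scenario.sigma_lambda else np.zeros(N)
    lin_m = tau0 + scenario.tau[0] * day + scenario.tau[1] * beep1 + scenario.tau[2] * beep6
    p_miss = expit(lin_m + lam[s])
    m = rng.binomial(1, p_miss).astype(float)

    def _draw_block(blk: GenBlock, X_loc, X_scale):
        z = rng.standard_normal((2, N))
        eta0 = blk.sigma_eta0 * z[0]
        eta1 = blk.sigma_eta1 * (blk.rho * z[0] + np.sqrt(1 - blk.rho**2) * z[1])
        eff = SubjectEffects.from_shared(blk.gamma, blk.delta, lam, eta0, eta1)
        mu = blk.beta0 + X_loc @ np.asarray(blk.beta) + eff.v0[s]
        lv = blk.alpha0 + X_scale @ np.asarray(blk.alpha) + eff.v1[s]
        vals = rng.normal(mu, np.exp(0.5 * lv))
        return vals, eff

    # step 3: time-varying covariate x1 given x2 and lam
    X2 = x2_i[s][:, None]
    x1, eff_x1 = _draw_block(scenario.x1_params, X2, X2)

    # step 4: outcome y given x1, x2 and lam
    X12 = np.column_stack([x1, x2_i[s]])
    y, eff_y = _draw_block(scenario.y_params, X12, X12)

    masked = m == 1
    frame = pd.DataFrame(
        {
            "subject": subject,
            "day": day,
            "beep": beep,
            "beep1": beep1,
            "beep6": beep6,
            "x2": x2_i[s],
            "x1": np.where(masked, np.nan, x1),
            "y": np.where(masked, np.nan, y),
            "m": m,
            "true_x1": x1,
            "true_y": y,
        }
    )
    assert len(frame) == n
    return GeneratedData(
        data=EMADataset(frame),
        tau0=float(tau0),
        lam=lam,
        effects_x1=eff_x1,
        effects_y=eff_y,
        scenario=scenario,
    )
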