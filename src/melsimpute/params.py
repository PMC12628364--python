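"""Parameter containers for the three nested mixed models.

Three models of increasing structure are supported:

* ``RILM`` — random-intercept linear mixed model: one random location
  effect per subject, constant within-subject (WS) variance
  ``sigma_eps^2 = exp(alpha0)``.
* ``MELS`` — mixed-effects location-scale model: the log WS variance is a
  linear model in covariates plus a random scale effect ``v1`` correlated
  with the location effect ``v0``.
* ``SPMELS`` — shared-parameter MELS: a random-intercept logistic model
  for the missingness indicator whose random effect ``lambda`` loads on
  the outcome's location (via ``gamma``) and log scale (via ``delta``)::

      v0_i = gamma * lam_i + eta0_i
      v1_i = delta * lam_i + eta1_i

  with ``(eta0, eta1)`` bivariate normal, independent of ``lam``.

All containers store random-effect covariances as (SD, SD, correlation)
so the positivity / |rho| < 1 invariants are directly checkable.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "RILMParams",
    "MELSParams",
    "SPMELSParams",
    "SubjectEffects",
]


def _as_vector(x) -> np.ndarray:
    v = np.atleast_1d(np.asarray(x, dtype=float))
    if v.ndim != 1:
        raise ValueError("expected a 1-d coefficient vector")
    return v


@dataclass
class RILMParams:
    """Random-intercept linear mixed model parameters.

    ``alpha0`` is the *log* of the (constant) WS variance, so that all
    three models share one interface for the variance submodel.
    """

    beta0: float
    beta: np.ndarray
    alpha0: float
    sigma_v0: float

    def __post_init__(self) -> None:
        self.beta = _as_vector(self.beta)
        if not self.sigma_v0 > 0:
            raise ValueError(f"sigma_v0 must be positive, got {self.sigma_v0}")
        if not np.isfinite([self.beta0, self.alpha0, self.sigma_v0]).all():
            raise ValueError("non-finite parameter value")

    @property
    def p(self) -> int:
        return self.beta.size


@dataclass
class MELSParams:
    """Mixed-effects location-scale model parameters."""

    beta0: float
    beta: np.ndarray
    alpha0: float
    alpha: np.ndarray
    sigma_v0: float
    sigma_v1: float
    rho_v0v1: float

    def __post_init__(self) -> None:
        self.beta = _as_vector(self.beta)
        self.alpha = _as_vector(self.alpha)
        if not (self.sigma_v0 > 0 and self.sigma_v1 > 0):
            raise ValueError("random-effect SDs must be positive")
        if not abs(self.rho_v0v1) < 1:
            raise ValueError(f"|rho_v0v1| must be < 1, got {self.rho_v0v1}")

    @property
    def p(self) -> int:
        return self.beta.size

    def effects_cov(self) -> np.ndarray:
        """2x2 covariance of (v0, v1); positive definite by construction."""
        c = self.rho_v0v1 * self.sigma_v0 * self.sigma_v1
        return np.array(
            [[self.sigma_v0**2, c], [c, self.sigma_v1**2]]
        )


@dataclass
class SPMELSParams:
    """Shared-parameter MELS parameters.

    The 3x3 covariance of (eta0, eta1, lam) is block diagonal: ``lam`` is
    independent of the residual effects by construction.
    """

    beta0: float
    beta: np.ndarray
    alpha0: float
    alpha: np.ndarray
    tau0: float
    tau: np.ndarray
    gamma: float
    delta: float
    sigma_eta0: float
    sigma_eta1: float
    rho_eta0eta1: float
    sigma_lambda: float

    def __post_init__(self) -> None:
        self.beta = _as_vector(self.beta)
        self.alpha = _as_vector(self.alpha)
        self.tau = _as_vector(self.tau)
        for name in ("sigma_eta0", "sigma_eta1", "sigma_lambda"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be positive")
        if not abs(self.rho_eta0eta1) < 1:
            raise ValueError(f"|rho_eta0eta1| must be < 1, got {self.rho_eta0eta1}")

    @property
    def p(self) -> int:
        return self.beta.size

    @property
    def q(self) -> int:
        return self.tau.size

    def effects_cov(self) -> np.ndarray:
        """3x3 block-diagonal covariance of (eta0, eta1, lam)."""
        c = self.rho_eta0eta1 * self.sigma_eta0 * self.sigma_eta1
        return np.array(
            [
                [self.sigma_eta0**2, c, 0.0],
                [c, self.sigma_eta1**2, 0.0],
                [0.0, 0.0, self.sigma_lambda**2],
            ]
        )

    def implied_sigma_v0(self) -> float:
        """Marginal SD of the composite location effect v0."""
        return float(np.hypot(self.gamma * self.sigma_lambda, self.sigma_eta0))

    def implied_sigma_v1(self) -> float:
        """Marginal SD of the composite scale effect v1."""
        return float(np.hypot(self.delta * self.sigma_lambda, self.sigma_eta1))


@dataclass
class SubjectEffects:
    """Per-subject random effects.

    For RILM only ``v0`` is populated; for MELS ``v0, v1``; for SPMELS the
    composite effects satisfy ``v0 = gamma*lam + eta0`` and
    ``v1 = delta*lam + eta1`` elementwise.
    """

    v0: np.ndarray
    v1: np.ndarray = field(default_factory=lambda: np.empty(0))
    lam: np.ndarray = field(default_factory=lambda: np.empty(0))
    eta0: np.ndarray = field(default_factory=lambda: np.empty(0))
    eta1: np.ndarray = field(default_factory=lambda: np.empty(0))

    def __post_init__(self) -> None:
        self.v0 = np.asarray(self.v0, dtype=float)
        self.v1 = np.asarray(self.v1, dtype=float)
        self.lam = np.asarray(self.lam, dtype=float)
        self.eta0 = np.asarray(self.eta0, dtype=float)
        self.eta1 = np.asarray(self.eta1, dtype=float)

    @property
    def n_subjects(self) -> int:
        return self.v0.size

    @classmethod
    def from_shared(
        cls, gamma: float, delta: float, lam, eta0, eta1
    ) -> "SubjectEffects":
        """Build composite (v0, v1) from the shared-parameter decomposition."""
        lam = np.asarray(lam, dtype=float)
        eta0 = np.asarray(eta0, dtype=float)
        eta1 = np.asarray(eta1, dtype=float)
        return cls(
            v0=gamma * lam + eta0,
            v1=delta * lam + eta1,
            lam=lam,
            eta0=eta0,
            eta1=eta1,
        )

    def check_shared_consistency(self, gamma: float, delta: float, atol=1e-10):
        if self.lam.size:
            if not np.allclose(self.v0, gamma * self.lam + self.eta0, atol=atol):
                raise ValueError("v0 != gamma*lam + eta0")
            if not np.allclose(self.v1, delta * self.lam + self.eta1, atol=atol):
                raise ValueError("v1 != delta*lam + eta1")
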