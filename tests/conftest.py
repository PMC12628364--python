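import numpy as np
import pandas as pd
import pytest

from melsimpute import (
    EMADataset,
    MELSParams,
    RILMParams,
    SPMELSParams,
    Scenario,
    SubjectEffects,
    generate_dataset,
)
from melsimpute.data import ModelArrays


@pytest.fixture(scope="session")
def base_scenario():
    return Scenario.base()


@pytest.fixture(scope="session")
def small_replicate(base_scenario):
    """One generated replicate of the base design (600 rows, ~20% missing)."""
    return generate_dataset(base_scenario, seed=42)


def make_arrays(frame, response="y", loc=("x1", "x2"), scale=None, missing=None,
                missing_covariates=()):
    return ModelArrays.build(
        EMADataset(frame, validate=False),
        response=response,
        loc_covariates=loc,
        scale_covariates=scale,
        missing=missing,
        missing_covariates=missing_covariates,
    )


@pytest.fixture
def tiny_frame():
    """One subject, three occasions, fully observed."""
    return pd.DataFrame(
        {
            "subject": [1, 1, 1],
            "day": [1, 1, 2],
            "beep1": [1.0, 0.0, 1.0],
            "beep6": [0.0, 1.0, 0.0],
            "x1": [0.3, -0.2, 0.5],
            "x2": [0.7, 0.7, 0.7],
            "y": [0.1, 1.2, -0.4],
            "m": [0.0, 0.0, 1.0],
        }
    )


def random_spmels_params(rng, p=2, q=3):
    return SPMELSParams(
        beta0=rng.normal(),
        beta=rng.normal(size=p) * 0.5,
        alpha0=rng.normal() * 0.3,
        alpha=rng.normal(size=p) * 0.2,
        tau0=rng.normal(),
        tau=rng.normal(size=q) * 0.3,
        gamma=rng.normal() * 0.5,
        delta=rng.normal() * 0.5,
        sigma_eta0=np.exp(rng.normal() * 0.2),
        sigma_eta1=np.exp(rng.normal() * 0.2),
        rho_eta0eta1=np.tanh(rng.normal() * 0.5),
        sigma_lambda=np.exp(rng.normal() * 0.2),
    )


def random_effects(rng, params, n_subjects):
    if isinstance(params, SPMELSParams):
        return SubjectEffects.from_shared(
            params.gamma,
            params.delta,
            rng.normal(0, params.sigma_lambda, n_subjects),
            rng.normal(0, params.sigma_eta0, n_subjects),
            rng.normal(0, params.sigma_eta1, n_subjects),
        )
    if isinstance(params, MELSParams):
        return SubjectEffects(
            v0=rng.normal(0, params.sigma_v0, n_subjects),
            v1=rng.normal(0, params.sigma_v1, n_subjects),
        )
    assert isinstance(params, RILMParams)
    return SubjectEffects(v0=rng.normal(0, params.sigma_v0, n_subjects))
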