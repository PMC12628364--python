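"""Log-density building blocks checked against direct per-row oracles."""

import numpy as np
import pandas as pd
import pytest
from scipy import integrate
from scipy.stats import bernoulli, norm

from melsimpute import (
    MELSParams,
    RILMParams,
    SPMELSParams,
    SubjectEffects,
    joint_log_density,
    loglik_missing,
    loglik_y,
    missingness_prob,
    variance_share,
    ws_variance,
)
from melsimpute.densities import effects_log_density

from conftest import make_arrays, random_effects, random_spmels_params


class TestWSVariance:
    def test_rilm_is_exp_alpha0(self):
        p = RILMParams(beta0=0, beta=[0.0], alpha0=np.log(4.0), sigma_v0=1.0)
        assert ws_variance(p) == pytest.approx(4.0)

    def test_mels_exponent_sums(self):
        p = MELSParams(beta0=0, beta=[0.0], alpha0=0.0, alpha=[0.5],
                       sigma_v0=1, sigma_v1=1, rho_v0v1=0.0)
        eff = SubjectEffects(v0=[0.0], v1=[-0.5])
        assert ws_variance(p, x_row=[1.0], effects_row=eff) == pytest.approx(1.0)

    def test_spmels_loading_on_scale(self):
        p = SPMELSParams(beta0=0, beta=[0.0], alpha0=0.0, alpha=[0.0], tau0=0,
                         tau=[0.0], gamma=0.0, delta=0.7, sigma_eta0=1,
                         sigma_eta1=1, rho_eta0eta1=0, sigma_lambda=1)
        eff = SubjectEffects.from_shared(0.0, 0.7, lam=[1.0], eta0=[0.0], eta1=[0.3])
        assert ws_variance(p, x_row=[0.0], effects_row=eff) == pytest.approx(np.e)

    def test_log_inverts_to_linear_predictor(self):
        rng = np.random.default_rng(1)
        for _ in range(50):
            a0, a1, v1 = rng.normal(size=3)
            p = MELSParams(beta0=0, beta=[0.0], alpha0=a0, alpha=[a1],
                           sigma_v0=1, sigma_v1=1, rho_v0v1=0.0)
            x = rng.normal()
            got = np.log(ws_variance(p, [x], SubjectEffects(v0=[0.0], v1=[v1])))
            assert got == pytest.approx(a0 + a1 * x + v1, abs=1e-12)

    def test_dimension_mismatch(self):
        p = MELSParams(beta0=0, beta=[0.0], alpha0=0, alpha=[0.1, 0.2],
                       sigma_v0=1, sigma_v1=1, rho_v0v1=0)
        with pytest.raises(ValueError, match="length"):
            ws_variance(p, [1.0], SubjectEffects(v0=[0.0], v1=[0.0]))


class TestMissingnessProb:
    def test_zero_predictor(self):
        assert missingness_prob(0.0, [0.0], [1.0], 0.0) == pytest.approx(0.5)

    def test_log3_predictor(self):
        assert missingness_prob(np.log(3), [], [], 0.0) == pytest.approx(0.75)

    def test_limit_and_monotonicity(self):
        assert missingness_prob(-500.0, [], [], 0.0) == pytest.approx(0.0, abs=1e-12)
        grid = np.linspace(-3, 3, 13)
        probs = [missingness_prob(t0, [1.0], [0.5], 0.2) for t0 in grid]
        assert np.all(np.diff(probs) > 0)
        probs_lam = [missingness_prob(0.1, [1.0], [0.5], l) for l in grid]
        assert np.all(np.diff(probs_lam) > 0)


class TestLoglikY:
    def test_single_standard_normal_at_mean(self):
        f = pd.DataFrame({"subject": [1], "x1": [0.0], "x2": [0.0], "y": [1.5]})
        arrays = make_arrays(f)
        p = RILMParams(beta0=1.5, beta=[0.0, 0.0], alpha0=0.0, sigma_v0=1.0)
        eff = SubjectEffects(v0=[0.0])
        assert loglik_y(p, arrays, eff) == pytest.approx(-0.5 * np.log(2 * np.pi))

    def test_additivity_two_iid(self):
        f = pd.DataFrame({"subject": [1, 2], "x1": [0.0, 0.0], "x2": [0.0, 0.0],
                          "y": [0.7, 0.7]})
        arrays = make_arrays(f)
        p = RILMParams(beta0=0.7, beta=[0.0, 0.0], alpha0=0.0, sigma_v0=1.0)
        eff = SubjectEffects(v0=[0.0, 0.0])
        assert loglik_y(p, arrays, eff) == pytest.approx(-np.log(2 * np.pi))

    def test_matches_per_row_density_oracle(self):
        rng = np.random.default_rng(7)
        n, N = 40, 5
        f = pd.DataFrame(
            {
                "subject": rng.integers(1, N + 1, n),
                "x1": rng.normal(size=n),
                "x2": rng.normal(size=n),
                "y": rng.normal(size=n),
            }
        )
        f.loc[rng.choice(n, 6, replace=False), "y"] = np.nan
        arrays = make_arrays(f)
        params = random_spmels_params(rng)
        eff = random_effects(rng, params, arrays.n_subjects)
        got = loglik_y(params, arrays, eff)
        # oracle: per-row scipy normal logpdf over observed rows
        expected = 0.0
        for i in range(n):
            if np.isnan(f.loc[i, "y"]):
                continue
            s = arrays.subject[i]
            mu = (params.beta0 + f.loc[i, "x1"] * params.beta[0]
                  + f.loc[i, "x2"] * params.beta[1]
                  + eff.eta0[s] + params.gamma * eff.lam[s])
            lv = (params.alpha0 + f.loc[i, "x1"] * params.alpha[0]
                  + f.loc[i, "x2"] * params.alpha[1]
                  + eff.eta1[s] + params.delta * eff.lam[s])
            expected += norm.logpdf(f.loc[i, "y"], mu, np.exp(lv / 2))
        assert got == pytest.approx(expected, abs=1e-10)


class TestLoglikMissing:
    def test_all_zero_predictor(self):
        f = pd.DataFrame({"subject": [1] * 10, "x1": 0.0, "x2": 0.0,
                          "y": 0.0, "m": [0.0] * 10})
        arrays = make_arrays(f, missing="m")
        p = random_spmels_params(np.random.default_rng(0), q=0)
        p.tau0, p.tau = 0.0, np.empty(0)
        eff = SubjectEffects.from_shared(p.gamma, p.delta, [0.0], [0.0], [0.0])
        assert loglik_missing(p, arrays, eff) == pytest.approx(10 * np.log(0.5))

    def test_one_occasion_log3(self):
        f = pd.DataFrame({"subject": [1], "x1": [0.0], "x2": [0.0],
                          "y": [np.nan], "m": [1.0]})
        arrays = make_arrays(f, missing="m")
        p = random_spmels_params(np.random.default_rng(0), q=0)
        p.tau0, p.tau = np.log(3.0), np.empty(0)
        eff = SubjectEffects.from_shared(p.gamma, p.delta, [0.0], [0.0], [0.0])
        assert loglik_missing(p, arrays, eff) == pytest.approx(np.log(0.75))

    def test_matches_bernoulli_oracle(self):
        rng = np.random.default_rng(11)
        n, N = 60, 6
        f = pd.DataFrame(
            {
                "subject": rng.integers(1, N + 1, n),
                "day": rng.integers(1, 6, n).astype(float),
                "beep1": rng.integers(0, 2, n).astype(float),
                "beep6": rng.integers(0, 2, n).astype(float),
                "x1": rng.normal(size=n),
                "x2": rng.normal(size=n),
                "y": rng.normal(size=n),
                "m": rng.integers(0, 2, n).astype(float),
            }
        )
        arrays = make_arrays(f, missing="m", missing_covariates=("day", "beep1", "beep6"))
        params = random_spmels_params(rng)
        eff = random_effects(rng, params, arrays.n_subjects)
        got = loglik_missing(params, arrays, eff)
        expected = 0.0
        for i in range(n):
            s = arrays.subject[i]
            pr = missingness_prob(
                params.tau0, params.tau,
                [f.loc[i, "day"], f.loc[i, "beep1"], f.loc[i, "beep6"]],
                eff.lam[s],
            )
            expected += bernoulli.logpmf(int(f.loc[i, "m"]), pr)
        assert got == pytest.approx(expected, abs=1e-12)


class TestJointLogDensity:
    def test_spmels_reduces_to_mels_plus_missing(self, tiny_frame):
        """With gamma = delta = 0 the joint splits into MELS + missingness + lam."""
        rng = np.random.default_rng(3)
        f = tiny_frame.copy()
        arrays_sp = make_arrays(f, missing="m", missing_covariates=("day", "beep1", "beep6"))
        arrays_mels = make_arrays(f)
        sp = random_spmels_params(rng)
        sp.gamma, sp.delta = 0.0, 0.0
        eff = random_effects(rng, sp, 1)
        mels = MELSParams(
            beta0=sp.beta0, beta=sp.beta, alpha0=sp.alpha0, alpha=sp.alpha,
            sigma_v0=sp.sigma_eta0, sigma_v1=sp.sigma_eta1, rho_v0v1=sp.rho_eta0eta1,
        )
        eff_mels = SubjectEffects(v0=eff.eta0, v1=eff.eta1)
        lam_logpdf = norm.logpdf(eff.lam, 0, sp.sigma_lambda).sum()
        lhs = joint_log_density(sp, arrays_sp, eff)
        rhs = (joint_log_density(mels, arrays_mels, eff_mels)
               + loglik_missing(sp, arrays_sp, eff) + lam_logpdf)
        assert lhs == pytest.approx(rhs, abs=1e-10)

    @pytest.mark.parametrize("kind", ["rilm", "mels", "spmels"])
    def test_marginal_likelihood_matches_quadrature_oracle(self, kind, tiny_frame):
        """Adaptive quadrature and Gauss-Hermite marginals agree on 1 subject."""
        rng = np.random.default_rng(5)
        f = tiny_frame.iloc[:2].copy()  # two occasions keep the 3-d integral fast
        sp = random_spmels_params(rng)
        if kind == "rilm":
            arrays = make_arrays(f)
            params = RILMParams(beta0=sp.beta0, beta=sp.beta, alpha0=0.2, sigma_v0=0.8)

            def joint(v0):
                return joint_log_density(params, arrays, SubjectEffects(v0=[v0]))

            gh = _gh_marginal(joint, [0.8], order=80)
            adaptive, _ = integrate.quad(lambda v: np.exp(joint(v)), -8, 8, epsabs=1e-12)
        elif kind == "mels":
            arrays = make_arrays(f)
            params = MELSParams(beta0=sp.beta0, beta=sp.beta, alpha0=0.1,
                                alpha=sp.alpha, sigma_v0=0.8, sigma_v1=0.5,
                                rho_v0v1=-0.3)

            def joint(v0, v1):
                return joint_log_density(params, arrays, SubjectEffects(v0=[v0], v1=[v1]))

            gh = _gh_marginal(joint, [0.8, 0.5], order=60)
            adaptive, _ = integrate.nquad(
                lambda a, b: np.exp(joint(a, b)), [(-7, 7), (-5, 5)]
            )
        else:
            arrays = make_arrays(f, missing="m", missing_covariates=("day", "beep1", "beep6"))
            # moderate scale-effect SD keeps the 3-d integrand resolvable by
            # a tensor rule (large sigma_eta1 makes a near-singular ridge)
            params = SPMELSParams(
                beta0=sp.beta0, beta=sp.beta, alpha0=0.1, alpha=sp.alpha,
                tau0=sp.tau0, tau=sp.tau, gamma=-0.4, delta=0.5,
                sigma_eta0=0.8, sigma_eta1=0.4, rho_eta0eta1=-0.2,
                sigma_lambda=0.7,
            )

            def joint(e0, e1, lam):
                eff = SubjectEffects.from_shared(
                    params.gamma, params.delta, [lam], [e0], [e1]
                )
                return joint_log_density(params, arrays, eff)

            # the scale effect enters through exp(eta1): slow GH dimension
            gh = _gh_marginal(joint, [params.sigma_eta0, params.sigma_eta1,
                                      params.sigma_lambda], order=(24, 64, 32))
            adaptive = _spmels_marginal_oracle(params, f)
        assert adaptive == pytest.approx(gh, rel=1e-6)

    def test_mels_marginal_approaches_rilm_in_degenerate_limit(self, tiny_frame):
        """alpha = 0, sigma_v1 -> 0, rho = 0 collapses MELS onto RILM."""
        f = tiny_frame.iloc[:2].copy()
        arrays = make_arrays(f)
        ri = RILMParams(beta0=0.2, beta=[0.4, -0.1], alpha0=0.3, sigma_v0=0.7)
        me = MELSParams(beta0=0.2, beta=[0.4, -0.1], alpha0=0.3, alpha=[0.0, 0.0],
                        sigma_v0=0.7, sigma_v1=1e-8, rho_v0v1=0.0)

        def joint_ri(v0):
            return joint_log_density(ri, arrays, SubjectEffects(v0=[v0]))

        def joint_me(v0, v1):
            return joint_log_density(me, arrays, SubjectEffects(v0=[v0], v1=[v1]))

        lik_ri = _gh_marginal(joint_ri, [0.7], order=60)
        lik_me = _gh_marginal(joint_me, [0.7, 1e-8], order=60)
        assert np.log(lik_me) == pytest.approx(np.log(lik_ri), abs=1e-6)


def _gh_marginal(joint_fn, sds, order):
    """Tensor Gauss-Hermite integral of exp(joint) over the effects.

    Importance form: the Gaussian effect prior inside the joint is divided
    out and absorbed into the Hermite weight, i.e.
    integral = pi^(-d/2) * sum_i w_i exp(joint(x_i) - log phi(x_i)).
    ``order`` may be an int or a per-dimension sequence.
    """
    d = len(sds)
    orders = [order] * d if np.isscalar(order) else list(order)
    rules = [np.polynomial.hermite.hermgauss(o) for o in orders]
    grids = np.meshgrid(
        *[np.sqrt(2) * s * r[0] for s, r in zip(sds, rules)], indexing="ij"
    )
    wgrids = np.meshgrid(*[r[1] for r in rules], indexing="ij")
    pts = np.stack([g.ravel() for g in grids], axis=1)
    wts = np.prod(np.stack([w.ravel() for w in wgrids], axis=1), axis=1)
    vals = np.empty(len(pts))
    for i, p in enumerate(pts):
        kern = sum(
            -0.5 * (p[j] / sds[j]) ** 2 - 0.5 * np.log(2 * np.pi) - np.log(sds[j])
            for j in range(d)
        )
        vals[i] = joint_fn(*p) - kern
    return float(np.sum(wts * np.exp(vals)) / np.pi ** (d / 2))


def _spmels_marginal_oracle(params, frame):
    """Brute-force 1-subject marginal: analytic eta0 integral (conjugate
    normal, conditioning on eta1 through the effect correlation) followed
    by high-order 2-d Gauss-Hermite over (eta1, lam).

    Independent of the package density code: every term is written out
    from the model definition.
    """
    y = frame["y"].to_numpy()
    m = frame["m"].to_numpy()
    X = frame[["x1", "x2"]].to_numpy()
    T = frame[["day", "beep1", "beep6"]].to_numpy()
    s0, s1, sl = params.sigma_eta0, params.sigma_eta1, params.sigma_lambda
    rho = params.rho_eta0eta1
    nodes, w = np.polynomial.hermite.hermgauss(100)
    E1, LAM = np.meshgrid(np.sqrt(2) * s1 * nodes, np.sqrt(2) * sl * nodes,
                          indexing="ij")
    W = np.outer(w, w)
    e1 = E1.ravel()[:, None]
    lam = LAM.ravel()[:, None]
    sig2 = np.exp(params.alpha0 + X @ params.alpha + e1 + params.delta * lam)
    r = y - (params.beta0 + X @ params.beta + params.gamma * lam)
    mu_c = rho * s0 / s1 * e1[:, 0]
    tau2_c = s0**2 * (1 - rho**2)
    P = 1 / tau2_c + np.sum(1 / sig2, axis=1)
    b = mu_c / tau2_c + np.sum(r / sig2, axis=1)
    quad = np.sum(r * r / sig2, axis=1) + mu_c**2 / tau2_c - b * b / P
    log_y = (
        -0.5 * np.sum(np.log(2 * np.pi * sig2), axis=1)
        - 0.5 * np.log(2 * np.pi * tau2_c)
        + 0.5 * np.log(2 * np.pi / P)
        - 0.5 * quad
    )
    c = params.tau0 + T @ params.tau + lam
    log_m = np.sum(m * c - np.logaddexp(0.0, c), axis=1)
    return float(np.sum(W.ravel() * np.exp(log_y + log_m)) / np.pi)


class TestVarianceShare:
    def test_zero_loading(self):
        assert variance_share(0.0, 1.0, 1.0) == 0.0

    def test_symmetric_half(self):
        assert variance_share(1.0, 1.0, 1.0) == pytest.approx(0.5)

    def test_limits_and_errors(self):
        assert variance_share(2.0, 1.0, 0.0) == pytest.approx(1.0)
        with pytest.raises(ValueError):
            variance_share(0.0, 1.0, 0.0)
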