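"""Step-2 imputation: observed-data preservation, degenerate limits,
pooling, and the sequential two-variable pipeline."""

import numpy as np
import pandas as pd
import pytest

from melsimpute import (
    EMADataset,
    MCMCConfig,
    RILM,
    RILMParams,
    SubjectEffects,
    impute_variable,
    pool_mean,
    sequential_impute,
)
from melsimpute.imputation import ImputationSet

FAST = MCMCConfig(chains=1, warmup=200, draws=200, rhat_threshold=1.3)


@pytest.fixture(scope="module")
def rilm_fit(small_replicate):
    model = RILM(small_replicate.data, response="y",
                 loc_covariates=("x2", "day", "beep1", "beep6"))
    return model.fit("ml")


class TestImputeVariable:
    def test_no_missing_is_identity(self, small_replicate, rilm_fit):
        complete = small_replicate.data.frame.copy()
        complete["y"] = complete["true_y"]
        data = EMADataset(complete, validate=False)
        model = RILM(data, response="y", loc_covariates=("x2", "day", "beep1", "beep6"))
        fit = model.fit("ml")
        imps = impute_variable(data, fit.draw_step1(4, seed=0), model, "y", seed=1)
        for f in imps.frames:
            np.testing.assert_array_equal(f["y"], complete["y"])

    def test_observed_cells_preserved_bit_exact(self, small_replicate, rilm_fit):
        data = small_replicate.data
        imps = impute_variable(data, rilm_fit.draw_step1(5, seed=2),
                               rilm_fit.model, "y", seed=3)
        obs = data.frame["y"].notna()
        for f in imps.frames:
            assert (f.loc[obs, "y"] == data.frame.loc[obs, "y"]).all()
            assert f["y"].notna().all()

    def test_zero_ws_variance_gives_conditional_mean(self, small_replicate):
        data = small_replicate.data
        model = RILM(data, response="y", loc_covariates=("x2", "day", "beep1", "beep6"))
        params = RILMParams(beta0=1.0, beta=[0.5, 0.1, 0.0, 0.0], alpha0=-60.0,
                            sigma_v0=1.0)
        effects = SubjectEffects(v0=np.zeros(20))
        imps = impute_variable(data, [(params, effects)], model, "y", seed=4)
        f = data.frame
        miss = f["y"].isna()
        expected = (1.0 + 0.5 * f["x2"] + 0.1 * f["day"])[miss]
        np.testing.assert_allclose(imps.frames[0].loc[miss, "y"], expected, atol=1e-6)

    def test_missing_covariate_raises(self, small_replicate, rilm_fit):
        data = small_replicate.data
        model = RILM(data, response="y", loc_covariates=("x1", "x2"))
        # x1 is itself missing at the rows to impute
        fit = rilm_fit
        with pytest.raises(ValueError, match="impute them first"):
            impute_variable(data, fit.draw_step1(2, seed=0), model, "y", seed=0)

    def test_mcar_rilm_imputations_center_on_conditional_mean(self):
        """Under MCAR the mean of many imputed values matches the
        generating conditional mean within Monte-Carlo error."""
        rng = np.random.default_rng(3)
        N, n_per = 40, 20
        s = np.repeat(np.arange(N), n_per)
        v0 = rng.normal(0, 0.8, N)
        x = rng.normal(size=N * n_per)
        y = 0.3 + 0.7 * x + v0[s] + rng.normal(0, 1.0, N * n_per)
        f = pd.DataFrame({"subject": s + 1, "x2": x, "y": y})
        mask = rng.random(len(f)) < 0.2  # MCAR
        truth = f["y"].copy()
        f.loc[mask, "y"] = np.nan
        model = RILM(f, response="y", loc_covariates=("x2",))
        fit = model.fit("ml")
        L = 50
        imps = impute_variable(EMADataset(f, validate=False),
                               fit.draw_step1(L, seed=5), model, "y", seed=6)
        stack = imps.column_stack("y")[:, mask]
        params = fit.params()
        mean_hat, _ = fit._eb_moments(params)
        cond = params.beta0 + params.beta[0] * f.loc[mask, "x2"].to_numpy() \
            + mean_hat[s[mask]]
        # average over missing cells and copies; allow 3 x combined MC error
        resid = stack.mean(axis=0) - cond
        se = np.sqrt(np.exp(params.alpha0) / L + 0.1) / np.sqrt(mask.sum())
        assert abs(resid.mean()) < 3 * np.sqrt(np.exp(params.alpha0) / L) / np.sqrt(mask.sum()) + 0.05


class TestPoolMean:
    def test_identical_copies_pass_through(self, small_replicate, rilm_fit):
        data = small_replicate.data
        [(p, e)] = rilm_fit.draw_step1(1, seed=0)
        imps = impute_variable(data, [(p, e), (p, e)], rilm_fit.model, "y", seed=7)
        # same params but fresh noise per copy: force equality instead
        imps.frames[1] = imps.frames[0].copy()
        pooled = pool_mean(imps)
        np.testing.assert_array_equal(pooled["y"], imps.frames[0]["y"])

    def test_two_copy_average(self):
        base = pd.DataFrame({"subject": [1], "y": [np.nan]})
        f1, f2 = base.copy(), base.copy()
        f1["y"], f2["y"] = [1.0], [3.0]
        imps = ImputationSet(frames=[f1, f2], targets=["y"], mode="multiple")
        assert pool_mean(imps)["y"].iloc[0] == pytest.approx(2.0)

    def test_elementwise_mean_oracle(self, small_replicate, rilm_fit):
        data = small_replicate.data
        imps = impute_variable(data, rilm_fit.draw_step1(7, seed=1),
                               rilm_fit.model, "y", seed=8)
        pooled = pool_mean(imps)
        manual = np.mean([f["y"].to_numpy() for f in imps.frames], axis=0)
        np.testing.assert_array_equal(pooled["y"].to_numpy(), manual)

    def test_empty_set_raises(self):
        with pytest.raises(ValueError):
            pool_mean(ImputationSet(frames=[], targets=["y"], mode="single"))


class TestRubinPool:
    def test_matches_textbook_formulas(self):
        from melsimpute import rubin_pool

        q = [1.0, 1.2, 0.9, 1.1]
        u = [0.04, 0.05, 0.04, 0.045]
        out = rubin_pool(q, u)
        L = 4
        b = np.var(q, ddof=1)
        assert out["estimate"] == pytest.approx(np.mean(q))
        assert out["variance"] == pytest.approx(np.mean(u) + (1 + 1 / L) * b)
        assert out["df"] == pytest.approx(
            (L - 1) * (1 + np.mean(u) / ((1 + 1 / L) * b)) ** 2
        )

    def test_needs_two_copies(self):
        from melsimpute import rubin_pool

        with pytest.raises(ValueError):
            rubin_pool([1.0], [0.1])


class TestSequential:
    def test_pipeline_completes_and_preserves_observed(self, small_replicate):
        data = small_replicate.data
        imps = sequential_impute(data, {"x1": "rilm", "y": "rilm"}, L=3, seed=9,
                                 mode="proper", mcmc=FAST)
        assert imps.L == 3
        obs = data.frame["m"] == 0
        for f in imps.frames:
            assert f["x1"].notna().all() and f["y"].notna().all()
            assert (f.loc[obs, "x1"] == data.frame.loc[obs, "x1"]).all()
            assert (f.loc[obs, "y"] == data.frame.loc[obs, "y"]).all()

    def test_single_imputation_arm_is_one_copy(self, small_replicate):
        imps = sequential_impute(small_replicate.data, {"x1": "rilm", "y": "rilm"},
                                 L=1, seed=10, mode="fast", mcmc=FAST)
        assert imps.L == 1 and imps.mode == "single"

    def test_no_missing_x1_reduces_to_y_only(self, small_replicate):
        complete = small_replicate.data.frame.copy()
        complete["x1"] = complete["true_x1"]
        data = EMADataset(complete, validate=False)
        imps = sequential_impute(data, {"x1": "rilm", "y": "rilm"}, L=2, seed=11,
                                 mode="fast", mcmc=FAST)
        for f in imps.frames:
            np.testing.assert_array_equal(f["x1"], complete["x1"])
            assert f["y"].notna().all()

    def test_between_copy_variability_at_missing_cells(self, small_replicate):
        data = small_replicate.data
        imps = sequential_impute(data, {"x1": "rilm", "y": "rilm"}, L=4, seed=12,
                                 mode="fast", mcmc=FAST)
        miss = data.frame["y"].isna().to_numpy()
        stack = imps.column_stack("y")[:, miss]
        assert np.all(stack.std(axis=0) > 0)
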