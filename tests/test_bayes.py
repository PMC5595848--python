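"""Samplers against conjugate closed forms, plus summaries and diagnostics."""

import numpy as np
import pandas as pd
import pytest

from melibiome.bayes import (
    ChainSet,
    McmcSettings,
    PriorSpec,
    dic,
    effective_sample_size,
    fit_group_model,
    fit_linear_model,
    fit_logistic_model,
    gelman_rubin,
    summarize,
)

FAST = McmcSettings(n_chains=2, burn_in=300, n_iter=3000, thin=3, seed=11)


def _mc_se(x):
    return x.std() / np.sqrt(len(x))


class TestGroupModel:
    def test_conjugate_posterior_with_fixed_precision(self):
        # tau fixed at 1, y = {1,2,3}: mu | y ~ N(3*2/(3+1e-6), 1/(3+1e-6))
        y = np.array([1.0, 2.0, 3.0])
        fit = fit_group_model(y, ["g"] * 3, settings=FAST, fixed_tau=1.0)
        draws = fit.chains.pooled()[:, fit.chains.param_names.index("mu_g")]
        post_mean = 3 * 2.0 / (3 + 1e-6)
        post_sd = 1.0 / np.sqrt(3 + 1e-6)
        assert abs(draws.mean() - post_mean) < 3 * _mc_se(draws)
        assert draws.std() == pytest.approx(post_sd, rel=0.1)

    def test_identical_groups_symmetric_contrast(self):
        rng = np.random.default_rng(0)
        y = rng.normal(0, 1, 60)
        fit = fit_group_model(
            np.concatenate([y, y]), ["a"] * 60 + ["b"] * 60, settings=FAST
        )
        assert abs(fit.contrast_pp("a", "b") - 0.5) < 0.05

    def test_separated_groups_decisive_contrast(self):
        rng = np.random.default_rng(1)
        a = rng.normal(10.0, 1.0, 50)
        b = rng.normal(0.0, 1.0, 50)
        fit = fit_group_model(
            np.concatenate([a, b]), ["a"] * 50 + ["b"] * 50, settings=FAST
        )
        assert fit.contrast_pp("a", "b") > 0.99

    def test_unequal_variances_recovered(self):
        rng = np.random.default_rng(2)
        a = rng.normal(0.0, 0.5, 200)
        b = rng.normal(0.0, 3.0, 200)
        fit = fit_group_model(
            np.concatenate([a, b]), ["a"] * 200 + ["b"] * 200, settings=FAST
        )
        assert fit.sigma["a"].etpi_95[1] < fit.sigma["b"].etpi_95[0]

    def test_singleton_group_allowed_empty_rejected(self):
        fit = fit_group_model([1.0, 2.0, 3.0], ["a", "a", "b"], settings=FAST)
        assert "b" in fit.mu
        with pytest.raises(ValueError):
            fit_group_model([], [], settings=FAST)

    def test_seeded_determinism(self):
        y = np.arange(10.0)
        g = ["a"] * 5 + ["b"] * 5
        f1 = fit_group_model(y, g, settings=FAST)
        f2 = fit_group_model(y, g, settings=FAST)
        np.testing.assert_array_equal(f1.chains.draws, f2.chains.draws)


def _design(x):
    return pd.DataFrame({"intercept": np.ones(len(x)), "x": x})


class TestLinearModel:
    def test_noiseless_regression_concentrates_at_truth(self):
        x = np.linspace(0, 1, 50)
        y = 2.0 + 3.0 * x
        fit = fit_linear_model(y, _design(x), settings=FAST)
        assert fit.coefficients["intercept"].pm == pytest.approx(2.0, abs=0.01)
        assert fit.coefficients["x"].pm == pytest.approx(3.0, abs=0.01)
        lo, hi = fit.coefficients["x"].etpi_95
        assert lo <= 3.0 <= hi

    def test_conjugate_posterior_with_fixed_precision(self):
        rng = np.random.default_rng(3)
        x = rng.normal(size=40)
        y = 1.0 + 2.0 * x + rng.normal(size=40)
        design = _design(x)
        prior = PriorSpec()
        fit = fit_linear_model(y, design, prior, FAST, fixed_tau=1.0)
        # closed form: beta | y ~ N(V X'y, V), V = (X'X + tau0 I)^-1
        xm = design.to_numpy()
        v = np.linalg.inv(xm.T @ xm + prior.coef_precision * np.eye(2))
        mean = v @ (xm.T @ y)
        pooled = fit.chains.pooled()[:, :2]
        for j in range(2):
            assert abs(pooled[:, j].mean() - mean[j]) < 3 * _mc_se(pooled[:, j])
            assert pooled[:, j].std() == pytest.approx(np.sqrt(v[j, j]), rel=0.1)

    def test_huge_prior_precision_pins_coefficient(self):
        rng = np.random.default_rng(4)
        x = rng.normal(size=60)
        y = 5.0 + 0.0 * x + rng.normal(size=60, scale=0.5)
        strong = PriorSpec(coef_precision=1e8)
        fit = fit_linear_model(y - y.mean(), _design(x), strong, FAST)
        assert abs(fit.coefficients["x"].pm) < 0.01

    def test_recovery_within_three_posterior_sds(self):
        rng = np.random.default_rng(5)
        n = 100
        x = rng.normal(size=n)
        beta = (1.5, -2.0)
        y = beta[0] + beta[1] * x + rng.normal(size=n, scale=1.2)
        fit = fit_linear_model(y, _design(x), settings=FAST)
        pooled = fit.chains.pooled()
        for j, truth in enumerate(beta):
            sd = pooled[:, j].std()
            assert abs(fit.coefficients[list(fit.coefficients)[j]].pm - truth) < 3 * sd

    def test_rank_deficient_design_names_columns(self):
        x = np.ones(10)
        design = pd.DataFrame({"intercept": x, "copy": x})
        with pytest.raises(ValueError, match="copy"):
            fit_linear_model(np.zeros(10), design, settings=FAST)

    def test_thinning_bookkeeping(self):
        s = McmcSettings(n_chains=2, burn_in=100, n_iter=1000, thin=3, seed=0)
        fit = fit_linear_model(np.arange(10.0), _design(np.arange(10.0) ** 2), settings=s)
        assert fit.chains.draws.shape == (2, 1000 // 3, 3)


class TestLogisticModel:
    def test_balanced_intercept_near_zero(self):
        y = np.array([1, 1, 1, 1, 1, 0, 0, 0, 0, 0], dtype=float)
        design = pd.DataFrame({"intercept": np.ones(10)})
        fit = fit_logistic_model(y, design, settings=FAST)
        assert abs(fit.coefficients["intercept"].pm) < 0.3

    def test_recovery_at_study_effect_sizes(self):
        # generating coefficients are the survival-model defaults
        rng = np.random.default_rng(6)
        n = 2000
        pop = rng.integers(0, 2, n).astype(float)
        plant = rng.integers(0, 2, n).astype(float)
        beta = (-0.5, -0.56, -0.15)
        eta = beta[0] + beta[1] * pop + beta[2] * plant
        y = (rng.random(n) < 1 / (1 + np.exp(-eta))).astype(float)
        design = pd.DataFrame({"intercept": np.ones(n), "pop": pop, "plant": plant})
        fit = fit_logistic_model(y, design, settings=FAST)
        pooled = fit.chains.pooled()
        for j, truth in enumerate(beta):
            name = list(fit.coefficients)[j]
            sd = pooled[:, j].std()
            assert abs(fit.coefficients[name].pm - truth) < 3 * sd

    def test_degenerate_response_warns_and_shifts(self):
        y = np.ones(10)
        design = pd.DataFrame({"intercept": np.ones(10)})
        with pytest.warns(UserWarning, match="degenerate"):
            fit = fit_logistic_model(y, design, settings=FAST)
        assert fit.coefficients["intercept"].pm > 1.0

    def test_fitted_cell_probabilities(self):
        rng = np.random.default_rng(7)
        n = 400
        x = rng.integers(0, 2, n).astype(float)
        y = (rng.random(n) < np.where(x > 0, 0.8, 0.3)).astype(float)
        design = pd.DataFrame({"intercept": np.ones(n), "x": x})
        fit = fit_logistic_model(
            y, design, settings=FAST,
            cells={"x0": np.array([1.0, 0.0]), "x1": np.array([1.0, 1.0])},
        )
        assert fit.fitted_probabilities["x0"].pm == pytest.approx(0.3, abs=0.1)
        assert fit.fitted_probabilities["x1"].pm == pytest.approx(0.8, abs=0.1)


class TestSummaries:
    def test_median_and_tails(self):
        draws = np.array([1.0, 2.0, 3.0, 4.0, 5.0]).reshape(1, 5, 1)
        s = summarize(ChainSet(draws, ["p"]))["p"]
        assert s.pm == 3.0
        assert s.pp_gt0 == 1.0 and s.pp_lt0 == 0.0

    def test_symmetric_draws_half_positive(self):
        rng = np.random.default_rng(8)
        draws = rng.normal(size=(2, 5000, 1))
        s = summarize(ChainSet(draws, ["p"]))["p"]
        assert abs(s.pp_gt0 - 0.5) < 0.02
        assert s.pp_gt0 + s.pp_lt0 == pytest.approx(1.0)

    def test_normal_quantiles(self):
        rng = np.random.default_rng(9)
        draws = rng.standard_normal((1, 1_000_000, 1))
        s = summarize(ChainSet(draws, ["p"]))["p"]
        assert s.etpi_95[0] == pytest.approx(-1.96, abs=0.01)
        assert s.etpi_95[1] == pytest.approx(1.96, abs=0.01)
        assert s.etpi_95[0] <= s.pm <= s.etpi_95[1]


class TestDiagnostics:
    def test_gelman_rubin_identical_chains(self):
        rng = np.random.default_rng(10)
        one = rng.normal(size=(1, 500, 1))
        chains = ChainSet(np.repeat(one, 3, axis=0), ["p"])
        assert gelman_rubin(chains)["p"] == 1.0

    def test_gelman_rubin_iid_chains_near_one(self):
        rng = np.random.default_rng(11)
        chains = ChainSet(rng.normal(size=(3, 5000, 1)), ["p"])
        assert gelman_rubin(chains)["p"] < 1.01

    def test_gelman_rubin_divergent_chains_large(self):
        rng = np.random.default_rng(12)
        draws = rng.normal(size=(2, 1000, 1))
        draws[1] += 10.0
        assert gelman_rubin(ChainSet(draws, ["p"]))["p"] > 1.1

    def test_gelman_rubin_single_chain_rejected(self):
        with pytest.raises(ValueError, match="2 chains"):
            gelman_rubin(ChainSet(np.zeros((1, 10, 1)), ["p"]))

    def test_ess_iid(self):
        rng = np.random.default_rng(13)
        chains = ChainSet(rng.normal(size=(2, 5000, 1)), ["p"])
        ess = effective_sample_size(chains)["p"]
        assert abs(ess - 10_000) < 1000

    def test_ess_ar1(self):
        rho, n = 0.9, 20_000
        rng = np.random.default_rng(14)
        x = np.empty(n)
        x[0] = rng.normal()
        for t in range(1, n):
            x[t] = rho * x[t - 1] + rng.normal() * np.sqrt(1 - rho**2)
        ess = effective_sample_size(ChainSet(x.reshape(1, n, 1), ["p"]))["p"]
        expected = n * (1 - rho) / (1 + rho)
        assert expected / 1.5 < ess < expected * 1.5

    def test_ess_constant_chain_zero_with_warning(self):
        with pytest.warns(UserWarning, match="constant"):
            ess = effective_sample_size(ChainSet(np.ones((1, 100, 1)), ["p"]))["p"]
        assert ess == 0.0


class TestDic:
    def test_degenerate_chain_has_zero_pd(self):
        draws = np.full((1, 50, 1), 2.0)
        ll = np.full((1, 50), -10.0)
        chains = ChainSet(draws, ["p"], ll, loglik_at=lambda theta: -10.0)
        dic_val, pd_eff, dbar = dic(chains)
        assert pd_eff == pytest.approx(0.0)
        assert dic_val == pytest.approx(dbar) == pytest.approx(20.0)

    def test_normal_mean_model_pd_near_one(self):
        rng = np.random.default_rng(15)
        y = rng.normal(3.0, 1.0, 100)
        fit = fit_group_model(y, ["g"] * 100, settings=FAST, fixed_tau=1.0)
        _, pd_eff, _ = dic(fit.chains)
        assert pd_eff == pytest.approx(1.0, abs=0.3)

    def test_extra_junk_covariates_raise_pd(self):
        rng = np.random.default_rng(16)
        diffs = []
        fast = McmcSettings(n_chains=2, burn_in=200, n_iter=1200, thin=3, seed=1)
        for rep in range(20):
            rng_rep = np.random.default_rng(100 + rep)
            n = 60
            y = rng_rep.normal(size=n)
            small = pd.DataFrame({"intercept": np.ones(n)})
            big = small.copy()
            for k in range(3):
                big[f"junk{k}"] = rng_rep.normal(size=n)
            import dataclasses

            f_small = fit_linear_model(y, small, settings=dataclasses.replace(fast, seed=rep))
            f_big = fit_linear_model(y, big, settings=dataclasses.replace(fast, seed=500 + rep))
            diffs.append(f_big.pd_eff - f_small.pd_eff)
        assert np.mean(diffs) == pytest.approx(3.0, abs=1.0)

    def test_missing_loglik_rejected(self):
        with pytest.raises(ValueError, match="log-likelihood"):
            dic(ChainSet(np.zeros((1, 10, 1)), ["p"]))
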