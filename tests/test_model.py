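"""Gibbs sampler correctness: oracles, identities, diagnostics, reproducibility."""

import numpy as np
import pytest

from promediate import (
    CohortConfig,
    MCMCConfig,
    MediationParams,
    PriorSpec,
    closed_form_posterior,
    derive_effects,
    fit_mediation,
    simulate_ground_truth,
    summarize,
)
from promediate.extraction import AnalysisTable, ExtractedRecord
from promediate.model import PosteriorDraws, SUMMARY_QUANTITIES, outcome_design
from promediate.errors import ConfigError, DegenerateDesignError, RankDeficiencyError


def _table_from_truth(cfg):
    return AnalysisTable.from_ground_truth(simulate_ground_truth(cfg))


def _table(n=40, seed=0, **param_kw):
    params = MediationParams(**param_kw) if param_kw else MediationParams()
    return _table_from_truth(CohortConfig(n_subjects=n, params=params, seed=seed))


class TestFitMediation:
    def test_noiseless_limit_recovers_truth(self, quick_mcmc):
        # sigma_m stays a few orders above sigma_y: with *both* at zero the
        # mediator is an exact linear function of (1, x) and b is unidentified
        p = MediationParams(sigma_m=1e-3, sigma_y=1e-6)
        table = _table_from_truth(CohortConfig(n_subjects=200, params=p, seed=1))
        s = summarize(fit_mediation(table, mcmc=quick_mcmc)).table
        assert s.loc["a", "mean"] == pytest.approx(p.a, abs=0.02)
        assert s.loc["b", "mean"] == pytest.approx(p.b, abs=0.02)
        assert s.loc["cprime", "mean"] == pytest.approx(p.c_prime, abs=0.02)

    def test_matches_closed_form_with_fixed_variance(self):
        # with both residual variances frozen the coefficient draws are exact
        # iid samples from the conjugate Gaussian posterior
        table = _table(n=40, seed=2)
        priors = PriorSpec()
        mcmc = MCMCConfig(n_chains=2, n_draws=4000, n_burn_in=100, seed=3)
        draws = fit_mediation(table, priors=priors, mcmc=mcmc,
                              fixed_sigma2_m=0.25, fixed_sigma2_y=0.25)
        Xy, y = outcome_design(table)
        mean, cov = closed_form_posterior(Xy, y, priors, fixed_sigma2=0.25)
        n_total = 2 * 4000
        for i, name in enumerate(["iy", "cprime", "d", "b"]):
            sd = np.sqrt(cov[i, i])
            mcse = sd / np.sqrt(n_total)
            assert abs(draws.stacked(name).mean() - mean[i]) < 3 * mcse
            assert draws.stacked(name).std() == pytest.approx(sd, rel=0.05)

    def test_reproducible_given_seed(self, small_table, quick_mcmc):
        d1 = fit_mediation(small_table, mcmc=quick_mcmc)
        d2 = fit_mediation(small_table, mcmc=quick_mcmc)
        d3 = fit_mediation(small_table, mcmc=MCMCConfig(
            n_chains=2, n_draws=800, n_burn_in=300, seed=99))
        for name in SUMMARY_QUANTITIES:
            assert np.array_equal(d1.draws[name], d2.draws[name])
        assert not np.array_equal(d1.draws["a"], d3.draws["a"])

    def test_single_arm_is_degenerate(self, quick_mcmc):
        rows = tuple(
            ExtractedRecord(subject_id=f"S{i}", x=1, y=2.0 + i, z=5.0 + i, m=1.0 + i, branch="yes")
            for i in range(10)
        )
        with pytest.raises(DegenerateDesignError):
            fit_mediation(AnalysisTable(rows=rows), mcmc=quick_mcmc)

    def test_constant_covariate_is_rank_deficient(self, quick_mcmc):
        table = _table_from_truth(CohortConfig(n_subjects=20, z_sd=0.0, seed=4))
        with pytest.raises(RankDeficiencyError):
            fit_mediation(table, mcmc=quick_mcmc)

    def test_too_few_subjects(self, quick_mcmc):
        table = AnalysisTable(rows=tuple(
            ExtractedRecord(subject_id=f"S{i}", x=i % 2, y=1.0, z=2.0, m=3.0, branch="no")
            for i in range(4)
        ))
        with pytest.raises(ConfigError):
            fit_mediation(table, mcmc=quick_mcmc)

    def test_weak_prior_insensitivity(self, quick_mcmc):
        # at n=75 widening coef_sd from 10 to 100 barely moves posterior means
        table = _table(n=75, seed=6)
        m10 = summarize(fit_mediation(table, priors=PriorSpec(coef_sd=10.0), mcmc=quick_mcmc)).table["mean"]
        m100 = summarize(fit_mediation(table, priors=PriorSpec(coef_sd=100.0), mcmc=quick_mcmc)).table["mean"]
        for name in SUMMARY_QUANTITIES:
            assert abs(m100[name] - m10[name]) < 0.10 * max(abs(m10[name]), 0.1)

    def test_posterior_error_shrinks_with_sample_size(self, quick_mcmc):
        # mean absolute error over a 20-seed family decreases from n=75 to
        # 5000 for every parameter (single-seed errors are too noisy to order)
        truth = MediationParams()
        true_map = {"a": truth.a, "b": truth.b, "cprime": truth.c_prime,
                    "d": truth.d, "im": truth.i_m, "iy": truth.i_y,
                    "sigma_m": truth.sigma_m, "sigma_y": truth.sigma_y}
        errors = {}
        for n in (75, 500, 5000):
            per_param = {k: [] for k in true_map}
            for seed in range(101, 121):
                table = _table_from_truth(CohortConfig(n_subjects=n, seed=seed))
                s = summarize(fit_mediation(table, mcmc=quick_mcmc)).table
                for k, g in true_map.items():
                    per_param[k].append(abs(s.loc[k, "mean"] - g))
            errors[n] = {k: np.mean(v) for k, v in per_param.items()}
        for k in true_map:
            assert errors[75][k] > errors[500][k] > errors[5000][k]


class TestClosedFormPosterior:
    def _data(self, n=25, p=3, seed=0):
        rng = np.random.default_rng(seed)
        X = np.column_stack([np.ones(n), rng.standard_normal((n, p))])
        beta = rng.standard_normal(p + 1)
        y = X @ beta + 0.5 * rng.standard_normal(n)
        return X, y

    def test_flat_prior_limit_is_least_squares(self):
        X, y = self._data()
        mean, _ = closed_form_posterior(X, y, PriorSpec(coef_sd=1e8), fixed_sigma2=0.25)
        ols, *_ = np.linalg.lstsq(X, y, rcond=None)
        assert mean == pytest.approx(ols, abs=1e-6)

    def test_degenerate_prior_limit_is_the_prior_mean(self):
        X, y = self._data()
        mean, _ = closed_form_posterior(
            X, y, PriorSpec(coef_mean=1.5, coef_sd=1e-6), fixed_sigma2=0.25)
        assert mean == pytest.approx(np.full(4, 1.5), abs=1e-4)

    def test_mean_matches_grid_search_density_maximizer(self):
        # the Gaussian posterior mode (= mean) found by brute-force grid search
        X, y = self._data(n=25, p=3, seed=7)
        priors = PriorSpec()
        sigma2 = 0.25
        mean, _ = closed_form_posterior(X, y, priors, fixed_sigma2=sigma2)

        step = 0.02
        axes = [np.arange(mu - 0.2, mu + 0.2 + step / 2, step) for mu in np.round(mean, 1)]
        grids = np.meshgrid(*axes, indexing="ij")
        betas = np.stack([g.ravel() for g in grids], axis=1)  # (n_grid, 4)
        resid = y[None, :] - betas @ X.T
        log_post = (
            -0.5 * np.sum(resid**2, axis=1) / sigma2
            - 0.5 * np.sum((betas - priors.coef_mean) ** 2, axis=1) / priors.coef_sd**2
        )
        best = betas[np.argmax(log_post)]
        assert best == pytest.approx(mean, abs=step)

    def test_rank_deficient_design_rejected(self):
        X = np.column_stack([np.ones(10), np.ones(10)])
        with pytest.raises(RankDeficiencyError):
            closed_form_posterior(X, np.arange(10.0), PriorSpec(), fixed_sigma2=1.0)

    def test_requires_positive_variance(self):
        X, y = self._data()
        with pytest.raises(ConfigError):
            closed_form_posterior(X, y, PriorSpec(), fixed_sigma2=0.0)


class TestDeriveEffects:
    def test_pointwise_examples(self):
        draws = {
            "a": np.array([[0.0, 0.4]]),
            "b": np.array([[5.0, 0.5]]),
            "cprime": np.array([[1.2, 0.3]]),
        }
        out = derive_effects(draws)
        assert out["indirect"][0, 0] == 0.0 and out["total"][0, 0] == 1.2
        assert out["indirect"][0, 1] == pytest.approx(0.20)
        assert out["total"][0, 1] == pytest.approx(0.50)

    def test_identity_holds_for_every_draw(self, small_table, quick_mcmc):
        d = fit_mediation(small_table, mcmc=quick_mcmc).draws
        assert np.array_equal(d["direct"], d["cprime"])
        assert np.array_equal(d["indirect"], d["a"] * d["b"])
        assert np.array_equal(d["total"], d["direct"] + d["indirect"])
        assert d["total"].mean() == pytest.approx(
            d["direct"].mean() + d["indirect"].mean(), abs=1e-12)

    def test_missing_parameter_rejected(self):
        with pytest.raises(ConfigError):
            derive_effects({"a": np.zeros((1, 10))})


def _pseudo_draws(array_2d):
    """Wrap identical (chain, draw) arrays for all quantities."""
    draws = {name: array_2d.copy() for name in ("a", "b", "cprime", "d", "im", "iy", "sigma_m", "sigma_y")}
    return PosteriorDraws(
        draws=derive_effects(draws), priors=PriorSpec(),
        mcmc=MCMCConfig(n_chains=array_2d.shape[0], n_draws=max(array_2d.shape[1], 500)),
        data_hash="synthetic",
    )


class TestSummarize:
    def test_constant_draws_collapse_interval(self):
        s = summarize(_pseudo_draws(np.full((2, 500), 2.0)))
        row = s.table.loc["a"]
        assert row["mean"] == 2.0
        assert row["ci_lower"] == 2.0 and row["ci_upper"] == 2.0
        assert s.converged

    def test_gaussian_draws_hit_the_normal_quantiles(self):
        rng = np.random.default_rng(12)
        s = summarize(_pseudo_draws(rng.standard_normal((4, 2500))))
        row = s.table.loc["a"]
        assert row["ci_lower"] == pytest.approx(-1.96, abs=0.08)
        assert row["ci_upper"] == pytest.approx(1.96, abs=0.08)

    def test_disjoint_chains_flag_nonconvergence(self):
        rng = np.random.default_rng(3)
        arr = np.vstack([
            rng.standard_normal((1, 1000)),
            10.0 + rng.standard_normal((1, 1000)),
        ])
        s = summarize(_pseudo_draws(arr))
        assert s.table.loc["a", "rhat"] > 1.05
        assert not s.converged

    def test_invalid_level_rejected(self):
        with pytest.raises(ConfigError):
            summarize(_pseudo_draws(np.zeros((2, 500))), level=1.5)
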