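"""Sampler correctness: oracle comparisons and distributional checks."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import smallarea as sa


def quadrature_posterior_means(data, x, prior_beta_var=1e5,
                               half_width=4.0, n_grid=801):
    """Dense 2-D grid integration of the no-random-effect posterior.

    Independent oracle for the intercept-plus-one-covariate Poisson model
    with flat alpha and N(0, prior_beta_var) on beta.
    """
    O, E = data.observed, data.expected
    # center the grid roughly on the MLE via a crude profile
    a_grid = np.linspace(-half_width, half_width, n_grid)
    b_grid = np.linspace(-half_width, half_width, n_grid)
    A, B = np.meshgrid(a_grid, b_grid, indexing="ij")
    logpost = -0.5 * B**2 / prior_beta_var
    for i in range(len(O)):
        eta = A + B * x[i]
        logpost += O[i] * (np.log(E[i]) + eta) - E[i] * np.exp(eta)
    logpost -= logpost.max()
    w = np.exp(logpost)
    w /= w.sum()
    return float((w * A).sum()), float((w * B).sum())


class TestAgainstQuadratureOracle:
    def test_three_area_posterior_means(self, toy_table):
        spec = sa.ModelSpec(covariate_names=["x"], include_spatial=False,
                            include_heterogeneity=False)
        cfg = sa.MCMCConfig(n_iter=42_000, burn_in=2_000, n_chains=2, thin=2,
                            seed=31)
        s = sa.run_mcmc(toy_table, None, spec, cfg)
        a_hat, b_hat = quadrature_posterior_means(
            toy_table, toy_table.covariates["x"].to_numpy())
        for name, draws, oracle in [
                ("alpha", s.stacked("alpha"), a_hat),
                ("beta", s.stacked("beta")[:, 0], b_hat)]:
            ess = sa.effective_sample_size(
                draws.reshape(s.n_chains, s.n_draws))
            mcse = draws.std() / np.sqrt(ess)
            assert abs(draws.mean() - oracle) < 3 * mcse, name


class TestDegenerateGLMLimit:
    def test_matches_poisson_mle_without_random_effects(self, default_dataset):
        # with both random effects off and vague priors the posterior mean
        # should sit within 2 posterior SDs of the frequentist Poisson MLE
        import statsmodels.api as sm

        data = sa.compute_expected(default_dataset.area_table)
        names = ["immigration", "policing", "physical_disorder"]
        spec = sa.ModelSpec(covariate_names=names, include_spatial=False,
                            include_heterogeneity=False)
        cfg = sa.MCMCConfig(n_iter=20_000, burn_in=2_000, n_chains=2, thin=5,
                            seed=5)
        s = sa.run_mcmc(data, None, spec, cfg)
        X = sm.add_constant(data.covariate_matrix(names))
        glm = sm.GLM(data.observed, X, family=sm.families.Poisson(),
                     offset=np.log(data.expected)).fit()
        post = np.column_stack([s.stacked("alpha"), s.stacked("beta")])
        for k, name in enumerate(["intercept"] + names):
            mean, sd = post[:, k].mean(), post[:, k].std()
            assert abs(mean - glm.params[k]) < 2 * sd, name


class TestSamplerBehavior:
    def test_acceptance_rates_in_band(self, default_fit):
        _, _, samples = default_fit
        for block, rate in samples.acceptance.items():
            assert 0.2 <= rate <= 0.6, (block, rate)

    def test_reproducible_given_seed(self, toy_table):
        spec = sa.ModelSpec(covariate_names=["x"], include_spatial=False,
                            include_heterogeneity=False)
        cfg = sa.MCMCConfig(n_iter=2_000, burn_in=500, n_chains=2, thin=5, seed=9)
        s1 = sa.run_mcmc(toy_table, None, spec, cfg)
        s2 = sa.run_mcmc(toy_table, None, spec, cfg)
        assert np.array_equal(s1.stacked("alpha"), s2.stacked("alpha"))
        assert np.array_equal(s1.stacked("beta"), s2.stacked("beta"))

    def test_spatial_model_requires_matching_graph(self, toy_table):
        spec = sa.ModelSpec(covariate_names=["x"])
        cfg = sa.MCMCConfig(n_iter=1_000, burn_in=100, seed=1)
        with pytest.raises(ValueError, match="graph"):
            sa.run_mcmc(toy_table, None, spec, cfg)
        big = sa.lattice_graph(2, 3, "rook")
        with pytest.raises(ValueError, match="size"):
            sa.run_mcmc(toy_table, big, spec, cfg)

    def test_island_graph_rejected_for_fitting(self):
        t = sa.compute_expected(sa.AreaTable(
            area_id=["a", "b", "c"], observed=np.array([1, 2, 3]),
            population=np.array([10, 10, 10]),
            covariates=pd.DataFrame({"x": [0.0, 0.1, 0.2]})))
        g = sa.AdjacencyGraph([np.array([1]), np.array([0]), np.array([])])
        spec = sa.ModelSpec(covariate_names=["x"])
        with pytest.raises(ValueError, match="isolated"):
            sa.run_mcmc(t, g, spec, sa.MCMCConfig(n_iter=1_000, burn_in=100, seed=1))


@pytest.fixture(scope="module")
def prior_draws():
    rng = np.random.default_rng(12)
    t = sa.compute_expected(sa.AreaTable(
        area_id=[str(i) for i in range(12)],
        observed=rng.integers(1, 6, 12),
        population=rng.integers(100, 500, 12),
        covariates=pd.DataFrame({"x": rng.normal(size=12)})))
    g = sa.lattice_graph(3, 4, "rook")
    spec = sa.ModelSpec(covariate_names=["x"])
    cfg = sa.MCMCConfig(n_iter=1_010_000, burn_in=10_000, n_chains=2,
                        thin=20, seed=21, prior_only=True)
    return sa.run_mcmc(t, g, spec, cfg)


class TestPriorOnly:
    """With the likelihood switched off the sampler must reproduce its priors."""

    def test_beta_variance_matches_prior(self, prior_draws):
        beta = prior_draws.stacked("beta")[:50_000, 0]
        assert beta.var() == pytest.approx(1e5, rel=0.05)

    def test_sigma_draws_uniform(self, prior_draws):
        # the KS test assumes independent draws; the sigmas mix slowly under
        # random-walk MH, so it runs on draws 2,000 sweeps apart, where the
        # measured lag autocorrelation is ~0.04
        for name in ("sigma_S", "sigma_H"):
            draws = prior_draws.stacked(name)[::100]
            d, p = stats.kstest(draws, "uniform")
            assert p > 0.01, (name, d, p)

    def test_loglik_not_reported(self, prior_draws):
        assert np.isnan(prior_draws.stacked("loglik")).all()
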