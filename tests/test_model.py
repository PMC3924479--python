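import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import smallarea as sa
from smallarea.model import ParameterState


def _state(n, p, alpha=0.0, beta=None, S=None, H=None, sS=0.5, sH=0.5):
    return ParameterState(alpha=alpha,
                          beta=np.zeros(p) if beta is None else np.asarray(beta, float),
                          S=np.zeros(n) if S is None else np.asarray(S, float),
                          H=np.zeros(n) if H is None else np.asarray(H, float),
                          sigma_S=sS, sigma_H=sH)


class TestLogLikelihood:
    def test_unit_rate_zero_count(self):
        t = sa.AreaTable(area_id=["a"], observed=np.array([0]),
                         population=np.array([100]),
                         covariates=pd.DataFrame({"x": [0.0]}),
                         expected=np.array([1.0]))
        assert sa.log_likelihood(_state(1, 1), t) == pytest.approx(-1.0)

    def test_additivity_over_identical_areas(self):
        t1 = sa.AreaTable(area_id=["a"], observed=np.array([3]),
                          population=np.array([100]),
                          covariates=pd.DataFrame({"x": [0.4]}),
                          expected=np.array([3.0]))
        t2 = sa.AreaTable(area_id=["a", "b"], observed=np.array([3, 3]),
                          population=np.array([100, 100]),
                          covariates=pd.DataFrame({"x": [0.4, 0.4]}),
                          expected=np.array([3.0, 3.0]))
        s1 = _state(1, 1, alpha=0.2, beta=[0.3])
        s2 = _state(2, 1, alpha=0.2, beta=[0.3])
        assert sa.log_likelihood(s2, t2) == pytest.approx(2 * sa.log_likelihood(s1, t1))

    def test_matches_scipy_poisson_logpmf(self):
        rng = np.random.default_rng(4)
        n, p = 5, 2
        t = sa.AreaTable(area_id=[str(i) for i in range(n)],
                         observed=np.array([1, 0, 4, 2, 3]),
                         population=np.full(n, 100),
                         covariates=pd.DataFrame(rng.normal(size=(n, p)),
                                                 columns=["u", "v"]),
                         expected=np.full(n, 2.0))
        st_ = _state(n, p, alpha=0.1, beta=rng.normal(size=p) * 0.2,
                     S=rng.normal(size=n) * 0.3, H=rng.normal(size=n) * 0.1)
        mu = t.expected * np.exp(st_.alpha + t.covariate_matrix() @ st_.beta
                                 + st_.S + st_.H)
        oracle = stats.poisson.logpmf(t.observed, mu).sum()
        assert sa.log_likelihood(st_, t) == pytest.approx(oracle, abs=1e-10)

    def test_missing_expected_raises(self):
        t = sa.AreaTable(area_id=["a"], observed=np.array([1]),
                         population=np.array([10]),
                         covariates=pd.DataFrame({"x": [0.0]}))
        with pytest.raises(ValueError, match="expected"):
            sa.log_likelihood(_state(1, 1), t)


class TestICARConditional:
    def test_direct_evaluation(self):
        g = sa.AdjacencyGraph([np.array([1, 2, 3]), np.array([0]),
                               np.array([0]), np.array([0])])
        m, v = sa.icar_conditional(0, np.array([0.0, 1.0, 2.0, 3.0]), g, 0.6)
        assert m == pytest.approx(2.0)
        assert v == pytest.approx(0.12)

    def test_constant_field_has_constant_mean(self, path3):
        m, _ = sa.icar_conditional(1, np.full(3, 1.7), path3, 1.0)
        assert m == pytest.approx(1.7)

    def test_island_raises(self):
        g = sa.AdjacencyGraph([np.array([1]), np.array([0]), np.array([])])
        with pytest.raises(ValueError, match="no neighbors"):
            sa.icar_conditional(2, np.zeros(3), g, 1.0)

    def test_conditionals_consistent_with_joint(self, path3):
        # Brook's-lemma consistency on the 3-node path: changing one site's
        # value changes the joint pairwise-difference density by exactly the
        # ratio of that site's normal full conditional.
        sigma = 0.8

        def log_joint(S):
            e = sa.icar_structure(path3)
            return -0.5 * S @ e @ S / sigma**2

        grid = [-1.0, -0.2, 0.5, 1.3]
        S = np.array([0.4, -0.1, 0.9])
        for i in range(3):
            for new in grid:
                S2 = S.copy()
                S2[i] = new
                m, v = sa.icar_conditional(i, S, path3, sigma)
                lhs = log_joint(S2) - log_joint(S)
                rhs = (stats.norm.logpdf(new, m, np.sqrt(v))
                       - stats.norm.logpdf(S[i], m, np.sqrt(v)))
                assert lhs == pytest.approx(rhs, abs=1e-10)


class TestLogPrior:
    def test_sigma_outside_support(self, path3):
        spec = sa.ModelSpec(covariate_names=["x"])
        st_ = _state(3, 1, sS=1.5)
        assert sa.log_prior(st_, spec, path3) == -math.inf
        st_ = _state(3, 1, sH=-0.1)
        assert sa.log_prior(st_, spec, path3) == -math.inf

    def test_constant_field_no_quadratic_penalty(self, path3):
        spec = sa.ModelSpec(covariate_names=["x"])
        lp_flat = sa.log_prior(_state(3, 1, S=[0.5, 0.5, 0.5]), spec, path3)
        lp_zero = sa.log_prior(_state(3, 1, S=[0, 0, 0]), spec, path3)
        assert lp_flat == pytest.approx(lp_zero)

    def test_path_quadratic_term(self, path3):
        # S = (-1, 0, 1), sigma_S = 1: edges contribute (1 + 1)/2 = 1
        spec = sa.ModelSpec(covariate_names=["x"])
        lp = sa.log_prior(_state(3, 1, S=[-1, 0, 1], sS=1.0), spec, path3)
        lp0 = sa.log_prior(_state(3, 1, sS=1.0), spec, path3)
        assert lp0 - lp == pytest.approx(1.0, abs=1e-12)
        # cross-check against the Q-form -1/2 S'QS
        Q = sa.icar_structure(path3)
        S = np.array([-1.0, 0.0, 1.0])
        assert 0.5 * S @ Q @ S == pytest.approx(1.0)

    def test_joint_invariant_to_alpha_s_tradeoff(self, toy_table, path3):
        # adding c to every S_i and subtracting it from alpha leaves the
        # joint log posterior unchanged (the ICAR quadratic sees only
        # differences and the likelihood sees only alpha + S)
        spec = sa.ModelSpec(covariate_names=["x"])
        rng = np.random.default_rng(0)
        st1 = _state(3, 1, alpha=0.3, beta=[0.2], S=rng.normal(size=3),
                     H=rng.normal(size=3) * 0.1, sS=0.4, sH=0.3)
        c = 0.73
        st2 = ParameterState(st1.alpha - c, st1.beta, st1.S + c, st1.H,
                             st1.sigma_S, st1.sigma_H)
        j1 = sa.log_likelihood(st1, toy_table) + sa.log_prior(st1, spec, path3)
        j2 = sa.log_likelihood(st2, toy_table) + sa.log_prior(st2, spec, path3)
        assert j1 == pytest.approx(j2, abs=1e-9)


class TestConfigContracts:
    def test_burn_in_must_be_less_than_n_iter(self):
        with pytest.raises(ValueError, match="burn_in"):
            sa.MCMCConfig(n_iter=1000, burn_in=1000)

    def test_model_spec_validation(self):
        with pytest.raises(ValueError):
            sa.ModelSpec(covariate_names=[], prior_beta_variance=0.0)
        with pytest.raises(ValueError):
            sa.ModelSpec(covariate_names=[], sigma_upper=-1.0)
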