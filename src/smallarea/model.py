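"""The Poisson BYM-type model: likelihood, priors, and the MCMC driver.

Three nested models share one likelihood, O_i ~ Poisson(lambda_i E_i) with

    log lambda_i = alpha + X_i beta + S_i + H_i ,

where S is a spatially structured random effect with an intrinsic CAR
prior (each S_i conditionally normal around the mean of its neighbors with
variance sigma_S^2 / n_i) and H is exchangeable N(0, sigma_H^2) noise
absorbing extra-Poisson dispersion.  Model 1 drops both random effects;
the spatial models carry both.

Priors: flat (improper) on alpha, vague N(0, 1e5) on each regression
coefficient, U(0, 1) on both standard deviations.  The ICAR prior is
improper; identifiability of alpha is restored by recentering S to zero
mean per connected component each sweep, with the grand mean absorbed
into alpha.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.special import gammaln

from . import _kernel
from .graph import AdjacencyGraph
from .io import AreaTable

__all__ = [
    "ModelSpec",
    "MCMCConfig",
    "ParameterState",
    "PosteriorSamples",
    "log_likelihood",
    "icar_conditional",
    "log_prior",
    "run_mcmc",
]

ACCEPT_BLOCKS = ("alpha", "beta", "S", "H", "sigma_S", "sigma_H")


@dataclass
class ModelSpec:
    """Which terms enter the linear predictor, and their hyperpriors."""

    covariate_names: list[str]
    include_spatial: bool = True
    include_heterogeneity: bool = True
    prior_beta_variance: float = 1e5
    sigma_upper: float = 1.0
    covariate_scaling: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.prior_beta_variance <= 0:
            raise ValueError("prior_beta_variance must be positive")
        if self.sigma_upper <= 0:
            raise ValueError("sigma_upper must be positive")


@dataclass
class MCMCConfig:
    n_iter: int = 100_000
    burn_in: int = 10_000
    n_chains: int = 2
    thin: int = 10
    seed: int = 0
    adapt_interval: int = 50
    target_accept: float = 0.44
    prior_only: bool = False
    init_jitter: float = 0.1

    def __post_init__(self) -> None:
        if self.burn_in >= self.n_iter:
            raise ValueError("burn_in must be smaller than n_iter")
        if self.thin < 1:
            raise ValueError("thin must be >= 1")
        if self.n_chains < 1:
            raise ValueError("need at least one chain")


@dataclass
class ParameterState:
    """One point in parameter space (used for initialization and plug-ins)."""

    alpha: float
    beta: np.ndarray
    S: np.ndarray
    H: np.ndarray
    sigma_S: float
    sigma_H: float


class PosteriorSamples:
    """Post-burn-in, thinned MCMC draws, per chain.

    Arrays are indexed (chain, draw[, component]).  ``loglik`` stores the
    full Poisson log likelihood (including the log O_i! constant, so the
    deviance matches the usual full-deviance convention) at every retained
    draw.
    """

    def __init__(self, alpha, beta, S, H, sigma_S, sigma_H, loglik,
                 acceptance, spec: ModelSpec, config: MCMCConfig,
                 covariate_names: list[str]):
        self.alpha = alpha
        self.beta = beta
        self.S = S
        self.H = H
        self.sigma_S = sigma_S
        self.sigma_H = sigma_H
        self.loglik = loglik
        self.acceptance = acceptance
        self.spec = spec
        self.config = config
        self.covariate_names = list(covariate_names)

    @property
    def n_chains(self) -> int:
        return self.alpha.shape[0]

    @property
    def n_draws(self) -> int:
        return self.alpha.shape[1]

    def stacked(self, name: str) -> np.ndarray:
        """Draws for one parameter family with chains concatenated."""
        arr = getattr(self, name)
        return arr.reshape(arr.shape[0] * arr.shape[1], *arr.shape[2:])

    def scalar_chains(self) -> dict[str, np.ndarray]:
        """(chain, draw) arrays for every scalar parameter, for diagnostics."""
        out = {"alpha": self.alpha}
        for k, name in enumerate(self.covariate_names):
            out[f"beta_{name}"] = self.beta[:, :, k]
        if self.spec.include_spatial:
            out["sigma_S"] = self.sigma_S
        if self.spec.include_heterogeneity:
            out["sigma_H"] = self.sigma_H
        return out

    def posterior_mean_state(self) -> ParameterState:
        return ParameterState(
            alpha=float(self.stacked("alpha").mean()),
            beta=self.stacked("beta").mean(axis=0),
            S=self.stacked("S").mean(axis=0),
            H=self.stacked("H").mean(axis=0),
            sigma_S=float(self.stacked("sigma_S").mean()),
            sigma_H=float(self.stacked("sigma_H").mean()),
        )

    def to_dataframe(self):
        import pandas as pd

        rows = {"chain": np.repeat(np.arange(self.n_chains), self.n_draws),
                "draw": np.tile(np.arange(self.n_draws), self.n_chains),
                "alpha": self.stacked("alpha")}
        for k, name in enumerate(self.covariate_names):
            rows[f"beta_{name}"] = self.stacked("beta")[:, k]
        rows["sigma_S"] = self.stacked("sigma_S")
        rows["sigma_H"] = self.stacked("sigma_H")
        rows["loglik"] = self.stacked("loglik")
        df = pd.DataFrame(rows)
        S, H = self.stacked("S"), self.stacked("H")
        for i in range(S.shape[1]):
            df[f"S_{i}"] = S[:, i]
            df[f"H_{i}"] = H[:, i]
        return df


# ---------------------------------------------------------------------------
# densities


def _linear_predictor(state: ParameterState, X: np.ndarray) -> np.ndarray:
    return state.alpha + X @ state.beta + state.S + state.H


def log_likelihood(state: ParameterState, data: AreaTable,
                   X: np.ndarray | None = None) -> float:
    """Poisson log likelihood sum_i [O_i log(lambda_i E_i) - lambda_i E_i - log O_i!]."""
    if data.expected is None:
        raise ValueError("expected counts E_i are missing; run compute_expected first")
    if X is None:
        X = data.covariate_matrix()
    eta = _linear_predictor(state, X)
    mu = data.expected * np.exp(eta)
    O = data.observed
    return float(np.sum(O * np.log(mu) - mu - gammaln(O + 1.0)))


def icar_conditional(i: int, S: np.ndarray, graph: AdjacencyGraph,
                     sigma_S: float) -> tuple[float, float]:
    """Full conditional of S_i under the intrinsic CAR.

    Mean is the average of the neighbors' values; variance is
    sigma_S^2 / n_i.  Undefined (raises) for an isolated area.
    """
    nb = graph.neighbors[i]
    if len(nb) == 0:
        raise ValueError(f"area {i} has no neighbors; the CAR conditional is undefined")
    return float(S[nb].mean()), float(sigma_S**2 / len(nb))


def icar_log_density(S: np.ndarray, graph: AdjacencyGraph, sigma_S: float,
                     n_components: int | None = None) -> float:
    """Improper ICAR log density on the sum-to-zero subspace (up to a constant):

        -(n - c) log sigma_S - (1 / 2 sigma_S^2) sum_{i~j, i<j} (S_i - S_j)^2
    """
    if n_components is None:
        n_components, _ = graph.components()
    edges = graph.edges()
    quad = float(np.sum((S[edges[:, 0]] - S[edges[:, 1]]) ** 2)) if len(edges) else 0.0
    rank = graph.n_areas - n_components
    return -rank * math.log(sigma_S) - quad / (2.0 * sigma_S**2)


def log_prior(state: ParameterState, spec: ModelSpec,
              graph: AdjacencyGraph | None) -> float:
    """Joint log prior; returns -inf outside the support.

    alpha is flat (contributes 0); beta_k ~ N(0, prior_beta_variance);
    S has the improper ICAR density; H_i ~ N(0, sigma_H^2) i.i.d.;
    sigma_S, sigma_H ~ U(0, sigma_upper).
    """
    lp = 0.0
    v = spec.prior_beta_variance
    lp += float(np.sum(-0.5 * state.beta**2 / v - 0.5 * math.log(2 * math.pi * v)))
    if spec.include_spatial:
        if not (0.0 < state.sigma_S <= spec.sigma_upper):
            return -math.inf
        if graph is None:
            raise ValueError("spatial prior requires an adjacency graph")
        lp += icar_log_density(state.S, graph, state.sigma_S)
    if spec.include_heterogeneity:
        if not (0.0 < state.sigma_H <= spec.sigma_upper):
            return -math.inf
        sh2 = state.sigma_H**2
        lp += float(np.sum(-0.5 * state.H**2 / sh2
                           - 0.5 * math.log(2 * math.pi * sh2)))
    return lp


# ---------------------------------------------------------------------------
# sampler driver


def _initial_state(data: AreaTable, p: int, rng: np.random.Generator,
                   jitter: float) -> ParameterState:
    # alpha at the log crude relative risk (0 under internal standardization),
    # jittered per chain for honestly overdispersed starting points
    a0 = math.log(data.observed.sum() / data.expected.sum())
    return ParameterState(
        alpha=a0 + jitter * rng.standard_normal(),
        beta=jitter * 0.1 * rng.standard_normal(p),
        S=np.zeros(data.n_areas),
        H=np.zeros(data.n_areas),
        sigma_S=float(np.clip(0.5 + jitter * rng.standard_normal(), 0.05, 0.95)),
        sigma_H=float(np.clip(0.5 + jitter * rng.standard_normal(), 0.05, 0.95)),
    )


def run_mcmc(data: AreaTable, graph: AdjacencyGraph | None, spec: ModelSpec,
             cfg: MCMCConfig) -> PosteriorSamples:
    """Run ``cfg.n_chains`` independent Metropolis-within-Gibbs chains.

    Chains are seeded deterministically from ``cfg.seed`` and differ in
    both their random streams and their (jittered) starting points.
    """
    if data.expected is None:
        raise ValueError("expected counts E_i are missing; run compute_expected first")
    X = data.covariate_matrix(spec.covariate_names, spec.covariate_scaling)
    n, p = X.shape

    if spec.include_spatial:
        if graph is None:
            raise ValueError("spatial model requires an adjacency graph")
        if graph.n_areas != n:
            raise ValueError("graph size does not match the area table")
        if len(graph.islands):
            raise ValueError(f"graph has isolated areas {graph.islands.tolist()}; "
                             "the ICAR conditional is undefined for them")
        indptr, indices = graph.csr_indices()
        n_comp, comp_id = graph.components()
    else:
        indptr = np.zeros(n + 1, dtype=np.int64)
        indices = np.zeros(0, dtype=np.int64)
        n_comp, comp_id = 1, np.zeros(n, dtype=np.int64)
    comp_count = np.bincount(comp_id, minlength=n_comp).astype(np.int64)

    O = data.observed.astype(np.float64)
    E = data.expected.astype(np.float64)
    logfact = gammaln(O + 1.0)

    ss = np.random.SeedSequence(cfg.seed)
    chain_seeds = [int(s) for s in ss.generate_state(cfg.n_chains) % (2**31 - 1)]

    n_keep = (cfg.n_iter - cfg.burn_in) // cfg.thin
    alpha = np.empty((cfg.n_chains, n_keep))
    beta = np.empty((cfg.n_chains, n_keep, p))
    S = np.empty((cfg.n_chains, n_keep, n))
    H = np.empty((cfg.n_chains, n_keep, n))
    sigma_S = np.empty((cfg.n_chains, n_keep))
    sigma_H = np.empty((cfg.n_chains, n_keep))
    loglik = np.empty((cfg.n_chains, n_keep))
    acc = np.empty((cfg.n_chains, _kernel.N_BLOCKS))

    for c in range(cfg.n_chains):
        rng = np.random.default_rng(chain_seeds[c])
        st = _initial_state(data, p, rng, cfg.init_jitter)
        like_w = 0.0 if cfg.prior_only else 1.0
        check = ParameterState(st.alpha, st.beta, np.zeros(n), np.zeros(n),
                               st.sigma_S, st.sigma_H)
        lp0 = log_prior(check, spec, graph) + like_w * log_likelihood(check, data, X)
        if not np.isfinite(lp0):
            raise ValueError("non-finite joint posterior at the initial state")
        out = _kernel.run_chain(
            O, E, X, logfact, indptr, indices, comp_id, comp_count, n_comp,
            spec.include_spatial, spec.include_heterogeneity, like_w,
            spec.prior_beta_variance, spec.sigma_upper,
            cfg.n_iter, cfg.burn_in, cfg.thin, cfg.target_accept,
            cfg.adapt_interval,
            st.alpha, st.beta, st.S, st.H, st.sigma_S, st.sigma_H,
            chain_seeds[c])
        (alpha[c], beta[c], S[c], H[c], sigma_S[c], sigma_H[c],
         loglik[c], acc[c]) = out

    acceptance = {}
    for b, name in enumerate(ACCEPT_BLOCKS):
        rates = acc[:, b]
        if np.all(np.isnan(rates)):
            continue
        acceptance[name] = float(np.nanmean(rates))

    return PosteriorSamples(alpha, beta, S, H, sigma_S, sigma_H, loglik,
                            acceptance, spec, cfg, spec.covariate_names)
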