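"""Synthetic small-area datasets with the generative structure the model assumes.

The real protection-order data are confidential police records, so every
pipeline stage is exercised on simulated districts instead: an 8x10
lattice of 80 "census block groups" whose covariate marginals (truncated
normals) and population at risk match the published district summaries,
with counts drawn from the Poisson BYM-type model itself,

    O_i ~ Poisson(E_i exp(alpha + X_i beta + S_i + H_i)),

at the published final-model effect sizes.  The generator returns the
ground truth alongside the data so recovery can be measured.

The ICAR field S is sampled exactly on the per-component sum-to-zero
subspace via the eigendecomposition of the structure matrix Q: independent
N(0, sigma_S^2 / omega_k) coefficients on the eigenvectors with positive
eigenvalue omega_k.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .graph import AdjacencyGraph, icar_structure, lattice_graph
from .io import AreaTable

__all__ = [
    "CovariateSpec",
    "GeneratorConfig",
    "SyntheticDataset",
    "sample_covariates",
    "sample_icar_field",
    "simulate_dataset",
]

# Published district marginals (mean, sd, min, max) per covariate and for
# the population of women aged 16+; effect sizes from the final fitted
# model (intercept, three active covariates, both random-effect scales);
# 368 events over the whole district.
TABLE1_COVARIATES: dict[str, tuple[float, float, float, float]] = {
    "property_value": (22_440.0, 9_160.0, 11_190.0, 52_580.0),
    "immigration": (16.58, 6.85, 6.33, 33.17),
    "policing": (10.16, 3.56, 2.0, 18.0),
    "social_disorder": (0.29, 0.75, 0.0, 4.0),
    "physical_disorder": (6.2, 3.26, 0.0, 16.0),
    "residential_mobility": (22.92, 6.01, 11.39, 34.52),
}
WOMEN_16_PLUS = (651.3, 191.15, 361.0, 1_174.0)
TRUE_ALPHA = -1.715
TRUE_BETA = {"immigration": 0.046, "policing": 0.064, "physical_disorder": 0.030}
TRUE_SIGMA_S = 0.232
TRUE_SIGMA_H = 0.190
BASELINE_TOTAL = 368.0


@dataclass
class CovariateSpec:
    mean: float
    sd: float
    lo: float
    hi: float

    def __post_init__(self) -> None:
        if self.sd < 0:
            raise ValueError("sd must be >= 0")
        if not (self.lo <= self.mean <= self.hi):
            raise ValueError("need lo <= mean <= hi")
        if self.lo == self.hi and self.sd > 0:
            raise ValueError("degenerate bounds with positive sd")


@dataclass
class GeneratorConfig:
    """Study conditions of the synthetic district.

    Defaults emulate the published district: an 8x10 rook lattice (80
    areas), covariate and population marginals from the published summary
    table, effect sizes from the final spatial model, and 368 expected
    events in total.
    """

    n_rows: int = 8
    n_cols: int = 10
    contiguity: str = "rook"
    covariate_specs: dict[str, CovariateSpec] = field(default_factory=lambda: {
        k: CovariateSpec(*v) for k, v in TABLE1_COVARIATES.items()})
    population_spec: CovariateSpec = field(
        default_factory=lambda: CovariateSpec(*WOMEN_16_PLUS))
    true_alpha: float = TRUE_ALPHA
    true_beta: dict[str, float] = field(default_factory=lambda: dict(TRUE_BETA))
    true_sigma_S: float = TRUE_SIGMA_S
    true_sigma_H: float = TRUE_SIGMA_H
    baseline_total: float = BASELINE_TOTAL
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_rows * self.n_cols < 2:
            raise ValueError("lattice needs at least 2 areas")
        if self.true_sigma_S < 0 or self.true_sigma_H < 0:
            raise ValueError("sigma parameters must be >= 0")
        if self.baseline_total <= 0:
            raise ValueError("baseline_total must be positive")
        unknown = set(self.true_beta) - set(self.covariate_specs)
        if unknown:
            raise ValueError(f"true_beta names not among covariates: {sorted(unknown)}")


@dataclass
class SyntheticDataset:
    area_table: AreaTable
    graph: AdjacencyGraph
    truth: dict

    def truth_linear_predictor(self) -> np.ndarray:
        t = self.truth
        X = self.area_table.covariate_matrix(list(t["beta"]))
        return t["alpha"] + X @ np.array(list(t["beta"].values())) + t["S"] + t["H"]


def _truncnorm(spec: CovariateSpec):
    if spec.sd == 0:
        return None
    a = (spec.lo - spec.mean) / spec.sd
    b = (spec.hi - spec.mean) / spec.sd
    return stats.truncnorm(a, b, loc=spec.mean, scale=spec.sd)


def truncated_normal_mean(spec: CovariateSpec) -> float:
    """Closed-form mean of the truncated sampling distribution (truncation
    shifts it away from the nominal location when the bounds are asymmetric)."""
    dist = _truncnorm(spec)
    return spec.mean if dist is None else float(dist.mean())


def sample_covariates(config: GeneratorConfig, seed: int | None = None) -> pd.DataFrame:
    """Draw each covariate i.i.d. from its truncated normal, independently.

    Only marginal summaries of the real district are published, so columns
    are sampled without cross-correlation; real neighborhood covariates are
    of course correlated.
    """
    rng = np.random.default_rng(config.seed if seed is None else seed)
    n = config.n_rows * config.n_cols
    cols = {}
    for name, spec in config.covariate_specs.items():
        dist = _truncnorm(spec)
        if dist is None:
            cols[name] = np.full(n, spec.mean)
        else:
            cols[name] = dist.rvs(size=n, random_state=rng)
    return pd.DataFrame(cols)


def sample_icar_field(graph: AdjacencyGraph, sigma_S: float,
                      seed: int | np.random.Generator = 0) -> np.ndarray:
    """Exact draw from the intrinsic CAR restricted to sum-to-zero per component."""
    if sigma_S < 0:
        raise ValueError("sigma_S must be >= 0")
    n = graph.n_areas
    if sigma_S == 0:
        return np.zeros(n)
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    Q = icar_structure(graph)
    w, V = np.linalg.eigh(Q)
    n_comp, _ = graph.components()
    pos = w > 1e-10
    if pos.sum() != n - n_comp:
        raise RuntimeError("unexpected ICAR rank; graph may be degenerate")
    coef = rng.standard_normal(int(pos.sum())) * sigma_S / np.sqrt(w[pos])
    return V[:, pos] @ coef


def simulate_dataset(config: GeneratorConfig) -> SyntheticDataset:
    """Generate a full synthetic district; byte-reproducible from the seed."""
    rng = np.random.default_rng(config.seed)
    graph = lattice_graph(config.n_rows, config.n_cols, config.contiguity)
    n = graph.n_areas

    covariates = sample_covariates(config, seed=rng)
    pop_dist = _truncnorm(config.population_spec)
    pop_raw = (np.full(n, config.population_spec.mean) if pop_dist is None
               else pop_dist.rvs(size=n, random_state=rng))
    population = np.maximum(1, np.rint(pop_raw)).astype(np.int64)

    S = sample_icar_field(graph, config.true_sigma_S, rng)
    H = (rng.standard_normal(n) * config.true_sigma_H
         if config.true_sigma_H > 0 else np.zeros(n))

    E = config.baseline_total * population / population.sum()
    beta_names = list(config.true_beta)
    X = covariates[beta_names].to_numpy() if beta_names else np.zeros((n, 0))
    beta = np.array([config.true_beta[k] for k in beta_names])
    lam = np.exp(config.true_alpha + X @ beta + S + H)
    observed = rng.poisson(lam * E)

    table = AreaTable(
        area_id=[f"bg{i:03d}" for i in range(n)],
        observed=observed,
        population=population,
        covariates=covariates,
    )
    truth = {
        "alpha": config.true_alpha,
        "beta": dict(config.true_beta),
        "S": S,
        "H": H,
        "sigma_S": config.true_sigma_S,
        "sigma_H": config.true_sigma_H,
        "lambda": lam,
        "expected": E,
    }
    return SyntheticDataset(area_table=table, graph=graph, truth=truth)
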