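"""Convergence assessment and model comparison.

R-hat is the classic Gelman–Rubin potential scale reduction factor
computed on post-burn-in, thinned draws (the split-chain refinement is
available as an option).  Model comparison uses the Deviance Information
Criterion with the plug-in deviance evaluated at the posterior mean of the
log-scale parameters (alpha, beta, S, H) — the parameterization-dependent
convention of the classic BUGS implementation, which this package follows
so that pD reads as an effective number of parameters.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io import AreaTable
from .model import PosteriorSamples, log_likelihood

__all__ = [
    "gelman_rubin",
    "effective_sample_size",
    "ConvergenceReport",
    "convergence_report",
    "DICReport",
    "compute_dic",
]


def gelman_rubin(chains: np.ndarray, split: bool = False) -> float:
    """Classic potential scale reduction factor.

    ``chains`` is an (m, n) array of m parallel chains of length n.  With
    W the mean within-chain variance and B/n the variance of the chain
    means, R-hat = sqrt(((n-1)/n W + B/n) / W).  ``split=True`` halves
    each chain first (detects within-chain trends).
    """
    chains = np.asarray(chains, dtype=float)
    if chains.ndim != 2 or chains.shape[0] < 2:
        raise ValueError("gelman_rubin needs >= 2 chains of equal length")
    if split:
        m, n = chains.shape
        h = n // 2
        chains = np.vstack([chains[:, :h], chains[:, n - h:]])
    m, n = chains.shape
    if n < 2:
        raise ValueError("chains must have length >= 2")
    W = float(np.mean(np.var(chains, axis=1, ddof=1)))
    if W == 0.0:
        raise ValueError("zero within-chain variance; R-hat is undefined")
    B_over_n = float(np.var(np.mean(chains, axis=1), ddof=1))
    v_hat = (n - 1) / n * W + B_over_n
    return float(np.sqrt(v_hat / W))


def effective_sample_size(chains: np.ndarray) -> float:
    """Effective sample size of pooled chains (ArviZ's bulk ESS)."""
    import arviz as az

    chains = np.asarray(chains, dtype=float)
    if chains.ndim == 1:
        chains = chains[None, :]
    return float(az.ess(az.convert_to_dataset(chains), method="bulk")["x"].values)


@dataclass
class ConvergenceReport:
    rhat: dict[str, float]
    ess: dict[str, float]
    threshold: float
    converged: bool

    def worst(self) -> tuple[str, float]:
        name = max(self.rhat, key=self.rhat.get)
        return name, self.rhat[name]


def convergence_report(samples: PosteriorSamples,
                       threshold: float = 1.05) -> ConvergenceReport:
    """R-hat and ESS for every scalar parameter of a fit.

    The run is flagged converged when every R-hat is at or below
    ``threshold`` (default 1.05, a practical reading of "near 1.0").
    """
    rhat, ess = {}, {}
    for name, ch in samples.scalar_chains().items():
        rhat[name] = gelman_rubin(ch)
        ess[name] = effective_sample_size(ch)
    return ConvergenceReport(rhat=rhat, ess=ess, threshold=threshold,
                             converged=all(v <= threshold for v in rhat.values()))


@dataclass
class DICReport:
    """Deviance Information Criterion summary.

    Dbar is the posterior mean of the deviance -2 log L; Dhat the deviance
    at the posterior mean of (alpha, beta, S, H); pD = Dbar - Dhat the
    effective number of parameters; DIC = Dbar + pD = Dhat + 2 pD.
    """

    Dbar: float
    Dhat: float
    pD: float
    DIC: float

    def __post_init__(self) -> None:
        if not np.isfinite(self.pD):
            raise ValueError("pD is not finite")
        assert abs(self.DIC - (self.Dhat + 2 * self.pD)) <= 1e-9 * max(1.0, abs(self.DIC))


def compute_dic(samples: PosteriorSamples, data: AreaTable) -> DICReport:
    """DIC from stored per-draw log likelihoods and the plug-in posterior mean."""
    ll = samples.stacked("loglik")
    if ll.size == 0:
        raise ValueError("no posterior draws")
    if np.any(np.isnan(ll)):
        raise ValueError("per-draw log likelihood unavailable (prior-only run?)")
    dbar = float(np.mean(-2.0 * ll))
    X = data.covariate_matrix(samples.spec.covariate_names,
                              samples.spec.covariate_scaling)
    dhat = -2.0 * log_likelihood(samples.posterior_mean_state(), data, X)
    pd_ = dbar - dhat
    return DICReport(Dbar=dbar, Dhat=dhat, pD=pd_, DIC=dbar + pd_)
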