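# Methods

## Model

Counts per areal unit are Poisson, `O_i ~ Poisson(lambda_i E_i)`, with
`log lambda_i = alpha + X_i beta + S_i + H_i`. Expected counts use
internal standardization, `E_i = pop_i * (sum O / sum pop)`; consequently
`sum E = sum O` exactly and `lambda_i` reads as relative risk against the
district-wide incidence. `log E_i` enters the sampler as a fixed offset.

The spatial effect `S` carries the intrinsic CAR (ICAR) prior: the full
conditional of `S_i` is normal with mean the average of its neighbors'
values and variance `sigma_S^2 / n_i` (`n_i` = number of neighbors). By
Brook's lemma the corresponding joint density is

    p(S | sigma_S)  ∝  sigma_S^-(n-c) exp( - sum_{i~j, i<j} (S_i - S_j)^2 / (2 sigma_S^2) )
                    =  sigma_S^-(n-c) exp( - S' Q S / (2 sigma_S^2) ),   Q = D - W,

improper with rank `n - c` (`c` = connected components). Identifiability
of `alpha` is restored by constraining `S` to sum to zero within each
component. A consequence worth spelling out because it is easy to get
wrong: on a 2-node path with `sigma_S = 1`, `Var(S_1 - S_2) = 1` (the
single positive eigenvalue of `Q` is 2 with orthonormal eigenvector
`(1,-1)/sqrt(2)`, so the coefficient has variance 1/2 and the difference
variance is `2 * 1/2 = 1`); the generator and the sampler are tested
against this closed form.

`H_i ~ N(0, sigma_H^2)` i.i.d. absorbs unstructured extra-Poisson
dispersion. Priors: improper flat on `alpha`; `N(0, prior_beta_variance)`
with default variance `1e5` on each coefficient (the "N(0, 100000)"
convention is read as a variance — the verbal intent is a vague prior,
and a precision of 1e5 would be nearly a point mass at zero); `U(0,
sigma_upper)` with default upper bound 1 on both standard deviations. The
unit upper bound is faithful to common practice for these data magnitudes
but is informative if the truth approaches 1; it is a config field and
the prior-sensitivity helper exercises `sigma_upper = 5` as a default
alternative.

## Sampler

A single-site adaptive random-walk Metropolis-within-Gibbs sweep updates,
in order: `alpha`; each `beta_k`; each `S_i` (likelihood term for area `i`
plus the ICAR conditional), followed by per-component recentering of `S`
with the grand mean absorbed into `alpha` (on a connected graph this is an
exact reparameterization that leaves the joint density unchanged); each
`H_i`; then `sigma_H` and `sigma_S` by random-walk MH on their
conditionals, the latter using the quadratic form with exponent
`-(n-c) log sigma_S`. The state `eta_i = log lambda_i` and
`mu_i = E_i exp(eta_i)` is maintained incrementally, so a sweep is O(n + p·n
+ edges). The kernel is numba-compiled; each chain is seeded independently
(via `numpy.random.SeedSequence` from the run seed) and starts from a
jittered point so that R-hat compares genuinely dispersed chains.

Proposal scales (one per update family: `alpha`, each `beta_k`, pooled
`S`, pooled `H`, each sigma) adapt on the log scale toward an acceptance
rate of 0.44 — the 1-D random-walk optimum — in windows of 50 sweeps
with a decaying gain, during burn-in only; after burn-in the kernel is
fixed, so the retained draws come from a valid time-homogeneous chain.
Post-adaptation acceptance rates are reported per block and sit in
[0.2, 0.6] on the default synthetic data (asserted in the tests).

Prior-only mode (`MCMCConfig(prior_only=True)`) drops every likelihood
term; `alpha`, whose flat prior is not a distribution, is then held
fixed. The tests verify the sampler reproduces its priors (coefficient
variance `1e5` within 5%; both sigmas uniform by Kolmogorov–Smirnov on
draws spaced widely enough — 2,000 sweeps — that the test's independence
assumption holds; the sigmas are the slowest-mixing parameters, with
integrated autocorrelation times of a few hundred sweeps on a 12-area
prior-only run).

Default schedule: 100,000 iterations, 10,000 burn-in, 2 chains, thin 10.
The replicate experiments in the test suite use 20,000/2,000 — the same
1/5 scaling of both numbers — which the coverage results show is ample at
n = 80.

## Diagnostics and model comparison

R-hat is the classic potential scale reduction factor
`sqrt((((n-1)/n) W + B/n) / W)` on the retained draws, with an optional
split-chain variant; two identical chains of (1,2,3,4) give exactly
`sqrt(3/4)`, which the tests pin. The practical convergence flag is
R-hat ≤ 1.05 for every scalar parameter. Effective sample sizes come from
ArviZ (bulk ESS); ArviZ's rank-normalized split R-hat is deliberately not
used for the headline diagnostic because it is a different (stricter)
statistic than the classic one summarized here.

DIC uses the full Poisson deviance (including `log O_i!`), `Dbar` the
posterior mean deviance, and `Dhat` the deviance at the posterior mean of
the *log-scale* parameters `(alpha, beta, S, H)`. DIC is
parameterization-sensitive; this plug-in matches the convention of the
classic BUGS implementation, so `p_D = Dbar - Dhat` reads as an effective
number of parameters (≈ 7 for the 7-fixed-effect model, ≈ 20–25 once the
80 partially-pooled random effects enter).

## Synthetic districts

`GeneratorConfig` defaults define the emulated study conditions: an 8×10
rook-contiguity lattice (80 areas — real block-group contiguity is
irregular, but degree distributions are comparable and any GAL-described
graph can be substituted); six covariates drawn i.i.d. from truncated
normals with the published mean/SD/min/max per covariate; population of
women 16+ from the same family rounded to integers (floor 1); a total of
368 expected events scaled by population share; and the published
final-model truth `alpha = -1.715`, `beta = 0.046` (immigration percent),
`0.064` (policing-activity index), `0.030` (physical-disorder score),
`sigma_S = 0.232`, `sigma_H = 0.190`, with the other three covariates
(property value, social disorder, residential mobility) generated but
null. The ICAR field is drawn exactly on the sum-to-zero subspace via the
eigendecomposition of `Q` (coefficients `N(0, sigma_S^2/omega_k)` on the
positive-eigenvalue eigenvectors).

What the generator does **not** emulate: cross-correlation between
covariates (only marginals are published; real neighborhood covariates
are strongly correlated, so real-data coefficient uncertainty is larger
than the synthetic experiments suggest), the actual street geometry, and
any misspecification of the Poisson/log-linear form. Passing recovery
tests therefore demonstrates the estimator is correct under the model's
own assumptions at the study's scale — not that the model is right for
any particular city.

## Numerical choices and edge cases

* Property value is rescaled to thousands before fitting (default
  per-covariate scaling map) so its coefficient lives on a scale the vague
  prior and the random-walk proposals handle well.
* Isolated areas (no neighbors) are rejected for spatial fitting — the
  CAR conditional is undefined at `n_i = 0`; inside the field sampler an
  island would be pinned at zero. Disconnected graphs are allowed, with
  the sum-to-zero constraint applied per component.
* Covariate screening: a covariate is kept when
  `max(P(beta>0), P(beta<0)) ≥ 0.90` from the Model 2 draws. The 0.90
  default reproduces the keep/drop pattern of the reference district
  analysis from its published intervals (a "CI excludes 0" rule, i.e.
  0.975, would not — it drops a covariate the reference analysis kept).
  `sign_probability_from_interval` applies the same rule to
  interval-only summaries via a normal approximation.
* Exceedance uses the strict inequality `lambda > 1`, so a degenerate
  posterior at exactly 1 has exceedance 0.
* If the screen retains nothing, the final model falls back to the full
  covariate set rather than fitting an intercept-only spatial model.
* The expected-count step refuses all-zero count tables (no district rate
  exists), and `read_area_table` validates counts, ids, and completeness
  with row-level error messages.

## Known limitations

* Single-site random-walk updates mix slowly for strongly coupled blocks;
  the sigmas have integrated autocorrelation times of O(10²) sweeps.
  Reliable interval estimates at n = 80 need a few tens of thousands of
  sweeps (seconds), but much larger graphs would warrant blocked or
  gradient-based updates.
* Exact covariate-set recovery by the screen is intrinsically limited at
  the calibrated effect sizes: the weakest true effect has a population
  sign probability of about 0.91 — right at the 0.90 threshold — so it is
  kept in only ~half of replicate districts, and each null covariate is
  falsely kept with probability ~0.2 at that threshold. These are
  properties of the screening rule at this signal strength, not of the
  sampler; the replicate experiments in the test suite measure them.
* DIC is used because it is the field's convention for these models; it
  shares the known weaknesses of plug-in criteria (parameterization
  dependence, no penalty for posterior skew). WAIC/LOO are out of scope.
* The proper CAR (with autocorrelation parameter), Leroux prior, and
  spatio-temporal extensions are out of scope.
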