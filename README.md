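# smallarea

Bayesian small-area relative-risk mapping for areal count data, built
around the Besag–York–Mollié ("convolution") Poisson model and the kind of
analysis used to study how neighborhood context shapes the geography of
rare adverse events — here, serious intimate-partner-violence cases
(court-issued protection orders) across the ~80 census block groups of an
urban police district.

The real event data of such studies are confidential police records, so
the package ships a calibrated synthetic-district generator: covariate and
population marginals, effect sizes, and event totals match the published
district summaries, and the generating truth travels with each dataset so
estimation quality can be measured.

## The model

For areas *i* = 1, …, *n* with observed counts *O_i* and expected counts
*E_i* (internal standardization, *E_i* = pop_i · ΣO/Σpop, so Σ*E* = Σ*O*):

    O_i ~ Poisson(λ_i E_i)
    log λ_i = α + X_i β + S_i + H_i

* *λ_i* — relative risk versus the whole-district incidence (*λ_i* = 1 is
  average);
* *S* — spatially structured random effect with an intrinsic CAR prior:
  *S_i* | *S_−i* ~ N(mean of neighbors, σ_S²/n_i), where n_i is the number
  of adjacent areas; improper, handled with a per-component sum-to-zero
  constraint;
* *H_i* ~ N(0, σ_H²) — exchangeable heterogeneity absorbing extra-Poisson
  dispersion;
* priors: flat on α, N(0, 10⁵) on each β_k, U(0, 1) on σ_S and σ_H.

Inference is a purpose-built adaptive single-site Metropolis-within-Gibbs
sampler (numba-compiled; ~10⁶ sweeps/minute at n = 80 on one core).
Convergence is assessed with the classic Gelman–Rubin R̂ and effective
sample sizes; models are compared by DIC = D̄ + p_D with the plug-in
deviance at the posterior mean of (α, β, S, H). The analysis workflow fits
three nested models — fixed effects only (Model 1), + both random effects
(Model 2), and the screened final model (Model 3) keeping covariates whose
posterior sign probability reaches 0.90 — and summarizes the winner as a
per-area surface of posterior mean risk, 95% credible interval, exceedance
probability P(λ_i > 1 | data), and the posterior mean spatial component.

## Worked example

```python
import smallarea as sa

ds = sa.simulate_dataset(sa.GeneratorConfig(seed=7))   # 80-area district
data = sa.compute_expected(ds.area_table)              # adds E_i
cfg = sa.MCMCConfig(n_iter=20_000, burn_in=2_000, n_chains=2, thin=10, seed=2)
res = sa.model_selection_workflow(data, ds.graph, cfg)
print(res.dic_table().round(1).to_string(index=False))
```

prints

```
model  Dbar  Dhat   pD   DIC
   m1 348.3 341.3  7.0 355.2
   m2 324.1 300.7 23.4 347.5
   m3 321.8 298.3 23.4 345.2
```

Model 1's p_D ≈ 7 is its parameter count (intercept + 6 coefficients); the
random effects add ~16 effective parameters but drop the DIC by ~8–10, so
the spatial convolution model fits this (spatially structured) district
better, and the screen keeps exactly the covariates that generated the
data (immigration 0.999, policing 1.000, physical disorder 0.976 sign
probability; the three null covariates fall below 0.90). Mapping the
chosen fit (`sa.risk_surface`) then gives, for instance, a hottest area
with posterior mean risk 2.53 (95% CI 1.54–3.89) and P(risk > 1) = 1.00 —
i.e. confidently two-and-a-half times the district average.

The `examples/` directory holds one short script per capability
(simulation, fitting, comparison, mapping, prior sensitivity); each prints
the numbers it computes and a line on how to read them. A thin CLI mirrors
the workflow for shell use:

```sh
smallarea simulate --seed 3 --out d/
smallarea compare --data d/areas.csv --adj d/areas.gal --config cfg.yaml --out d/
```

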