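"""Generate a synthetic district and look at the raw data.

The generator emulates an urban police district of 80 census block groups:
covariates and population at risk are drawn from published marginal
summaries, and protection-order counts come from the Poisson model with
spatially structured (ICAR) and unstructured random effects at the
published effect sizes.  The ground truth travels with the dataset.
"""

import numpy as np

import smallarea as sa

ds = sa.simulate_dataset(sa.GeneratorConfig(seed=7))
table = ds.area_table

print(f"areas: {table.n_areas}, total events: {table.observed.sum()}")
print(f"covariates: {table.covariate_names}")

rates = sa.raw_rates(table)
print(f"crude rates per 1,000 women 16+: min {rates.min():.2f}, "
      f"median {np.median(rates):.2f}, max {rates.max():.2f}")
# Crude small-area rates are noisy: areas with small populations can swing
# from 0 to tens per thousand, which is why the model smooths them.

truth = ds.truth
print(f"true relative risks span {truth['lambda'].min():.2f} to "
      f"{truth['lambda'].max():.2f} around the district average of 1")
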