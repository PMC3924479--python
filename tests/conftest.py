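import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

import smallarea as sa

settings.register_profile("ci", deadline=None, derandomize=True, max_examples=25)
settings.load_profile("ci")


@pytest.fixture
def toy_table() -> sa.AreaTable:
    """Three areas, one covariate, expected counts standardized."""
    table = sa.AreaTable(
        area_id=["a", "b", "c"],
        observed=np.array([2, 5, 9]),
        population=np.array([400, 600, 700]),
        covariates=pd.DataFrame({"x": [-1.0, 0.0, 1.0]}),
    )
    return sa.compute_expected(table)


@pytest.fixture
def path3() -> sa.AdjacencyGraph:
    """3-node path graph a-b-c."""
    return sa.AdjacencyGraph([np.array([1]), np.array([0, 2]), np.array([1])])


@pytest.fixture(scope="session")
def default_dataset() -> sa.SyntheticDataset:
    """One default synthetic district (80 areas at the calibrated truth)."""
    return sa.simulate_dataset(sa.GeneratorConfig(seed=20260))


@pytest.fixture(scope="session")
def default_fit(default_dataset):
    """A Model-3-style fit of the default district, shared across tests."""
    data = sa.compute_expected(default_dataset.area_table)
    spec = sa.ModelSpec(covariate_names=["immigration", "policing",
                                         "physical_disorder"])
    cfg = sa.MCMCConfig(n_iter=20_000, burn_in=2_000, n_chains=2, thin=10,
                        seed=11)
    samples = sa.run_mcmc(data, default_dataset.graph, spec, cfg)
    return data, default_dataset.graph, samples
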