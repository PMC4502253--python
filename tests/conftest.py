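import warnings

import numpy as np
import pytest

from spatemort import (
    AgeScheme,
    ModelSpec,
    SimulationConfig,
    fit,
    make_grid_adjacency,
    simulate_study,
)

warnings.filterwarnings("ignore", category=RuntimeWarning)
np.seterr(all="ignore")


@pytest.fixture(scope="session")
def default_scheme():
    return AgeScheme.default()


@pytest.fixture(scope="session")
def grid12():
    return make_grid_adjacency(3, 4)


@pytest.fixture(scope="session")
def study():
    """Default synthetic study: 12 districts, 19 ages, 20 years, model 3."""
    cfg = SimulationConfig(seed=11)
    data, truth, graph = simulate_study(cfg, model_id=3)
    return data, truth, graph


@pytest.fixture(scope="session")
def fitted_m3(study):
    """One model-3 fit of the default study, shared across tests."""
    data, truth, graph = study
    spec = ModelSpec(3, data.age_scheme, data.years, data.n_districts)
    samples = fit(spec, data, graph, chains=2, draws=500, warmup=500, seed=3)
    return spec, samples, truth


@pytest.fixture()
def tiny_scheme():
    """Two age groups (0-4, 5+), enough for brute-force likelihood checks."""
    return AgeScheme(np.array([0.0, 5.0]), np.array([5.0, np.inf]))
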