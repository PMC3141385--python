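import numpy as np
import pandas as pd
import pytest

import osteosim as o


@pytest.fixture(scope="session")
def params() -> o.ModelParameters:
    return o.default_parameters()


@pytest.fixture(scope="session")
def life_table() -> o.LifeTable:
    return o.synthetic_life_table()


@pytest.fixture(scope="session")
def excess() -> o.ExcessMortality:
    return o.ExcessMortality()


@pytest.fixture(scope="session")
def cohort_30k() -> pd.DataFrame:
    return o.generate_population(o.PopulationSpec(), 30_000, seed=7)


@pytest.fixture(scope="session")
def small_cohort() -> pd.DataFrame:
    return o.generate_population(o.PopulationSpec(), 2_000, seed=7)


@pytest.fixture
def uniform_cohort():
    """Factory: n identical women of a given age (single band instances)."""

    def make(n: int, age: float = 72.0, prior_prevalence: float = 0.597, seed: int = 5):
        rng = np.random.default_rng(seed)
        return pd.DataFrame(
            {
                "id": np.arange(n),
                "age": np.full(n, float(age)),
                "prior_fracture": rng.uniform(size=n) < prior_prevalence,
            }
        )

    return make


@pytest.fixture
def run(params, life_table, excess):
    """Factory running one alternative with defaults filled in."""

    def _run(population, alternative, seed=42, n_cycles=10, params_=None, uplift=0.0):
        settings = o.SimulationSettings(
            n_patients=len(population),
            n_cycles=n_cycles,
            seed=seed,
            alternative=alternative,
        )
        return o.run_alternative(
            params_ or params, settings, population, life_table, excess, uplift=uplift
        )

    return _run
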