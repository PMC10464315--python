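import logging

import numpy as np
import pytest

from xvar.synth import generate_landscape, plant_truth, simulate_cohort

logging.getLogger("xvar").setLevel(logging.ERROR)


@pytest.fixture(scope="session")
def small_landscape():
    return generate_landscape(300, seed=11)


@pytest.fixture(scope="session")
def planted_study(small_landscape):
    """A small planted landscape + truth shared across tests."""
    land, truth = plant_truth(
        small_landscape,
        n_var_xi=12, n_var_xa=2, n_mean_xa=3, n_mean_xi=2, n_composition=8,
        seed=13,
    )
    return land, truth


@pytest.fixture(scope="session")
def small_cohort(planted_study):
    land, truth = planted_study
    meth, samples = simulate_cohort(
        land, truth, 80, 70, cohorts=("C1", "C2"), seed=17
    )
    return meth, samples


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def null_design():
    """A fixed covariate design for repeated null simulations."""
    r = np.random.default_rng(99)
    n = 2000
    age = r.uniform(18, 85, n)
    X = np.column_stack([np.ones(n), age, r.normal(size=(n, 4))])
    return X, age
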