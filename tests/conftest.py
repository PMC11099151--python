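import numpy as np
import pytest

from clonepop.models import DemographicModel, single_population_model
from clonepop.simulate import simulate_population_set


@pytest.fixture(scope="session")
def small_single_pop():
    """One population, 10 diploids, 100 kb; moderate recombination."""
    model = single_population_model(size=250_000, sigma=0.1, theta_site=0.001, rho_site=2e-9)
    gm, truth = simulate_population_set(model, {"asia": 10}, 100_000, seed=11)
    return gm, truth


@pytest.fixture(scope="session")
def four_pop_matrix():
    """Study-shaped 4-population cohort at desk scale."""
    gm, truth = simulate_population_set(DemographicModel(), 6, 150_000, seed=7)
    return gm, truth


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
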