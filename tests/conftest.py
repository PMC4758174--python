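import numpy as np
import pytest

from nestnet.landscape import HabitatRaster
from nestnet.synthetic_data import SimulationScenario, generate_dataset


@pytest.fixture(scope="session")
def small_dataset():
    """A small forward-simulated dataset shared by sampler tests."""
    scenario = SimulationScenario(seed=42, n_females=3, n_males=3,
                                  observation_days=80)
    return generate_dataset(scenario)


@pytest.fixture(scope="session")
def study_dataset():
    """A dataset at the study's magnitudes (10 F + 10 M, 120 daily checks)."""
    return generate_dataset(SimulationScenario(seed=42))


@pytest.fixture
def rng():
    return np.random.default_rng(20260927)


def make_random_raster(rng, n=40, p=(0.32, 0.20, 0.38, 0.07, 0.03), resolution=25.0):
    """An i.i.d. multi-class raster (no spatial structure; worst case for
    connectivity code because components are tiny and numerous)."""
    grid = rng.choice([1, 2, 3, 4, 5], size=(n, n), p=list(p))
    return HabitatRaster(grid=grid, origin=(0.0, 0.0), resolution=resolution)
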