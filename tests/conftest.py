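import numpy as np
import pytest

from vcgsim import AnnealSchedule, Parameters, random_repeat_free_circle


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def quick_schedule():
    """Small annealing budget, plenty for circles far below the bound."""
    return AnnealSchedule(restarts=10)


@pytest.fixture(scope="session")
def circle10(quick_schedule):
    """A repeat-free virtual circle of length 10 (the 500NC fixture)."""
    return random_repeat_free_circle(10, 4, np.random.default_rng(77),
                                     quick_schedule)


@pytest.fixture
def small_params():
    """Downscaled reaction system exercising every channel quickly."""
    return Parameters(N0=80, N_init=0, l0=4, k_nuc=1.0, k_ann=80.0,
                      k_add=30.0, k_lig=5.0, k_melt=1.0, T_grow=2.0)
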