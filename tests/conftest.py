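import numpy as np
import pytest

from hcmito.config import CohortParams, ImageParams, SimulationConfig


@pytest.fixture
def sim_config():
    """Default study-condition simulation config with a fixed seed."""
    return SimulationConfig(seed=42)


@pytest.fixture
def small_cohort_config():
    """Small cohort (fast) with the default outcome distributions."""
    return SimulationConfig(
        seed=7, cohort_params=CohortParams(n_fish=4, neuromasts_per_fish=3,
                                           cells_per_neuromast=15))


@pytest.fixture
def noise_free_stack_config():
    """One-neuromast render with no camera noise for closure tests."""
    return SimulationConfig(
        seed=11,
        cohort_params=CohortParams(n_fish=1, neuromasts_per_fish=2,
                                   cells_per_neuromast=9),
        image_params=ImageParams(camera_noise_sd=0.0))


@pytest.fixture
def rng():
    return np.random.default_rng(20260920)
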