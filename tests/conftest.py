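import numpy as np
import pytest

from pigflux import SimulationConfig


@pytest.fixture
def config():
    """Default (calibrated) configuration."""
    return SimulationConfig()


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def ramp_only_config():
    """Configuration whose trajectories are pure growth ramps.

    No drinks (Poisson mean tiny, bounds forced to zero), no meals, no
    elimination events; the reservoirs still fill linearly, so the raw
    component sum is affine in t and the growth correction makes every
    trajectory an exact ramp from W0 to W0 + daily_gain.
    """
    return SimulationConfig(
        drink_bouts_mean=1e-9, drink_bouts_min=0, drink_bouts_max=0,
        meals_min=0, meals_max=0,
        urinations_min=0, urinations_max=0,
        defecations_min=0, defecations_max=0,
        n_pigs=8,
    )
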