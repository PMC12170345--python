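import numpy as np
import pytest

from mtdyn import mtsim


@pytest.fixture(scope="session")
def presets():
    return mtsim.builtin_presets()


@pytest.fixture()
def single_state_preset():
    """Deterministic single-state growth: 1 µm/min, no noise."""
    return mtsim.ConditionPreset(
        name="const",
        states=(mtsim.SLOW_GROWTH,),
        velocity_mean={mtsim.SLOW_GROWTH: 1.0},
        velocity_sd={mtsim.SLOW_GROWTH: 0.0},
        transition_rates={},
        initial_state=mtsim.SLOW_GROWTH,
    )


@pytest.fixture()
def two_state_preset():
    """Growth/pause switcher with hazard 6 min^-1 out of growth."""
    return mtsim.ConditionPreset(
        name="two",
        states=(mtsim.SLOW_GROWTH, mtsim.PAUSE),
        velocity_mean={mtsim.SLOW_GROWTH: 0.3, mtsim.PAUSE: 0.0},
        velocity_sd={mtsim.SLOW_GROWTH: 0.0, mtsim.PAUSE: 0.0},
        transition_rates={
            (mtsim.SLOW_GROWTH, mtsim.PAUSE): 6.0,
            (mtsim.PAUSE, mtsim.SLOW_GROWTH): 3.0,
        },
        initial_state=mtsim.SLOW_GROWTH,
    )


@pytest.fixture(scope="session")
def monomer_field():
    _, records = mtsim.simulate_spot_field(
        1000, {1: 1.0}, image_size=1024, seed=101
    )
    return records


@pytest.fixture(scope="session")
def dimer_field():
    _, records = mtsim.simulate_spot_field(
        1000, {2: 1.0}, image_size=1024, seed=102
    )
    return records


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(1234)
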