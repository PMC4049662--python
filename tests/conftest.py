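import dataclasses

import numpy as np
import pytest
from hypothesis import settings

from livergrowth.geometry import PrismLiverShape, TorusLiverShape
from livergrowth.growth import GrowthConfig
from livergrowth.synthetic import preset_scenarios

settings.register_profile("ci", derandomize=True, max_examples=50,
                          deadline=None)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def dog1_shape() -> TorusLiverShape:
    """Dog-1 torus model: tube radius 1 -> 1.291, d/r = 1.25, 2/3 ring."""
    return TorusLiverShape.with_initial_volume(
        r_b=1.0, r_e=1.291, d_b=1.25, P=2 / 3, initial_volume_cm3=374.28)


@pytest.fixture(scope="session")
def dog2_shape() -> TorusLiverShape:
    return TorusLiverShape.with_initial_volume(
        r_b=1.0, r_e=1.45, d_b=1.25, P=2 / 3, initial_volume_cm3=344.778)


def make_prism(lobe: str = "left", F: float = 0.485) -> PrismLiverShape:
    """Human-liver prism in the published proportions (width 1.2, bases 1
    and 3.5 widths, length 2.9 widths)."""
    return PrismLiverShape.from_width_units(1.2, 1.0, 3.5, 2.9,
                                            lobe=lobe, F=F)


@pytest.fixture(scope="session")
def left_prism() -> PrismLiverShape:
    return make_prism("left", 0.485)


@pytest.fixture(scope="session")
def config() -> GrowthConfig:
    return GrowthConfig()


@pytest.fixture(scope="session")
def presets():
    return preset_scenarios()


def noiseless(scenario, times=None):
    """A noiseless copy of a synthetic scenario, optionally re-timed."""
    kwargs = {"noise_cv": 0.0}
    if times is not None:
        kwargs["observation_times"] = np.asarray(times, dtype=float)
    return dataclasses.replace(scenario, **kwargs)
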