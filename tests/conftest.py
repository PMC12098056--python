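import numpy as np
import pytest

from bombusim import (
    FlowerSpecies,
    HandlingConfig,
    LandscapeSpec,
    Patch,
    generate_landscape,
)


@pytest.fixture
def clover():
    return FlowerSpecies(
        name="white_clover",
        corolla_depth_mm=2.0,
        nectar_volume_ul=1.5,
        interflower_travel_s=1.2,
        pollen_per_flower_g=0.002,
        flowering_start_doy=120,
        flowering_end_doy=270,
    )


@pytest.fixture
def patch(clover):
    return Patch(
        patch_id=0,
        x_m=100.0,
        y_m=200.0,
        species=clover,
        n_flowers=400,
        nectar_capacity_ul=500.0,
        nectar_stock_ul=500.0,
        pollen_capacity_g=0.8,
        pollen_stock_g=0.8,
        habitat="permanent_pasture",
    )


@pytest.fixture
def default_landscape():
    return generate_landscape(LandscapeSpec())


@pytest.fixture
def small_landscape():
    """A reduced landscape for fast whole-simulation unit tests."""
    return generate_landscape(LandscapeSpec(n_patches=16, extent_m=2000.0, seed=3))


@pytest.fixture
def fixed900():
    return HandlingConfig(fixed_handling_enabled=True, fixed_handling_time_s=900.0)
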