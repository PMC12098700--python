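import numpy as np
import pandas as pd
import pytest

import hydroshift as hs


@pytest.fixture(scope="session")
def tiny():
    """Hand-authored 2-market, 24-month fixture world with expected tables."""
    world, expected = hs.generate_tiny_fixture()
    return world, expected


@pytest.fixture(scope="session")
def tiny_panel(tiny):
    world, _ = tiny
    return hs.assemble_panel(world.combustion_plants, world.pm25, world.met,
                             world.truth.fhd, world.fire, world.runoff,
                             reference=world.config.reference_period)


def small_config(**overrides):
    """A 5-market, 5-year world: large enough for clustered inference,
    small enough for repeated simulation in tests."""
    base = dict(n_markets=5, n_markets_without_hydro=1,
                hydro_plants_per_market=2, combustion_plants_per_market=2,
                noncombustion_plants_per_market=1, basins_per_market=3,
                start_month="2000-01", end_month="2004-12",
                reference_period=(2000, 2004), seed=0)
    base.update(overrides)
    return hs.WorldConfig(**base)


@pytest.fixture(scope="session")
def small_world():
    return hs.generate_world(small_config(seed=3))


@pytest.fixture(scope="session")
def small_panel(small_world):
    w = small_world
    return hs.assemble_panel(w.combustion_plants, w.pm25, w.met, w.truth.fhd,
                             w.fire, w.runoff, reference=w.config.reference_period)


def make_grid_from(values, months, lat, lon, name="g"):
    from hydroshift.grids import make_grid
    return make_grid(np.asarray(values, dtype=float), months, lat, lon, name=name)


@pytest.fixture
def uniform_grid():
    """3x4 grid over 2 months with constant value 15.76."""
    months = ["2000-01", "2000-02"]
    lat = np.array([0.1, 0.2, 0.3])
    lon = np.array([0.1, 0.2, 0.3, 0.4])
    vals = np.full((2, 3, 4), 15.76)
    return make_grid_from(vals, months, lat, lon)
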