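"""Hand-sized deterministic fixture world.

Two markets, two hydropower and two combustion plants each, 24 months.
The runoff table is authored by hand so the drought chain can be checked
against pencil-and-paper arithmetic; the PM2.5 process is evaluated with
zero noise so the regression stage recovers the true coefficient
exactly. ``generate_tiny_fixture`` returns the world together with the
hand-derived expected tables.

Hand derivation of the drought measures (reference period 2000-2001,
3-month trailing window, strict negative rule):

* ``M00_h1`` (300 MW, watershed = single cell): runoff 2.0 through 2000
  and 1.0 through 2001, so the calendar-month climatology is 1.5 and
  anomalies are +0.5 in 2000 and -0.5 in 2001. The rolled series turns
  negative first at 2001-02 (mean of +0.5, -0.5, -0.5), so the plant is
  in drought 2001-02..2001-12. Anomaly sd = sqrt(24*0.25/23).
* ``M00_h0`` (100 MW, watershed = two cells averaging 2.0 every month):
  anomalies identically zero, never in drought.
  => FHD(M00) = 300/400 = 0.75 from 2001-02 on, else 0 (first two
  months missing); arithmetic variant 0.5; severe variant 0 because
  -0.5 is within one sd of normal.
* ``M01_h1`` (150 MW): runoff 1.0 except 0.4 in 2001-06; climatology for
  June is 0.7, so anomalies are +0.3 (2000-06) and -0.3 (2001-06). The
  rolled series is -0.1 for 2001-06..08; anomaly sd = sqrt(0.18/23) ~
  0.0885 < 0.1, so these months are also severe droughts.
* ``M01_h0`` (50 MW): constant runoff, never in drought.
  => FHD(M01) = 150/200 = 0.75 for 2001-06..08 (severe variant equal),
  else 0; arithmetic variant 0.5.
* Capacity-weighted mean anomalies: M00 = +-0.375 (2000/2001),
  M01 = +0.225 at 2000-06 and -0.225 at 2001-06, else 0.

One fire event is planted at combustion plant ``M00_c0`` in 2000-05,
excluding that plant-month from the analysis sample; plant ``M00_c1``
commissions in 2001, providing pre-operational placebo months.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import xarray as xr

from . import drought
from .grids import make_grid
from .months import month_range
from .synthetic import (WorldConfig, World, _build_met, _finish_world,
                        _grid_coords)

TINY_SEED = 7


def _tiny_config() -> WorldConfig:
    return WorldConfig(n_markets=2, n_markets_without_hydro=0,
                       hydro_plants_per_market=2, combustion_plants_per_market=2,
                       noncombustion_plants_per_market=1, basins_per_market=2,
                       start_month="2000-01", end_month="2001-12",
                       reference_period=(2000, 2001), noise_sd=0.0,
                       fire_event_rate=0.0, drought_episode_rate=0.0,
                       seed=TINY_SEED)


def _tiny_plants(cfg: WorldConfig) -> pd.DataFrame:
    slots = cfg._slots()
    rows = []
    for mi, market in enumerate(("M00", "M01")):
        lon0 = mi * cfg.grid_extent_deg
        c = [("c0", "coal", 40.0, 1995), ("c1", "oil", 20.0, 2001)] if mi == 0 \
            else [("c0", "gas", 100.0, 1995), ("c1", "biomass", 10.0, 1995)]
        for k, (tag, fuel, cap, comm) in enumerate(c):
            la, lo = slots[k]
            rows.append({"plant_id": f"{market}_{tag}", "kind": "combustion",
                         "market": market, "lat": la, "lon": lon0 + lo,
                         "capacity_mw": cap, "fuel": fuel,
                         "commissioning_year": comm, "outlet_basin": None})
        la, lo = slots[2]
        rows.append({"plant_id": f"{market}_w0", "kind": "noncombustion",
                     "market": market, "lat": la, "lon": lon0 + lo,
                     "capacity_mw": 30.0, "fuel": "wind",
                     "commissioning_year": 1995, "outlet_basin": None})
        h = [("h0", 100.0), ("h1", 300.0)] if mi == 0 else [("h0", 50.0), ("h1", 150.0)]
        for k, (tag, cap) in enumerate(h):
            rows.append({"plant_id": f"{market}_{tag}", "kind": "hydro",
                         "market": market, "lat": 1.0 + 0.3 * k,
                         "lon": lon0 + 0.6 + 0.3 * k, "capacity_mw": cap,
                         "fuel": "hydro", "commissioning_year": 1990,
                         "outlet_basin": f"{market}_b{k}" if mi == 1
                         else f"{market}_b{1 - k}"})
    return pd.DataFrame(rows)


def _tiny_basins(n_lat: int, n_lon: int) -> drought.BasinGraph:
    # M00: b0 -> b1 (b1 downstream terminal); single-cell basins.
    # M01: two disconnected single-cell basins.
    cells = {"M00_b0": np.array([5 * n_lon + 2]),
             "M00_b1": np.array([5 * n_lon + 3]),
             "M01_b0": np.array([5 * n_lon + 14]),
             "M01_b1": np.array([5 * n_lon + 16])}
    downstream = {"M00_b0": "M00_b1", "M00_b1": None,
                  "M01_b0": None, "M01_b1": None}
    return drought.BasinGraph(downstream=downstream, cells=cells)


def _tiny_runoff(cfg: WorldConfig):
    months = cfg.months
    lat, lon = _grid_coords(cfg, cfg.runoff_step_deg)
    vals = np.ones((len(months), lat.size, lon.size))
    y2000 = slice(0, 12)
    y2001 = slice(12, 24)
    vals[y2000, 5, 2] = 2.0   # M00_b0: high in 2000,
    vals[y2001, 5, 2] = 1.0   # low in 2001
    vals[y2000, 5, 3] = 2.0   # M00_b1: offsets b0 so the 2-cell mean is flat
    vals[y2001, 5, 3] = 3.0
    vals[17, 5, 16] = 0.4     # M01_b1: one dry month, 2001-06
    return make_grid(vals, months, lat, lon, name="runoff", units="mm/h")


def _tiny_population(cfg: WorldConfig):
    lat, lon = _grid_coords(cfg, cfg.pm25_step_deg)
    vals = np.stack([np.full((lat.size, lon.size), 100.0),
                     np.full((lat.size, lon.size), 120.0)])
    return xr.DataArray(vals, dims=("step_year", "lat", "lon"),
                        coords={"step_year": [2000, 2005], "lat": lat, "lon": lon},
                        name="population")


def _tiny_country() -> pd.DataFrame:
    rows = []
    for y in (2000, 2001):
        rows.append({"country": "M00", "year": y,
                     "frac65": 0.08 + 0.001 * (y - 2000), "gni_usd": 5000.0})
        rows.append({"country": "M01", "year": y, "frac65": 0.10,
                     "gni_usd": 8000.0})
        rows.append({"country": "USA", "year": y, "frac65": 0.16,
                     "gni_usd": 50_000.0})
    return pd.DataFrame(rows)


def expected_tables() -> dict:
    """Hand-derived drought measures for the fixture (see module docstring)."""
    months = month_range("2000-01", "2001-12")
    nan = float("nan")
    fhd = {"M00": [nan] * 2 + [0.0] * 11 + [0.75] * 11,
           "M01": [nan] * 2 + [0.0] * 15 + [0.75] * 3 + [0.0] * 4}
    fhd_arith = {"M00": [nan] * 2 + [0.0] * 11 + [0.5] * 11,
                 "M01": [nan] * 2 + [0.0] * 15 + [0.5] * 3 + [0.0] * 4}
    fhd_severe = {"M00": [nan] * 2 + [0.0] * 22,
                  "M01": [nan] * 2 + [0.0] * 15 + [0.75] * 3 + [0.0] * 4}
    mean_anomaly = {"M00": [0.375] * 12 + [-0.375] * 12,
                    "M01": [0.0] * 5 + [0.225] + [0.0] * 11 + [-0.225] + [0.0] * 6}
    out = {}
    for name, d in (("fhd", fhd), ("fhd_arith", fhd_arith),
                    ("fhd_severe", fhd_severe), ("mean_anomaly", mean_anomaly)):
        out[name] = pd.DataFrame(d, index=months).T
        out[name].index.name = "market"
    out["anomaly_sd"] = {"M00_h0": 0.0, "M00_h1": float(np.sqrt(24 * 0.25 / 23)),
                         "M01_h0": 0.0, "M01_h1": float(np.sqrt(0.18 / 23))}
    out["n_analysis_rows"] = 77  # 96 - 8 warm-up - 10 pre-operational - 1 fire
    return out


def generate_tiny_fixture() -> tuple[World, dict]:
    cfg = _tiny_config()
    plants = _tiny_plants(cfg)
    lat, lon = _grid_coords(cfg, cfg.runoff_step_deg)
    graph = _tiny_basins(lat.size, lon.size)
    runoff = _tiny_runoff(cfg)
    met = _build_met(cfg)
    fire = make_grid(np.zeros(runoff.shape), cfg.months, lat, lon, name="fire")
    # one fire event in the runoff cell containing M00_c0, 2000-05
    c0 = plants.set_index("plant_id").loc["M00_c0"]
    i = int(np.argmin(np.abs(lat - c0["lat"])))
    j = int(np.argmin(np.abs(lon - c0["lon"])))
    fire.values[4, i, j] = 1.5
    population = _tiny_population(cfg)
    country = _tiny_country()
    episodes = pd.DataFrame(columns=["plant_id", "start", "end", "depth"])
    world = _finish_world(cfg, plants, graph, runoff, met, fire, population,
                          country, episodes, base=np.ones((lat.size, lon.size)),
                          amp=0.0, phase={"M00": 0, "M01": 0})
    return world, expected_tables()
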