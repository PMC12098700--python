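"""Synthetic world with a known data-generating process.

Every pipeline input — plant registries, basin topology, gridded monthly
runoff, PM2.5, meteorology, fire emissions, population rasters, country
tables, and projected runoff ensembles — is generated here from an
explicit configurable truth, so estimation, counterfactual, and
projection stages can be verified against known parameters.

Geometry. Markets are synthetic country codes, one market per country,
laid out as square tiles side by side in longitude near the equator.
Emitting plants (combustion and non-combustion) occupy lattice slots
separated by more than twice the dispersion radius, so each plant's
radial mean is uncontaminated by its neighbours; hydropower plants sit
anywhere in the tile and are tied to sub-basins of a per-market river
network. No attempt is made to mimic real geography.

PM2.5 process. The surface equals, cell by cell, the panel-model value
of the nearest emitting plant: plant effect + month-year effect +
market-by-calendar-month effect + controls x gamma + beta x FHD (for
operational combustion plants) + a monthly noise draw shared across the
plant's neighbourhood (spatially correlated within the radius,
independent across months). Wildfire events splash additional PM onto
cells around the burning cell. Runoff is a deterministic calendar-month
seasonal cycle interrupted by scheduled negative-anomaly episodes in
hydropower watersheds — with the episode rate at zero, anomalies vanish
identically and FHD is zero everywhere.

Randomness is stream-split per component (layout, basins, runoff,
meteorology, fire, effects, noise, population, country, projections), so
changing one component's parameters does not shift the draws of others.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import drought, exposure
from .errors import ConfigurationError, ValidationError
from .grids import MonthlyGrid, make_grid
from .months import month_cal, month_range, month_year

_STREAMS = ("layout", "basins", "runoff", "met", "fire", "effects", "noise",
            "population", "country", "projections")

FUEL_PROBS = {"coal": 0.15, "gas": 0.35, "oil": 0.3, "biomass": 0.2}
KM_PER_DEG = 110.0  # conservative near-equator conversion for slot spacing


def _stream(seed: int, name: str) -> np.random.Generator:
    k = _STREAMS.index(name)
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(k,)))


@dataclass
class WorldConfig:
    """Configuration of the synthetic study region.

    Defaults describe the study conditions the pipeline is meant to
    reproduce at desk scale: 22 markets of which 3 lack hydropower (so
    19 markets enter the analysis), a 2000-2020 monthly panel with a
    2000-2019 reference period, a drought effect of 1.55 ug m-3 at
    FHD = 1, and runoff/fire grids at 0.25 deg. The PM2.5/population
    grid step defaults to 0.05 deg: fine enough that a 50 km dispersion
    radius covers ~250 cells, while keeping a full 21-year world cheap
    to regenerate many times.
    """

    n_markets: int = 22
    n_markets_without_hydro: int = 3
    hydro_plants_per_market: int = 3
    combustion_plants_per_market: int = 4
    noncombustion_plants_per_market: int = 1
    basins_per_market: int = 5
    grid_extent_deg: float = 3.0
    runoff_step_deg: float = 0.25
    pm25_step_deg: float = 0.05
    start_month: str = "2000-01"
    end_month: str = "2020-12"
    reference_period: tuple = (2000, 2019)
    true_beta: float = 1.55
    true_beta_by_group: dict | None = None
    true_gamma: dict = field(default_factory=lambda: {
        "temp_c": 0.06, "precip_mm_h": -1.2, "rh_pct": -0.02,
        "pressure_pa": 5e-4, "wind10_m_s": -0.25, "wind100_m_s": 0.1,
        "local_drought": 0.3, "hdd": 0.004, "cdd": 0.004})
    # controls enter the DGP centered at these nominal values so plant
    # effects set the PM2.5 *level*; centering shifts only the absorbed
    # intercepts, never the estimable coefficients
    control_centers: dict = field(default_factory=lambda: {
        "temp_c": 22.0, "precip_mm_h": 0.3, "rh_pct": 70.0,
        "pressure_pa": 101_325.0, "wind10_m_s": 3.0, "wind100_m_s": 3.9,
        "local_drought": 0.0, "hdd": 0.0, "cdd": 60.0})
    fe_scales: dict = field(default_factory=lambda: {
        "plant": 2.0, "month_year": 0.5, "market_calmonth": 0.8})
    plant_effect_mean: float = 15.76
    noise_sd: float = 1.0
    drought_episode_rate: float = 0.08
    episode_duration: int = 4
    episode_depth_range: tuple = (0.3, 0.8)
    fire_event_rate: float = 0.01
    fire_pm_boost: float = 20.0
    fire_splash_km: float = 5.0
    radius_km: float = 50.0
    window: int = 3
    commission_midpanel_share: float = 0.25
    seed: int = 0

    def __post_init__(self):
        for name in ("n_markets", "hydro_plants_per_market",
                     "combustion_plants_per_market", "basins_per_market"):
            if getattr(self, name) < 1:
                raise ConfigurationError(f"{name} must be >= 1")
        if not 0 <= self.n_markets_without_hydro < self.n_markets:
            raise ConfigurationError("n_markets_without_hydro must be in "
                                     "[0, n_markets)")
        if self.runoff_step_deg <= 0 or self.pm25_step_deg <= 0:
            raise ConfigurationError("grid steps must be positive")
        if self.noise_sd < 0:
            raise ConfigurationError("noise_sd must be >= 0")
        months = month_range(self.start_month, self.end_month)
        years = {month_year(m) for m in months}
        y0, y1 = self.reference_period
        if not set(range(y0, y1 + 1)) <= years:
            raise ConfigurationError(f"reference period {self.reference_period} "
                                     "is not a subrange of the panel years")
        self._slots()  # fail fast on infeasible geometry

    @property
    def months(self) -> list[str]:
        return month_range(self.start_month, self.end_month)

    def _slots(self) -> list[tuple[float, float]]:
        """Emitter slot offsets within a tile, separated by > 2 x radius."""
        spacing = 2.0 * self.radius_km / (KM_PER_DEG - 2.0) * 1.02
        margin = spacing / 2.0
        span = self.grid_extent_deg - 2 * margin
        if span < 0:
            raise ConfigurationError("tile too small for the dispersion radius")
        n1 = int(span / spacing) + 1
        coords = [margin + k * spacing for k in range(n1)]
        slots = [(a, b) for a in coords for b in coords]
        center = self.grid_extent_deg / 2
        slots.sort(key=lambda ab: (-((ab[0] - center) ** 2 + (ab[1] - center) ** 2),
                                   ab))
        n_emit = self.combustion_plants_per_market + self.noncombustion_plants_per_market
        if n_emit > len(slots):
            raise ConfigurationError(
                f"{n_emit} emitting plants per market do not fit the tile: only "
                f"{len(slots)} locations keep plants > {2 * self.radius_km:.0f} km "
                "apart (plants denser than the grid geometry allows)")
        return slots


@dataclass
class WorldTruth:
    """Ground truth of the data-generating process."""

    true_beta: float
    true_gamma: dict
    beta_by_plant: pd.Series
    plant_effects: pd.Series
    time_effects: pd.Series
    seasonal_effects: pd.Series
    episodes: pd.DataFrame
    fhd: pd.DataFrame
    mu_panel: pd.DataFrame
    noise_panel: pd.DataFrame
    runoff_base: np.ndarray
    seasonal_amp: float
    market_phase: dict


@dataclass
class World:
    config: WorldConfig
    plants: pd.DataFrame
    basins: drought.BasinGraph
    runoff: MonthlyGrid
    pm25: MonthlyGrid
    fire: MonthlyGrid
    met: dict
    population: MonthlyGrid  # dims (step_year, lat, lon)
    country: pd.DataFrame
    truth: WorldTruth

    @property
    def markets(self) -> list[str]:
        return sorted(self.plants["market"].unique())

    def plants_of_kind(self, kind: str) -> pd.DataFrame:
        return self.plants[self.plants["kind"] == kind].reset_index(drop=True)

    @property
    def hydro_plants(self) -> pd.DataFrame:
        return self.plants_of_kind("hydro")

    @property
    def combustion_plants(self) -> pd.DataFrame:
        return self.plants_of_kind("combustion")

    @property
    def noncombustion_plants(self) -> pd.DataFrame:
        return self.plants_of_kind("noncombustion")


# ---------------------------------------------------------------------------
# Component builders
# ---------------------------------------------------------------------------

def _grid_coords(cfg: WorldConfig, step: float):
    extent = cfg.grid_extent_deg
    per_tile = int(round(extent / step))
    lat = (np.arange(per_tile) + 0.5) * step
    lon = (np.arange(per_tile * cfg.n_markets) + 0.5) * step
    return lat, lon


def _market_codes(cfg: WorldConfig) -> list[str]:
    return [f"M{k:02d}" for k in range(cfg.n_markets)]


def _build_plants(cfg: WorldConfig) -> pd.DataFrame:
    rng = _stream(cfg.seed, "layout")
    slots = cfg._slots()
    rows = []
    markets = _market_codes(cfg)
    hydro_markets = markets[:cfg.n_markets - cfg.n_markets_without_hydro]
    fuels = list(FUEL_PROBS)
    probs = list(FUEL_PROBS.values())
    y0, y1 = month_year(cfg.start_month), month_year(cfg.end_month)
    # mid-panel commissioning keeps clear of both panel edges so the
    # pre-operational placebo has months on each side
    mid_lo, mid_hi = y0 + max(1, (y1 - y0) // 8), y0 + max(2, 3 * (y1 - y0) // 4)
    for mi, market in enumerate(markets):
        lon0 = mi * cfg.grid_extent_deg
        for k in range(cfg.combustion_plants_per_market):
            la, lo = slots[k]
            mid = rng.random() < cfg.commission_midpanel_share
            comm = int(rng.integers(mid_lo, mid_hi + 1)) if mid \
                else int(rng.integers(1970, y0))
            rows.append({"plant_id": f"{market}_c{k}", "kind": "combustion",
                         "market": market, "lat": la, "lon": lon0 + lo,
                         "capacity_mw": float(np.exp(rng.normal(3.4, 1.2))),
                         "fuel": rng.choice(fuels, p=probs),
                         "commissioning_year": comm, "outlet_basin": None})
        for k in range(cfg.noncombustion_plants_per_market):
            la, lo = slots[cfg.combustion_plants_per_market + k]
            rows.append({"plant_id": f"{market}_w{k}", "kind": "noncombustion",
                         "market": market, "lat": la, "lon": lon0 + lo,
                         "capacity_mw": float(np.exp(rng.normal(3.0, 0.8))),
                         "fuel": "wind", "commissioning_year": 1995,
                         "outlet_basin": None})
        if market in hydro_markets:
            for k in range(cfg.hydro_plants_per_market):
                rows.append({"plant_id": f"{market}_h{k}", "kind": "hydro",
                             "market": market,
                             "lat": float(rng.uniform(0.2, cfg.grid_extent_deg - 0.2)),
                             "lon": lon0 + float(rng.uniform(0.2, cfg.grid_extent_deg - 0.2)),
                             "capacity_mw": float(np.exp(rng.normal(4.6, 0.8))),
                             "fuel": "hydro", "commissioning_year": 1990,
                             "outlet_basin": None})  # assigned with the basins
    return pd.DataFrame(rows)


def _build_basins(cfg: WorldConfig, plants: pd.DataFrame,
                  n_lat: int, n_lon: int) -> drought.BasinGraph:
    """Per-market river networks: column stripes of runoff cells linked
    into a random forest; hydro outlets drawn among the market's basins."""
    rng = _stream(cfg.seed, "basins")
    per_tile = int(round(cfg.grid_extent_deg / cfg.runoff_step_deg))
    downstream, cells = {}, {}
    markets = _market_codes(cfg)
    for mi, market in enumerate(markets):
        cols = np.arange(mi * per_tile, (mi + 1) * per_tile)
        stripes = np.array_split(cols, cfg.basins_per_market)
        ids = [f"{market}_b{k}" for k in range(cfg.basins_per_market)]
        for k, bid in enumerate(ids):
            flat = (np.arange(n_lat)[:, None] * n_lon + stripes[k][None, :]).ravel()
            cells[bid] = flat
            if k == 0:
                downstream[bid] = None
            else:
                # point to an earlier basin or terminate; earlier-only => acyclic
                choice = int(rng.integers(-1, k))
                downstream[bid] = None if choice < 0 else ids[choice]
        hydro = plants[(plants["market"] == market) & (plants["kind"] == "hydro")]
        for idx in hydro.index:
            plants.at[idx, "outlet_basin"] = ids[int(rng.integers(len(ids)))]
    return drought.BasinGraph(downstream=downstream, cells=cells)


def _build_runoff(cfg: WorldConfig, plants: pd.DataFrame,
                  graph: drought.BasinGraph):
    rng = _stream(cfg.seed, "runoff")
    months = cfg.months
    lat, lon = _grid_coords(cfg, cfg.runoff_step_deg)
    n_lat, n_lon = lat.size, lon.size
    base = rng.uniform(0.5, 3.0, size=(n_lat, n_lon))
    amp = 0.4
    markets = _market_codes(cfg)
    phase = {m: int(rng.integers(0, 12)) for m in markets}
    per_tile = int(round(cfg.grid_extent_deg / cfg.runoff_step_deg))
    cal = np.array([month_cal(m) for m in months])
    seasonal = np.ones((len(months), n_lat, n_lon))
    for mi, market in enumerate(markets):
        sl = slice(mi * per_tile, (mi + 1) * per_tile)
        s = 1.0 + amp * np.sin(2 * np.pi * (cal - phase[market]) / 12.0)
        seasonal[:, :, sl] = s[:, None, None]

    # scheduled negative-anomaly episodes per hydropower watershed
    reduction = np.ones((len(months), n_lat * n_lon))
    episodes = []
    hydro = plants[plants["kind"] == "hydro"]
    for _, p in hydro.iterrows():
        basins = drought.delineate_watershed(graph, p["outlet_basin"])
        flat = np.unique(np.concatenate([graph.cells[b] for b in basins]))
        starts = np.nonzero(rng.random(len(months)) < cfg.drought_episode_rate)[0]
        depths = rng.uniform(*cfg.episode_depth_range, size=starts.size)
        for t0, depth in zip(starts, depths):
            t1 = min(t0 + cfg.episode_duration, len(months))
            reduction[t0:t1][:, flat] *= (1.0 - depth)
            episodes.append({"plant_id": p["plant_id"], "start": months[t0],
                             "end": months[t1 - 1], "depth": float(depth)})
    values = base[None] * seasonal * reduction.reshape(len(months), n_lat, n_lon)
    grid = make_grid(values, months, lat, lon, name="runoff", units="mm/h")
    return grid, pd.DataFrame(episodes, columns=["plant_id", "start", "end", "depth"]), \
        base, amp, phase


def _build_met(cfg: WorldConfig) -> dict:
    rng = _stream(cfg.seed, "met")
    months = cfg.months
    lat, lon = _grid_coords(cfg, cfg.runoff_step_deg)
    shape = (len(months), lat.size, lon.size)
    cal = np.array([month_cal(m) for m in months])[:, None, None]
    s = np.sin(2 * np.pi * cal / 12.0)
    temp = 22.0 + 6.0 * s + rng.uniform(-2, 2, shape[1:])[None] + rng.normal(0, 0.8, shape)
    precip = np.clip(0.3 + 0.2 * s + rng.normal(0, 0.08, shape), 0.0, None)
    rh = np.clip(70.0 + 8.0 * s + rng.normal(0, 3.0, shape), 5.0, 100.0)
    pressure = 101_325.0 + rng.uniform(-300, 300, shape[1:])[None] + rng.normal(0, 80.0, shape)
    wind10 = np.clip(3.0 + rng.normal(0, 0.6, shape), 0.1, None)
    wind100 = wind10 * 1.3 + rng.normal(0, 0.3, shape)
    fields = {"temp": (temp, "degC"), "precip": (precip, "mm/h"), "rh": (rh, "%"),
              "pressure": (pressure, "Pa"), "wind10": (wind10, "m/s"),
              "wind100": (wind100, "m/s")}
    return {k: make_grid(v, months, lat, lon, name=k, units=u)
            for k, (v, u) in fields.items()}


def _build_fire(cfg: WorldConfig) -> MonthlyGrid:
    rng = _stream(cfg.seed, "fire")
    months = cfg.months
    lat, lon = _grid_coords(cfg, cfg.runoff_step_deg)
    shape = (len(months), lat.size, lon.size)
    events = rng.random(shape) < cfg.fire_event_rate
    emission = np.where(events, np.exp(rng.normal(0.0, 1.0, shape)), 0.0)
    return make_grid(emission, months, lat, lon, name="fire", units="gC/m2/month")


def _build_population(cfg: WorldConfig):
    rng = _stream(cfg.seed, "population")
    lat, lon = _grid_coords(cfg, cfg.pm25_step_deg)
    base = np.exp(rng.normal(np.log(800.0), 1.0, size=(lat.size, lon.size)))
    y0, y1 = month_year(cfg.start_month), month_year(cfg.end_month)
    steps = list(range(y0 - y0 % 5, y1 + 1, 5))
    if len(steps) < 2:  # short panels still get an interpolable pair
        steps.append(steps[-1] + 5)
    per_tile = int(round(cfg.grid_extent_deg / cfg.pm25_step_deg))
    growth = rng.uniform(1.03, 1.12, size=cfg.n_markets)
    vals = np.empty((len(steps), lat.size, lon.size))
    for si in range(len(steps)):
        for mi in range(cfg.n_markets):
            sl = slice(mi * per_tile, (mi + 1) * per_tile)
            vals[si, :, sl] = base[:, sl] * growth[mi] ** si
    import xarray as xr
    return xr.DataArray(vals, dims=("step_year", "lat", "lon"),
                        coords={"step_year": steps, "lat": lat, "lon": lon},
                        name="population")


def _build_country(cfg: WorldConfig) -> pd.DataFrame:
    rng = _stream(cfg.seed, "country")
    years = sorted({month_year(m) for m in cfg.months})
    rows = []
    for market in _market_codes(cfg):
        off = float(rng.uniform(-0.01, 0.03))
        gni0 = float(rng.uniform(4000, 16000))
        g = float(rng.uniform(0.0, 0.03))
        for y in years:
            rows.append({"country": market, "year": y,
                         "frac65": 0.055 + 0.0015 * (y - years[0]) + off,
                         "gni_usd": gni0 * (1.02 + g) ** (y - years[0])})
    for y in years:
        rows.append({"country": "USA", "year": y, "frac65": 0.16,
                     "gni_usd": 48_000.0 * 1.015 ** (y - years[0])})
    return pd.DataFrame(rows)


def _beta_by_plant(cfg: WorldConfig, comb: pd.DataFrame) -> pd.Series:
    grp = cfg.true_beta_by_group or {}
    out = pd.Series(cfg.true_beta, index=comb["plant_id"].values, dtype=float)
    if "fuel" in grp:
        for fuel, b in grp["fuel"].items():
            out[comb.loc[comb["fuel"] == fuel, "plant_id"].values] = b
    if "size" in grp:
        large = comb["capacity_mw"] >= 30.0
        out[comb.loc[large, "plant_id"].values] = grp["size"].get("large", cfg.true_beta)
        out[comb.loc[~large, "plant_id"].values] = grp["size"].get("small", cfg.true_beta)
    return out


def _design_panel(cfg: WorldConfig, plants: pd.DataFrame, met: dict,
                  fhd_df: pd.DataFrame, fire: MonthlyGrid,
                  runoff: MonthlyGrid) -> pd.DataFrame:
    """Regression design for a plant subset via the same assembly code
    the analysis uses, guaranteeing generator/estimator consistency."""
    zero_pm = make_grid(np.zeros(runoff.shape), cfg.months,
                        runoff["lat"].values, runoff["lon"].values, name="pm25")
    return exposure.assemble_panel(plants, zero_pm, met, fhd_df, fire, runoff,
                                   reference=cfg.reference_period,
                                   radius_km=cfg.radius_km, window=cfg.window)


def _pm_from_mu(mu_eps: np.ndarray, emitters: pd.DataFrame, cfg: WorldConfig,
                fire: MonthlyGrid) -> MonthlyGrid:
    """Voronoi surface: each PM cell carries the panel value of the
    nearest emitter; fire events splash extra PM locally."""
    months = cfg.months
    lat, lon = _grid_coords(cfg, cfg.pm25_step_deg)
    lat2d, lon2d = np.meshgrid(lat, lon, indexing="ij")
    # nearest-emitter assignment with an equirectangular metric; at tile
    # scale near the equator its ordering agrees with haversine far within
    # the slot-separation margin, so disk cells always map to their plant
    plat = emitters["lat"].to_numpy(float)
    plon = emitters["lon"].to_numpy(float)
    flat_lat = lat2d.ravel()
    flat_lon = lon2d.ravel()
    coslat = np.cos(np.radians(flat_lat))
    owner = np.empty(flat_lat.size, dtype=int)
    # per-tile competition: only emitters of the tile and its neighbours
    # can be nearest to a cell of that tile
    extent = cfg.grid_extent_deg
    tile_of_cell = np.floor(flat_lon / extent).astype(int)
    tile_of_emit = np.floor(plon / extent).astype(int)
    for tile in np.unique(tile_of_cell):
        cells = np.nonzero(tile_of_cell == tile)[0]
        cand = np.nonzero(np.abs(tile_of_emit - tile) <= 1)[0]
        d2 = ((flat_lat[cells, None] - plat[None, cand]) ** 2
              + (coslat[cells, None] * (flat_lon[cells, None] - plon[None, cand])) ** 2)
        owner[cells] = cand[np.argmin(d2, axis=1)]
    vals = np.ascontiguousarray(mu_eps.T)[:, owner].reshape(
        len(months), lat.size, lon.size)

    if cfg.fire_pm_boost > 0:
        t_idx, fi, fj = np.nonzero(fire.values > 0)
        flat_f = np.asarray(fire["lat"].values), np.asarray(fire["lon"].values)
        dlat = cfg.fire_splash_km / 110.0
        # precomputed splash windows per fire-grid row/column
        ilo = np.searchsorted(lat, flat_f[0] - dlat, side="left")
        ihi = np.searchsorted(lat, flat_f[0] + dlat, side="right")
        jlo = np.searchsorted(lon, flat_f[1] - dlat * 1.01, side="left")
        jhi = np.searchsorted(lon, flat_f[1] + dlat * 1.01, side="right")
        fvals = fire.values
        for t, i, j in zip(t_idx, fi, fj):
            vals[t, ilo[i]:ihi[i], jlo[j]:jhi[j]] += cfg.fire_pm_boost * fvals[t, i, j]
    return make_grid(vals, months, lat, lon, name="pm25", units="ug/m3")


# ---------------------------------------------------------------------------
# Main entry points
# ---------------------------------------------------------------------------

def generate_world(config: WorldConfig | None = None) -> World:
    """Generate every pipeline input plus the ground truth; deterministic
    given (config, seed)."""
    cfg = config or WorldConfig()
    plants = _build_plants(cfg)
    lat, lon = _grid_coords(cfg, cfg.runoff_step_deg)
    graph = _build_basins(cfg, plants, lat.size, lon.size)
    runoff, episodes, base, amp, phase = _build_runoff(cfg, plants, graph)
    met = _build_met(cfg)
    fire = _build_fire(cfg)
    population = _build_population(cfg)
    country = _build_country(cfg)
    return _finish_world(cfg, plants, graph, runoff, met, fire, population,
                         country, episodes, base, amp, phase)


def _finish_world(cfg: WorldConfig, plants: pd.DataFrame,
                  graph: drought.BasinGraph, runoff: MonthlyGrid, met: dict,
                  fire: MonthlyGrid, population, country: pd.DataFrame,
                  episodes: pd.DataFrame, base: np.ndarray, amp: float,
                  phase: dict) -> World:
    """Evaluate the PM2.5 data-generating process on already-built inputs."""
    months = cfg.months
    hydro = plants[plants["kind"] == "hydro"]
    markets = _market_codes(cfg)
    fhd_df = drought.market_exposure(runoff, graph, hydro, window=cfg.window,
                                     reference=cfg.reference_period,
                                     markets=markets)

    comb = plants[plants["kind"] == "combustion"]
    nonc = plants[plants["kind"] == "noncombustion"]
    designs = {"combustion": _design_panel(cfg, comb, met, fhd_df, fire, runoff),
               "noncombustion": _design_panel(cfg, nonc, met, fhd_df, fire, runoff)}

    rng_eff = _stream(cfg.seed, "effects")
    emitters = pd.concat([comb, nonc], ignore_index=True)
    plant_effects = pd.Series(
        rng_eff.normal(cfg.plant_effect_mean, cfg.fe_scales["plant"], len(emitters)),
        index=emitters["plant_id"].values)
    time_effects = pd.Series(
        rng_eff.normal(0.0, cfg.fe_scales["month_year"], len(months)), index=months)
    seas_index = [f"{m}:{c}" for m in markets for c in range(1, 13)]
    seasonal_effects = pd.Series(
        rng_eff.normal(0.0, cfg.fe_scales["market_calmonth"], len(seas_index)),
        index=seas_index)
    beta_plant = _beta_by_plant(cfg, comb)

    gamma = pd.Series(cfg.true_gamma)
    centers = pd.Series(cfg.control_centers).reindex(gamma.index).fillna(0.0)
    mu_rows = {}
    for kind, design in designs.items():
        d = design.set_index(["plant_id", "month"])
        x = d[list(gamma.index)].fillna(0.0) - centers
        mu = (plant_effects.reindex(d.index.get_level_values(0)).values
              + time_effects.reindex(d.index.get_level_values(1)).values
              + seasonal_effects.reindex(d["market_calmonth"]).values
              + x.values @ gamma.values)
        if kind == "combustion":
            b = beta_plant.reindex(d.index.get_level_values(0)).values
            mu = mu + b * d["fhd"].fillna(0.0).values * d["operational"].values
        mu_rows.update(dict(zip(d.index, mu)))
    mu_panel = pd.Series(mu_rows).unstack()
    mu_panel = mu_panel.reindex(index=emitters["plant_id"].values, columns=months)

    rng_noise = _stream(cfg.seed, "noise")
    noise = rng_noise.normal(0.0, cfg.noise_sd, size=mu_panel.shape) \
        if cfg.noise_sd > 0 else np.zeros(mu_panel.shape)
    noise_panel = pd.DataFrame(noise, index=mu_panel.index, columns=months)

    pm25 = _pm_from_mu(mu_panel.values + noise, emitters, cfg, fire)

    truth = WorldTruth(true_beta=cfg.true_beta, true_gamma=dict(cfg.true_gamma),
                       beta_by_plant=beta_plant, plant_effects=plant_effects,
                       time_effects=time_effects, seasonal_effects=seasonal_effects,
                       episodes=episodes, fhd=fhd_df, mu_panel=mu_panel,
                       noise_panel=noise_panel, runoff_base=base,
                       seasonal_amp=amp, market_phase=phase)
    return World(config=cfg, plants=plants, basins=graph, runoff=runoff,
                 pm25=pm25, fire=fire, met=met, population=population,
                 country=country, truth=truth)


# ---------------------------------------------------------------------------
# Projected runoff ensembles
# ---------------------------------------------------------------------------

PROJECTION_START = "2019-11"  # two warm-up months so the 3-month window
PROJECTION_END = "2059-12"    # is complete from 2020-01 onward


def projection_drying_trends(n_models: int = 22,
                             scenarios=("SSP1-2.6", "SSP2-4.5", "SSP3-7.0"),
                             seed: int = 0) -> pd.DataFrame:
    """End-of-horizon fractional runoff decline per (model, scenario).

    Models share a persistent offset across scenarios; scenario means
    rise with climate forcing, so the imposed ordering SSP1 < SSP2 <
    SSP3 can be checked against recovered FHD changes.
    """
    rng = _stream(seed, "projections")
    scen_mean = {"SSP1-2.6": 0.08, "SSP2-4.5": 0.12, "SSP3-7.0": 0.16}
    rows = []
    for k in range(n_models):
        model = f"model{k:02d}"
        off = float(rng.normal(0.0, 0.04))
        for s in scenarios:
            rows.append({"model": model, "ssp_rcp": s,
                         "drying": float(np.clip(scen_mean.get(s, 0.1) + off,
                                                 -0.3, 0.8))})
    return pd.DataFrame(rows)


def generate_projection_runoff(world: World, model: str, ssp_rcp: str,
                               drying: float, proj_noise_sd: float = 0.15
                               ) -> MonthlyGrid:
    """Monthly runoff 2019-11..2059-12 for one (model, scenario).

    The historical seasonal cycle is scaled down by a linearly growing
    drying factor and perturbed by multiplicative month-cell noise, so
    projected anomalies against the historical climatology drift
    negative at a model- and scenario-specific pace.
    """
    cfg = world.config
    t = world.truth
    months = month_range(PROJECTION_START, PROJECTION_END)
    lat, lon = _grid_coords(cfg, cfg.runoff_step_deg)
    cal = np.array([month_cal(m) for m in months])
    per_tile = int(round(cfg.grid_extent_deg / cfg.runoff_step_deg))
    seasonal = np.ones((len(months), lat.size, lon.size))
    for mi, market in enumerate(_market_codes(cfg)):
        sl = slice(mi * per_tile, (mi + 1) * per_tile)
        s = 1.0 + t.seasonal_amp * np.sin(2 * np.pi * (cal - t.market_phase[market]) / 12.0)
        seasonal[:, :, sl] = s[:, None, None]
    progress = np.arange(len(months)) / max(len(months) - 1, 1)
    trend = (1.0 - drying * progress)[:, None, None]
    sub = np.random.SeedSequence(cfg.seed,
                                 spawn_key=(_STREAMS.index("projections"),
                                            abs(hash((model, ssp_rcp))) % (2**31)))
    rng = np.random.default_rng(sub)
    noise = 1.0 + rng.normal(0.0, proj_noise_sd, size=seasonal.shape)
    vals = np.clip(t.runoff_base[None] * seasonal * trend * noise, 0.0, None)
    return make_grid(vals, months, lat, lon, name="runoff", units="mm/h")


def projection_fhd_ensemble(world: World, n_models: int = 22,
                            scenarios=("SSP1-2.6", "SSP2-4.5", "SSP3-7.0"),
                            proj_noise_sd: float = 0.15) -> tuple[dict, pd.DataFrame]:
    """FHD tables for the full (model x scenario) ensemble.

    Grids are generated one at a time and reduced to FHD immediately, so
    memory stays bounded; returns ``(ensemble, trends)`` where ensemble
    maps (model, ssp_rcp) -> long FHD table.
    """
    from . import projections as proj
    trends = projection_drying_trends(n_models, scenarios, seed=world.config.seed)
    hist = drought.watershed_series_by_plant(world.runoff, world.basins,
                                             world.hydro_plants,
                                             world.config.reference_period)
    ensemble = {}
    for _, row in trends.iterrows():
        grid = generate_projection_runoff(world, row["model"], row["ssp_rcp"],
                                          row["drying"], proj_noise_sd)
        fhd = proj.projected_fhd(grid, world.basins, world.hydro_plants, hist,
                                 window=world.config.window,
                                 markets=world.markets)
        ensemble[(row["model"], row["ssp_rcp"])] = fhd
    return ensemble, trends
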