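"""Combustion-plant panel construction.

Builds the plant-month analysis table: radial PM2.5 and meteorology
means inside each plant's 50 km dispersion area, wildfire (and optional
dust) exclusion filters, heating/cooling degree-days, Thiessen-
partitioned population exposure, and the elderly-population series used
by the mortality calculation.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from . import drought
from .errors import ValidationError
from .geo import haversine_km
from .grids import MonthlyGrid, cells_within_radius, grid_months
from .months import days_in_month, month_cal, month_year

DEFAULT_RADIUS_KM = 50.0
HDD_REFERENCE_C = 18.0
HDD_THRESHOLD_C = 15.0
CDD_REFERENCE_C = 18.0
CDD_THRESHOLD_C = 21.0

FUEL_TYPES = ("coal", "gas", "oil", "biomass")
# registry fuels folded into the four analysis classes
FUEL_ALIASES = {"petcoke": "oil", "waste": "biomass"}


def normalize_fuel(fuel: str) -> str:
    f = FUEL_ALIASES.get(str(fuel).lower(), str(fuel).lower())
    if f not in FUEL_TYPES:
        raise ValidationError(f"unknown combustion fuel {fuel!r}")
    return f


# ---------------------------------------------------------------------------
# Radial means
# ---------------------------------------------------------------------------

def radial_mean(grid: MonthlyGrid, lat: float, lon: float,
                radius_km: float = DEFAULT_RADIUS_KM,
                plant_id=None) -> pd.Series:
    """Unweighted mean over cells whose centers lie within ``radius_km``."""
    ii, jj = cells_within_radius(grid, lat, lon, radius_km)
    if ii.size == 0:
        who = f" for plant {plant_id}" if plant_id is not None else ""
        raise ValidationError(f"no grid cells within {radius_km} km of "
                              f"({lat:.3f}, {lon:.3f}){who}")
    return pd.Series(grid.values[:, ii, jj].mean(axis=1), index=grid_months(grid))


def radial_mean_table(grid: MonthlyGrid, plants: pd.DataFrame,
                      radius_km: float = DEFAULT_RADIUS_KM) -> pd.DataFrame:
    """Plant x month table of radial means for every plant in the registry."""
    months = grid_months(grid)
    coords = (grid["lat"].values, grid["lon"].values)
    values = grid.values
    out = np.empty((len(plants), len(months)))
    for k, (_, p) in enumerate(plants.iterrows()):
        ii, jj = cells_within_radius(coords, p["lat"], p["lon"], radius_km)
        if ii.size == 0:
            raise ValidationError(f"no grid cells within {radius_km} km of plant "
                                  f"{p['plant_id']}")
        out[k] = values[:, ii, jj].mean(axis=1)
    return pd.DataFrame(out, index=pd.Index(plants["plant_id"], name="plant_id"),
                        columns=months)


# ---------------------------------------------------------------------------
# Degree-days
# ---------------------------------------------------------------------------

def degree_days(temp_c, n_days):
    """Heating and cooling degree-days for a monthly mean temperature.

    HDD uses an 18 degC reference activated below a 15 degC threshold;
    CDD uses an 18 degC reference activated above a 21 degC threshold
    (IEA convention): hdd = days*(18 - T) when T <= 15 else 0, and
    cdd = days*(T - 18) when T >= 21 else 0. In the dead band 15 < T < 21
    both are zero, so they are never simultaneously positive.
    """
    t = np.asarray(temp_c, dtype=float)
    d = np.asarray(n_days, dtype=float)
    hdd = np.where(t <= HDD_THRESHOLD_C, d * (HDD_REFERENCE_C - t), 0.0)
    cdd = np.where(t >= CDD_THRESHOLD_C, d * (t - CDD_REFERENCE_C), 0.0)
    if np.ndim(temp_c) == 0:
        return float(hdd), float(cdd)
    return hdd, cdd


# ---------------------------------------------------------------------------
# Fire / dust exclusion
# ---------------------------------------------------------------------------

def fire_free_table(plants: pd.DataFrame, fire_grid: MonthlyGrid,
                    radius_km: float = DEFAULT_RADIUS_KM) -> pd.DataFrame:
    """Plant x month boolean table: True when no positive fire-emission
    cell lies within ``radius_km`` of the plant that month."""
    if radius_km <= 0:
        raise ValidationError(f"radius must be positive, got {radius_km}")
    months = grid_months(fire_grid)
    coords = (fire_grid["lat"].values, fire_grid["lon"].values)
    values = fire_grid.values
    out = np.ones((len(plants), len(months)), dtype=bool)
    for k, (_, p) in enumerate(plants.iterrows()):
        ii, jj = cells_within_radius(coords, p["lat"], p["lon"], radius_km)
        if ii.size:
            out[k] = ~(values[:, ii, jj] > 0).any(axis=1)
    return pd.DataFrame(out, index=pd.Index(plants["plant_id"], name="plant_id"),
                        columns=months)


def exclusion_filter(panel: pd.DataFrame, plants: pd.DataFrame,
                     fire_grid: MonthlyGrid,
                     radius_km: float = DEFAULT_RADIUS_KM,
                     dust_seasonal_map: pd.DataFrame | None = None,
                     dust_season_months: dict | None = None):
    """Drop plant-months with fire (and optionally dust) activity nearby.

    Returns ``(filtered_panel, drop_log)`` where the log lists one row
    per dropped plant-month with the reason. ``dust_seasonal_map`` is a
    table (lat, lon, season) of dust-source cells and
    ``dust_season_months`` maps season name -> list of calendar months;
    the hemisphere-dependent season mapping is an explicit input.
    """
    ok = fire_free_table(plants, fire_grid, radius_km)
    keys = panel.set_index(["plant_id", "month"]).index
    fire_ok = pd.Series([ok.at[p, m] for p, m in keys], index=panel.index)
    reasons = pd.Series("fire_within_radius", index=panel.index)

    if dust_seasonal_map is not None:
        if dust_season_months is None:
            raise ValidationError("dust filtering requires a season->months mapping")
        coords = plants.set_index("plant_id")[["lat", "lon"]]
        dust_ok = pd.Series(True, index=panel.index)
        for idx, row in panel.iterrows():
            cm = month_cal(row["month"])
            active = dust_seasonal_map[[cm in dust_season_months[s]
                                        for s in dust_seasonal_map["season"]]]
            if len(active) == 0:
                continue
            lat0, lon0 = coords.loc[row["plant_id"]]
            d = haversine_km(active["lat"].values, active["lon"].values, lat0, lon0)
            if (d <= radius_km).any():
                dust_ok.loc[idx] = False
        reasons[~dust_ok & ~fire_ok] = "fire_and_dust_within_radius"
        reasons[~dust_ok & fire_ok] = "dust_within_radius"
        keep = fire_ok & dust_ok
    else:
        keep = fire_ok

    drop_log = panel.loc[~keep, ["plant_id", "month"]].copy()
    drop_log["reason"] = reasons[~keep]
    drop_log["radius_km"] = radius_km
    return panel.loc[keep].copy(), drop_log.reset_index(drop=True)


# ---------------------------------------------------------------------------
# Population exposure
# ---------------------------------------------------------------------------

def thiessen_population(plants: pd.DataFrame, pop_raster,
                        radius_km: float = DEFAULT_RADIUS_KM) -> pd.DataFrame:
    """Population within ``radius_km`` of each plant, without double counting.

    Every populated cell lying within the radius of at least one plant is
    assigned to its nearest plant (great-circle); the per-plant exposure
    is the sum of its assigned cells, so summing over plants recovers the
    population of the union of the radii exactly. Coincident plants are
    tie-broken by plant id (a warning is emitted).

    ``pop_raster`` is a DataArray with dims ``(step_year, lat, lon)`` (or
    ``(lat, lon)`` for a single snapshot). Returns plants x step_year.
    """
    lat = np.asarray(pop_raster["lat"].values, dtype=float)
    lon = np.asarray(pop_raster["lon"].values, dtype=float)
    lat2d, lon2d = np.meshgrid(lat, lon, indexing="ij")
    plat = plants["lat"].to_numpy(float)
    plon = plants["lon"].to_numpy(float)
    pid = plants["plant_id"].to_numpy()
    if len(np.unique(np.stack([plat, plon], axis=1), axis=0)) < len(plants):
        warnings.warn("coincident plant coordinates; ties broken by plant id",
                      stacklevel=2)

    best_d = np.full(lat2d.shape, np.inf)
    owner = np.full(lat2d.shape, -1, dtype=int)
    order = np.argsort(pid.astype(str))  # id order => deterministic tie-break
    for k in order:
        d = haversine_km(lat2d, lon2d, plat[k], plon[k])
        closer = d < best_d - 1e-12  # strictly closer wins; ties keep earlier id
        best_d = np.where(closer, d, best_d)
        owner = np.where(closer, k, owner)
    in_union = best_d <= radius_km

    values = pop_raster.values
    single = values.ndim == 2
    if single:
        values = values[None]
        steps = [0]
    else:
        steps = [int(s) for s in pop_raster["step_year"].values]
    out = np.zeros((len(plants), len(steps)))
    for k in range(len(plants)):
        mask = in_union & (owner == k)
        out[k] = values[:, mask].sum(axis=1)
    res = pd.DataFrame(out, index=pd.Index(pid, name="plant_id"), columns=steps)
    return res[0] if single else res


def interpolate_population(step_counts: pd.DataFrame, years: list[int] | None = None
                           ) -> pd.DataFrame:
    """Linear interpolation of per-plant counts between step years.

    No extrapolation: requested years outside the step range raise. A
    single step yields a constant series with a warning.
    """
    cols = sorted(int(c) for c in step_counts.columns)
    if years is None:
        years = list(range(cols[0], cols[-1] + 1))
    if len(cols) < 2:
        warnings.warn("single population step; returning a constant series",
                      stacklevel=2)
        return pd.DataFrame({y: step_counts[cols[0]] for y in years})
    if min(years) < cols[0] or max(years) > cols[-1]:
        raise ValidationError(f"years {min(years)}..{max(years)} extend beyond "
                              f"population steps {cols[0]}..{cols[-1]}")
    x = np.asarray(cols, dtype=float)
    vals = step_counts[cols].to_numpy(float)
    out = np.array([[np.interp(float(y), x, row) for y in years] for row in vals])
    return pd.DataFrame(out, index=step_counts.index, columns=years)


def elderly_population(annual_counts: pd.DataFrame, frac65: pd.DataFrame,
                       plant_country: pd.Series) -> pd.DataFrame:
    """All-age exposure times the country-year fraction aged 65+.

    Assumes a uniform age distribution within each country (the age
    structure is only available nationally).
    """
    f = frac65.set_index(["country", "year"])["frac65"]
    out = {}
    for pid, row in annual_counts.iterrows():
        country = plant_country.loc[pid]
        fr = []
        for y in annual_counts.columns:
            key = (country, int(y))
            if key not in f.index:
                raise ValidationError(f"missing 65+ fraction for {key}")
            fr.append(f.loc[key])
        out[pid] = row.values * np.asarray(fr)
    res = pd.DataFrame(out, index=annual_counts.columns).T
    res.index.name = "plant_id"
    return res


# ---------------------------------------------------------------------------
# Panel assembly
# ---------------------------------------------------------------------------

MET_COLUMNS = {"temp": "temp_c", "precip": "precip_mm_h", "rh": "rh_pct",
               "pressure": "pressure_pa", "wind10": "wind10_m_s",
               "wind100": "wind100_m_s"}


def local_drought_table(plants: pd.DataFrame, runoff: MonthlyGrid,
                        reference: tuple, window: int = 3) -> pd.DataFrame:
    """Binary local-drought control per plant-month.

    Defined analogously to the hydropower indicator but at the plant's
    own location: the runoff anomaly of the grid cell containing the
    plant, rolled over ``window`` months and flagged when negative.
    """
    lat = np.asarray(runoff["lat"].values, float)
    lon = np.asarray(runoff["lon"].values, float)
    out = {}
    for _, p in plants.iterrows():
        i = int(np.argmin(np.abs(lat - p["lat"])))
        j = int(np.argmin(np.abs(lon - p["lon"])))
        series = pd.Series(runoff.values[:, i, j], index=grid_months(runoff))
        ws = drought.compute_anomalies(series, reference)
        rolled = drought.rolling_anomaly(ws.anomaly, window)
        out[p["plant_id"]] = drought.drought_indicator(rolled, "negative")
    table = pd.DataFrame(out).T
    table.index.name = "plant_id"
    return table


def assemble_panel(plants: pd.DataFrame, pm25: MonthlyGrid, met: dict,
                   exposure_df: pd.DataFrame, fire_grid: MonthlyGrid,
                   runoff: MonthlyGrid, reference: tuple = (2000, 2019),
                   radius_km: float = DEFAULT_RADIUS_KM,
                   window: int = 3) -> pd.DataFrame:
    """One row per plant-month with outcome, controls, and sample flags.

    Sample flags rather than physical row deletion keep the bookkeeping
    auditable: ``in_analysis`` = operational AND fire-free AND market has
    hydropower AND all regressors observed.
    """
    months = grid_months(pm25)
    tabs = {"pm25": radial_mean_table(pm25, plants, radius_km)}
    for k, g in met.items():
        tabs[MET_COLUMNS[k]] = radial_mean_table(g, plants, radius_km)
    tabs["local_drought"] = local_drought_table(plants, runoff, reference, window)
    tabs["fire_free"] = fire_free_table(plants, fire_grid, radius_km)

    pids = tabs["pm25"].index.to_numpy()
    n_p, n_m = len(pids), len(months)
    panel = pd.DataFrame({"plant_id": np.repeat(pids, n_m),
                          "month": np.tile(np.asarray(months), n_p)})
    for name, t in tabs.items():
        panel[name] = t.reindex(index=pids, columns=months).to_numpy().ravel()
    pattrs = plants.set_index("plant_id")[["market", "capacity_mw", "fuel",
                                           "commissioning_year"]]
    orphans = set(panel["plant_id"]) - set(pattrs.index)
    if orphans:
        raise ValidationError(f"plant-month rows without registry entry: "
                              f"{sorted(orphans)[:5]}")
    panel = panel.join(pattrs, on="plant_id")
    panel["year"] = panel["month"].str[:4].astype(int)
    panel["calmonth"] = panel["month"].str[5:7].astype(int)
    panel["market_calmonth"] = (panel["market"].astype(str) + ":"
                                + panel["calmonth"].astype(str))
    panel["operational"] = (panel["year"] >= panel["commissioning_year"]).astype(int)

    fhd = exposure_df.set_index(["market", "month"])["fhd"]
    panel["fhd"] = fhd.reindex(pd.MultiIndex.from_frame(panel[["market", "month"]])).values
    hydro_markets = set(exposure_df.loc[exposure_df["fhd"].notna(), "market"])
    panel["market_has_hydro"] = panel["market"].isin(hydro_markets)

    # market-level degree-days from the market mean of plant temperatures
    mt = panel.groupby(["market", "month"])["temp_c"].mean()
    ndays = pd.Series({m: days_in_month(m) for m in months})
    hdd, cdd = degree_days(mt.values, ndays.reindex(mt.index.get_level_values(1)).values)
    dd = pd.DataFrame({"hdd": hdd, "cdd": cdd}, index=mt.index)
    panel = panel.merge(dd.reset_index(), on=["market", "month"], how="left")

    controls_obs = panel[["fhd", "local_drought"]].notna().all(axis=1)
    panel["in_analysis"] = (panel["operational"].astype(bool) & panel["fire_free"]
                            & panel["market_has_hydro"] & controls_obs)
    return panel


def no_combustion_within(plants_nc: pd.DataFrame, plants_comb: pd.DataFrame,
                         radius_km: float = DEFAULT_RADIUS_KM) -> pd.Series:
    """True for non-combustion plants with no combustion plant within
    ``radius_km`` (the placebo sample restriction)."""
    out = {}
    for _, p in plants_nc.iterrows():
        d = haversine_km(plants_comb["lat"].values, plants_comb["lon"].values,
                         p["lat"], p["lon"])
        out[p["plant_id"]] = bool((d > radius_km).all()) if len(d) else True
    return pd.Series(out, name="no_combustion_within_radius")
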