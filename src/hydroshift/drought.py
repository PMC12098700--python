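"""Hydrological-drought exposure of hydropower fleets.

This module turns gridded monthly runoff into market-level drought
measures. The chain is:

1. delineate each hydropower plant's watershed on a basin graph by
   tracing every upstream sub-basin that drains toward the plant;
2. average runoff over the watershed's grid cells, month by month;
3. form runoff anomalies against a calendar-month climatology computed
   over a reference period (default 2000-2019);
4. smooth anomalies with a trailing moving window (default 3 months) and
   flag drought months (negative rolled anomaly; or anomalies more than
   one standard deviation below normal for the "severe" variant);
5. aggregate plant-level drought flags to each electricity market, by
   default weighting by installed capacity. The resulting share is the
   fraction of hydropower capacity affected by drought (FHD), the
   exposure regressor used downstream.

Conventions fixed here (the underlying definitions leave them open):
the k-month window is trailing and includes the current month
(t-k+1..t); a rolled anomaly of exactly zero is *not* drought;
watershed means are unweighted across member cells; capacity weights
are the registry's static installed capacity.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ValidationError
from .grids import MonthlyGrid, grid_months
from .months import month_cal, month_year

STANDARD_WINDOWS = (1, 3, 6, 9, 12)


# ---------------------------------------------------------------------------
# Basin graph and watershed delineation
# ---------------------------------------------------------------------------

@dataclass
class BasinGraph:
    """A forest of sub-basins with downstream pointers.

    ``downstream[b]`` is the basin immediately downstream of ``b`` (or
    ``None`` for terminal basins); ``cells[b]`` holds flat indices into
    the runoff grid's (lat, lon) plane for the cells belonging to ``b``.
    """

    downstream: dict = field(default_factory=dict)
    cells: dict = field(default_factory=dict)

    def __post_init__(self):
        self.validate()

    def validate(self) -> None:
        for b, d in self.downstream.items():
            if d is not None and d not in self.downstream:
                raise ValidationError(f"basin {b} points downstream to unknown basin {d}")
        for b in self.downstream:
            if len(np.atleast_1d(self.cells.get(b, []))) < 1:
                raise ValidationError(f"basin {b} has no grid cells")
        # cycle check by pointer chasing with a visited set
        for start in self.downstream:
            seen = set()
            b = start
            while b is not None:
                if b in seen:
                    raise ValidationError(f"cycle in downstream pointers at basin {b}")
                seen.add(b)
                b = self.downstream[b]

    @property
    def basins(self) -> list:
        return list(self.downstream)

    def upstream_index(self) -> dict:
        up: dict = {b: [] for b in self.downstream}
        for b, d in self.downstream.items():
            if d is not None:
                up[d].append(b)
        return up


def delineate_watershed(graph: BasinGraph, outlet) -> set:
    """All basins from which water flows to ``outlet``, including itself."""
    if outlet not in graph.downstream:
        raise KeyError(f"unknown outlet basin {outlet!r}")
    up = graph.upstream_index()
    result = set()
    stack = [outlet]
    while stack:
        b = stack.pop()
        if b in result:
            continue
        result.add(b)
        stack.extend(up[b])
    return result


def watershed_runoff(grid: MonthlyGrid, graph: BasinGraph, basins) -> pd.Series:
    """Per-month unweighted mean runoff over the union of member cells."""
    basins = list(basins)
    if not basins:
        raise ValidationError("empty basin set")
    flat = np.unique(np.concatenate([np.atleast_1d(graph.cells[b]) for b in basins]))
    if flat.size == 0:
        raise ValidationError("watershed has no grid cells")
    n_lat, n_lon = grid.sizes["lat"], grid.sizes["lon"]
    vals = grid.values.reshape(grid.sizes["month"], n_lat * n_lon)[:, flat]
    return pd.Series(vals.mean(axis=1), index=grid_months(grid))


# ---------------------------------------------------------------------------
# Anomalies
# ---------------------------------------------------------------------------

@dataclass
class WatershedSeries:
    """Monthly runoff, anomalies, and anomaly dispersion for one watershed."""

    runoff: pd.Series
    anomaly: pd.Series
    anomaly_sd: float
    climatology: pd.Series  # indexed by calendar month 1..12
    reference: tuple


def compute_anomalies(series: pd.Series, reference: tuple = (2000, 2019),
                      climatology: pd.Series | None = None) -> WatershedSeries:
    """Runoff minus its calendar-month mean over the reference years.

    The climatology is calendar-month specific, so a seasonal cycle that
    repeats identically every year yields zero anomalies. Passing an
    explicit ``climatology`` (e.g. the historical one when processing
    projected runoff) overrides the internal computation. The stored
    anomaly standard deviation (ddof=1, over reference months) supports
    the severe-drought indicator.

    Numerical guard: anomalies smaller in magnitude than 1e-12 times the
    runoff scale are snapped to exactly zero. Without it, floating-point
    cancellation in the climatology mean can leave +-1 ulp residues that
    the strict ``< 0`` drought rule would misread as drought.
    """
    months = pd.Index(series.index.astype(str))
    years = np.array([month_year(m) for m in months])
    cals = np.array([month_cal(m) for m in months])
    y0, y1 = reference
    if climatology is None:
        in_ref = (years >= y0) & (years <= y1)
        if not in_ref.any():
            raise ValidationError(f"no months of reference period {reference} in series")
        clim = {}
        for cm in range(1, 13):
            mask = in_ref & (cals == cm)
            if cals[in_ref].size and not mask.any() and (cals == cm).any():
                raise ValidationError(f"calendar month {cm} absent from reference period")
            if mask.any():
                clim[cm] = float(series.values[mask].mean())
        climatology = pd.Series(clim)
    missing = sorted(set(cals) - set(climatology.index))
    if missing:
        raise ValidationError(f"calendar months {missing} absent from climatology")
    anomaly_vals = series.values - climatology.reindex(cals).values
    tol = 1e-12 * max(np.abs(series.values).max(), 1e-300)
    anomaly_vals[np.abs(anomaly_vals) < tol] = 0.0
    anomaly = pd.Series(anomaly_vals, index=months)
    ref_mask = (years >= y0) & (years <= y1)
    sd = float(anomaly.values[ref_mask].std(ddof=1)) if ref_mask.sum() > 1 else float("nan")
    return WatershedSeries(runoff=pd.Series(series.values, index=months),
                           anomaly=anomaly, anomaly_sd=sd,
                           climatology=climatology, reference=(y0, y1))


def rolling_anomaly(anomaly: pd.Series, window: int) -> pd.Series:
    """Trailing mean over months t-window+1..t; leading months are NaN."""
    if window < 1:
        raise ValidationError(f"window must be >= 1, got {window}")
    if window not in STANDARD_WINDOWS:
        warnings.warn(f"non-standard drought window {window}; standard choices are "
                      f"{STANDARD_WINDOWS}", stacklevel=2)
    return anomaly.rolling(window, min_periods=window).mean()


def drought_indicator(rolled: pd.Series, mode: str = "negative",
                      sd: float | None = None) -> pd.Series:
    """Binary drought flag per month; NaN inputs propagate.

    ``negative``: 1 when the rolled anomaly is strictly below zero.
    ``severe``: 1 when it is below minus one standard deviation.
    """
    if mode == "negative":
        threshold = 0.0
    elif mode == "severe":
        if sd is None or not np.isfinite(sd) or sd <= 0:
            raise ValidationError(f"severe mode requires a positive anomaly sd, got {sd}")
        threshold = -float(sd)
    else:
        raise ValidationError(f"unknown drought mode {mode!r}")
    out = (rolled < threshold).astype(float)
    out[rolled.isna()] = np.nan
    return out


# ---------------------------------------------------------------------------
# Market aggregation
# ---------------------------------------------------------------------------

def _weights(plants: pd.DataFrame, weighting: str) -> pd.Series:
    if (plants["capacity_mw"] <= 0).any():
        bad = plants.loc[plants["capacity_mw"] <= 0, "plant_id"].tolist()
        raise ValidationError(f"non-positive capacity for plants {bad}")
    if weighting == "capacity":
        return plants.set_index("plant_id")["capacity_mw"].astype(float)
    if weighting == "arithmetic":
        return pd.Series(1.0, index=plants["plant_id"])
    raise ValidationError(f"unknown weighting {weighting!r}")


def _apply_market_map(markets: pd.Series, market_map: dict | None) -> pd.Series:
    if market_map is None:
        return markets
    return markets.map(lambda m: market_map.get(m, m))


def aggregate_market(indicators: pd.DataFrame, plants: pd.DataFrame,
                     weighting: str = "capacity",
                     market_map: dict | None = None,
                     markets: list | None = None) -> pd.DataFrame:
    """Weighted mean of per-plant drought flags by (market, month).

    ``indicators`` is plant x month (rows indexed by plant_id). Months
    where a plant's flag is missing are excluded from that market-month's
    weighted mean; markets with no hydropower appear as NaN rows when
    listed in ``markets``. The merged-market robustness exercise is
    expressed through ``market_map`` (original market -> merged market).
    """
    w = _weights(plants, weighting)
    mkts = _apply_market_map(plants.set_index("plant_id")["market"], market_map)
    frames = {}
    for market, ids in mkts.groupby(mkts).groups.items():
        sub = indicators.loc[list(ids)]
        ww = w.loc[list(ids)].values[:, None] * sub.notna().values
        with np.errstate(invalid="ignore"):
            frames[market] = pd.Series(
                np.nansum(sub.values * w.loc[list(ids)].values[:, None], axis=0)
                / ww.sum(axis=0),
                index=sub.columns)
    out = pd.DataFrame(frames).T
    out.index.name = "market"
    if markets is not None:
        out = out.reindex(pd.Index(markets, name="market"))
    vals = out.to_numpy(float)
    with np.errstate(invalid="ignore"):
        if np.any((vals < -1e-12) | (vals > 1 + 1e-12)):
            raise ValidationError("aggregated drought share outside [0, 1]")
    return out


def market_mean_anomaly(anomalies: pd.DataFrame, plants: pd.DataFrame,
                        weighting: str = "capacity",
                        market_map: dict | None = None,
                        markets: list | None = None) -> pd.DataFrame:
    """Weighted mean runoff anomaly per market-month (sign-preserving).

    Unlike FHD this intensity measure lets negative anomalies at some
    plants be offset by positive anomalies at others.
    """
    w = _weights(plants, weighting)
    mkts = _apply_market_map(plants.set_index("plant_id")["market"], market_map)
    frames = {}
    for market, ids in mkts.groupby(mkts).groups.items():
        sub = anomalies.loc[list(ids)]
        wv = w.loc[list(ids)].values[:, None]
        denom = (wv * sub.notna().values).sum(axis=0)
        with np.errstate(invalid="ignore"):
            frames[market] = pd.Series(np.nansum(sub.values * wv, axis=0) / denom,
                                       index=sub.columns)
    out = pd.DataFrame(frames).T
    out.index.name = "market"
    if markets is not None:
        out = out.reindex(pd.Index(markets, name="market"))
    return out


# ---------------------------------------------------------------------------
# End-to-end market exposure table
# ---------------------------------------------------------------------------

def watershed_series_by_plant(runoff: MonthlyGrid, graph: BasinGraph,
                              hydro_plants: pd.DataFrame,
                              reference: tuple = (2000, 2019),
                              climatologies: dict | None = None) -> dict:
    """Per-plant :class:`WatershedSeries` keyed by plant_id.

    ``climatologies`` (plant_id -> calendar-month Series) overrides the
    internally computed climatology; used for projections where anomalies
    must be taken against the historical baseline.
    """
    out = {}
    for _, p in hydro_plants.iterrows():
        basins = delineate_watershed(graph, p["outlet_basin"])
        series = watershed_runoff(runoff, graph, basins)
        clim = None if climatologies is None else climatologies.get(p["plant_id"])
        out[p["plant_id"]] = compute_anomalies(series, reference, climatology=clim)
    return out


def market_exposure(runoff: MonthlyGrid, graph: BasinGraph,
                    hydro_plants: pd.DataFrame, window: int = 3,
                    reference: tuple = (2000, 2019),
                    markets: list | None = None,
                    market_map: dict | None = None,
                    climatologies: dict | None = None,
                    anomaly_sds: dict | None = None) -> pd.DataFrame:
    """Long table (market, month) with FHD and its variants.

    Columns: ``fhd`` (capacity-weighted), ``fhd_arith`` (plant-count
    weighted), ``fhd_severe`` (capacity-weighted, one-sd threshold), and
    ``mean_anomaly`` (capacity-weighted anomaly intensity in mm/h).
    ``anomaly_sds`` overrides the per-plant anomaly dispersion used by
    the severe indicator (needed when processing projected runoff with
    historical climatologies).
    """
    ws = watershed_series_by_plant(runoff, graph, hydro_plants, reference,
                                   climatologies=climatologies)
    neg, sev, anom = {}, {}, {}
    for pid, s in ws.items():
        rolled = rolling_anomaly(s.anomaly, window)
        neg[pid] = drought_indicator(rolled, "negative")
        sd = s.anomaly_sd if anomaly_sds is None else anomaly_sds[pid]
        if sd > 0:
            sev[pid] = drought_indicator(rolled, "severe", sd=sd)
        else:
            # degenerate watershed with constant anomalies: never severe
            sev[pid] = rolled * 0.0
        anom[pid] = s.anomaly
    neg = pd.DataFrame(neg).T
    sev = pd.DataFrame(sev).T
    anom = pd.DataFrame(anom).T
    frames = {
        "fhd": aggregate_market(neg, hydro_plants, "capacity", market_map, markets),
        "fhd_arith": aggregate_market(neg, hydro_plants, "arithmetic",
                                      market_map, markets),
        "fhd_severe": aggregate_market(sev, hydro_plants, "capacity",
                                       market_map, markets),
        "mean_anomaly": market_mean_anomaly(anom, hydro_plants, "capacity",
                                            market_map, markets),
    }
    mkts = frames["fhd"].index.to_numpy()
    mcols = frames["fhd"].columns.to_numpy()
    long = pd.DataFrame({"market": np.repeat(mkts, mcols.size),
                         "month": np.tile(mcols, mkts.size),
                         "window": window})
    for name, f in frames.items():
        long[name] = f.reindex(index=mkts, columns=mcols).to_numpy().ravel()
    return long
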