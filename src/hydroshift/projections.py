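"""Forward projection of drought exposure, deaths, and losses to 2059.

Each projected path combines one climate-model runoff projection, one
SSP-RCP scenario, and one energy-policy retirement schedule. Anomalies
for projected runoff are taken against the *historical* calendar-month
climatology (the same baseline as the retrospective analysis), so the
FHD machinery is reused unchanged. Deaths use the constant CRF and the
constant estimated coefficient (no adaptation, no technological change);
exposed population and VSL scale with scenario demographic and economic
multipliers; retired plants contribute nothing from their retirement
year onward, and no new combustion plants are ever added.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import drought
from .errors import ValidationError
from .health import CrfSpec

SSP_RCPS = ("SSP1-2.6", "SSP2-4.5", "SSP3-7.0")
ENERGY_POLICIES = ("APS", "STEPS", "RES")
# default pairing by expected end-of-century forcing; overridable because
# the full cross of policies and SSP-RCPs is also a supported exercise
DEFAULT_POLICY_PAIRING = {"SSP1-2.6": "APS", "SSP2-4.5": "STEPS", "SSP3-7.0": "RES"}
PROJECTION_YEARS = (2020, 2059)
BASE_YEARS = (2000, 2019)


@dataclass
class ScenarioSpec:
    """Scaling inputs for one SSP-RCP scenario.

    Multiplier tables are indexed (country, year) and applied to the
    base-year exposed population, 65+ fraction, and GNI-ratio VSL; the
    retirement schedule maps plant_id -> retirement year (empty = RES).
    """

    ssp_rcp: str
    energy_policy: str
    pop_multiplier: pd.DataFrame = field(default_factory=pd.DataFrame)
    frac65_multiplier: pd.DataFrame = field(default_factory=pd.DataFrame)
    gni_multiplier: pd.DataFrame = field(default_factory=pd.DataFrame)
    retirement: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.ssp_rcp not in SSP_RCPS:
            raise ValidationError(f"unknown SSP-RCP {self.ssp_rcp!r}")
        if self.energy_policy not in ENERGY_POLICIES:
            raise ValidationError(f"unknown energy policy {self.energy_policy!r}")
        if self.energy_policy == "RES" and self.retirement:
            raise ValidationError("RES assumes no retirements")
        for pid, y in self.retirement.items():
            if not PROJECTION_YEARS[0] <= y <= PROJECTION_YEARS[1]:
                raise ValidationError(f"retirement year {y} for {pid} outside "
                                      f"horizon {PROJECTION_YEARS}")
        for name in ("pop_multiplier", "frac65_multiplier", "gni_multiplier"):
            t = getattr(self, name)
            if len(t) and (t["multiplier"] <= 0).any():
                raise ValidationError(f"{name} must be positive")

    def _mult(self, name: str, country: str, year: int) -> float:
        t = getattr(self, name)
        if not len(t):
            return 1.0
        s = t.set_index(["country", "year"])["multiplier"]
        try:
            return float(s.loc[(country, int(year))])
        except KeyError as err:
            raise ValidationError(f"missing {name} for {err.args[0]}") from err


def projected_fhd(runoff_proj, graph, hydro_plants: pd.DataFrame,
                  historical: dict, window: int = 3,
                  markets: list | None = None) -> pd.DataFrame:
    """FHD series for projected runoff, using historical climatologies.

    ``historical`` maps plant_id -> :class:`~hydroshift.drought.WatershedSeries`
    from the retrospective run; its calendar-month climatology and
    anomaly sd anchor the projected anomalies and the severe threshold.
    """
    clims = {pid: ws.climatology for pid, ws in historical.items()}
    sds = {pid: ws.anomaly_sd for pid, ws in historical.items()}
    missing = set(hydro_plants["plant_id"]) - set(clims)
    if missing:
        raise ValidationError(f"no historical climatology for plants {sorted(missing)}")
    return drought.market_exposure(runoff_proj, graph, hydro_plants, window=window,
                                   reference=BASE_YEARS, markets=markets,
                                   climatologies=clims, anomaly_sds=sds)


def fhd_pct_change(fhd: pd.Series, base_period=BASE_YEARS,
                   future_period=PROJECTION_YEARS) -> float:
    """100 x (mean FHD over the future period - base mean) / base mean.

    ``fhd`` is indexed by "YYYY-MM" month keys (historical and projected
    months concatenated). A zero base mean leaves the change undefined.
    """
    years = fhd.index.str[:4].astype(int)
    base = fhd[(years >= base_period[0]) & (years <= base_period[1])].dropna()
    future = fhd[(years >= future_period[0]) & (years <= future_period[1])].dropna()
    if base.empty or future.empty:
        raise ValidationError("base or future period has no FHD observations")
    mb = base.mean()
    if mb == 0:
        raise ValidationError("zero base-period mean FHD; percent change undefined")
    return float(100.0 * (future.mean() - mb) / mb)


def build_retirement_schedule(exposed_pop: pd.Series, policy: str,
                              quantity_path: dict | None = None) -> dict:
    """Plant retirement years under an energy-policy scenario.

    ``exposed_pop`` maps plant_id -> exposed population; plants with the
    largest exposed population retire first (ties by plant id).
    ``quantity_path`` maps year -> number of plants retiring that year
    (the underlying capacity schedules are external inputs, so the path
    is a config quantity). RES retires nothing.
    """
    if policy not in ENERGY_POLICIES:
        raise ValidationError(f"unknown energy policy {policy!r}")
    if policy == "RES":
        return {}
    if not quantity_path:
        raise ValidationError(f"{policy} requires a retirement quantity path")
    idx = np.lexsort((exposed_pop.index.astype(str), -exposed_pop.values))
    ids = list(exposed_pop.index[idx])
    schedule: dict = {}
    pos = 0
    for year in sorted(quantity_path):
        n = int(quantity_path[year])
        if pos + n > len(ids):
            warnings.warn("retirement path exceeds fleet size; truncating",
                          stacklevel=2)
            n = len(ids) - pos
        for pid in ids[pos:pos + n]:
            schedule[pid] = int(year)
        pos += n
    return schedule


def project_paths(fhd_ensemble: dict, scenarios: dict, plants: pd.DataFrame,
                  pop65_base: pd.Series, vsl_base: pd.DataFrame,
                  crf: CrfSpec, beta: float) -> pd.DataFrame:
    """One projected annual path per (climate model, scenario).

    ``fhd_ensemble`` maps (model_id, ssp_rcp) -> long FHD table with
    columns (market, month, fhd); ``scenarios`` maps ssp_rcp ->
    :class:`ScenarioSpec`; ``pop65_base`` is the per-plant 65+ exposure
    in the base year; ``vsl_base`` has columns (country, vsl_usd2019)
    for the base year. Returns a long table (model, ssp_rcp, policy,
    year, market, fhd_mean, deaths, losses_usd2019).
    """
    combos = sorted({(m, s) for m, s in fhd_ensemble})
    missing = {s for _, s in combos} - set(scenarios)
    if missing:
        raise ValidationError(f"no ScenarioSpec for {sorted(missing)}")
    p = plants.set_index("plant_id")
    vsl0 = vsl_base.set_index("country")["vsl_usd2019"]
    rows = []
    for model, ssp in combos:
        spec = scenarios[ssp]
        fhd = fhd_ensemble[(model, ssp)].copy()
        fhd = fhd.loc[fhd["fhd"].notna()]
        fhd["year"] = fhd["month"].str[:4].astype(int)
        fhd = fhd[(fhd["year"] >= PROJECTION_YEARS[0])
                  & (fhd["year"] <= PROJECTION_YEARS[1])]
        fhd_year = fhd.groupby(["market", "year"])["fhd"].agg(["mean", "sum"])
        for (market, year), (fmean, fsum) in fhd_year.iterrows():
            mkt_plants = p[(p["market"] == market)]
            deaths_y = 0.0
            for pid, pl in mkt_plants.iterrows():
                if pid not in pop65_base.index:
                    continue
                retired = spec.retirement.get(pid)
                if retired is not None and year >= retired:
                    continue
                pop = (pop65_base.loc[pid]
                       * spec._mult("pop_multiplier", market, year)
                       * spec._mult("frac65_multiplier", market, year))
                deaths_y += crf.rate * crf.days_per_month * beta * fsum * pop / 1e6
            vsl_cy = float(vsl0.get(market, np.nan)) \
                * spec._mult("gni_multiplier", market, year)
            rows.append({"model": model, "ssp_rcp": ssp,
                         "policy": spec.energy_policy, "year": int(year),
                         "market": market, "fhd_mean": float(fmean),
                         "deaths": deaths_y,
                         "losses_usd2019": deaths_y * vsl_cy})
    out = pd.DataFrame(rows)
    n_paths = out[["model", "ssp_rcp"]].drop_duplicates().shape[0] if len(out) else 0
    expected = len(combos)
    if n_paths != expected:
        raise ValidationError(f"produced {n_paths} paths, expected {expected}")
    return out
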