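"""Monetization of premature deaths via value-of-statistical-life transfer.

A US base VSL is extrapolated to each country-year with a unit income
elasticity benefit transfer:

    VSL_cy = base_VSL x (GNI_cy / GNI_US,y) ^ elasticity

All monetary quantities are constant 2019 USD; inputs must be
pre-deflated (no within-pipeline deflation). The base VSL is a config
input: the default of $7.0M is a placeholder in the range of recent US
meta-analyses, not an authoritative value, and should be set explicitly
for any substantive use.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ValidationError

PLACEHOLDER_BASE_VSL_USD2019 = 7.0e6


@dataclass
class VslSpec:
    base_vsl_usd2019: float = PLACEHOLDER_BASE_VSL_USD2019
    income_elasticity: float = 1.0
    gni_per_capita: pd.DataFrame = field(default_factory=pd.DataFrame)
    us_country_code: str = "USA"

    def __post_init__(self):
        if self.base_vsl_usd2019 <= 0:
            raise ValidationError("base VSL must be positive")
        if self.income_elasticity < 0:
            raise ValidationError("income elasticity must be >= 0")
        if len(self.gni_per_capita):
            if (self.gni_per_capita["gni_usd"] <= 0).any():
                raise ValidationError("GNI per capita values must be positive")
            self._gni = self.gni_per_capita.set_index(["country", "year"])["gni_usd"]
        else:
            self._gni = pd.Series(dtype=float)


def country_vsl(spec: VslSpec, country: str, year: int) -> float:
    """Income-adjusted VSL for one country-year, in 2019 USD."""
    year = int(year)
    try:
        gni_c = spec._gni.loc[(country, year)]
        gni_us = spec._gni.loc[(spec.us_country_code, year)]
    except KeyError as err:
        raise ValidationError(f"missing GNI per capita for {err.args[0]}") from err
    return float(spec.base_vsl_usd2019 * (gni_c / gni_us) ** spec.income_elasticity)


def vsl_table(spec: VslSpec, countries, years) -> pd.DataFrame:
    rows = [{"country": c, "year": int(y), "vsl_usd2019": country_vsl(spec, c, y)}
            for c in countries for y in years]
    return pd.DataFrame(rows)


def monetize(draw_table: pd.DataFrame, vsl: pd.DataFrame) -> pd.DataFrame:
    """Losses per record: deaths x country-year VSL, appended as
    ``losses_usd2019``. The join key is (country, year)."""
    need = {"country", "year", "deaths"}
    if not need <= set(draw_table.columns):
        raise ValidationError(f"draw table needs columns {sorted(need)} to monetize; "
                              "aggregate no coarser than country-year")
    v = vsl.set_index(["country", "year"])["vsl_usd2019"]
    out = draw_table.copy()
    joined = out.join(v, on=["country", "year"])
    if joined["vsl_usd2019"].isna().any():
        bad = joined.loc[joined["vsl_usd2019"].isna(),
                         ["country", "year"]].drop_duplicates()
        raise ValidationError(f"unresolved VSL join for {bad.values.tolist()[:5]}")
    out["losses_usd2019"] = joined["deaths"] * joined["vsl_usd2019"]
    return out
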