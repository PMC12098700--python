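"""Premature-mortality burden of drought-induced excess PM2.5.

The counterfactual chain is deliberately simple and linear:

    excess PM2.5 = beta x FHD                       (ug m-3)
    deaths/month = CRF x days x excess x pop65 / 1e6

where the concentration-response function (CRF) is a constant daily
mortality rate per ug m-3 per million adults 65+ (default 0.69, scaled
to monthly frequency with 30 days), and estimation uncertainty in beta
is propagated by Monte Carlo: beta is drawn from its normal sampling
distribution (default mean 1.55, sd 0.31) and the whole chain is
re-evaluated per draw (default 1000 draws).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ValidationError


@dataclass
class CrfSpec:
    """Constant concentration-response function.

    ``rate`` is daily excess deaths per million adults 65+ per ug m-3;
    the monthly rate is ``rate * days_per_month`` (30 by convention).
    """

    rate: float = 0.69
    days_per_month: float = 30.0
    label: str = "deryugina-2019"

    def __post_init__(self):
        if self.rate < 0:
            raise ValidationError(f"CRF rate must be >= 0, got {self.rate}")
        if not 28 <= self.days_per_month <= 31:
            raise ValidationError(f"days_per_month must lie in [28, 31], "
                                  f"got {self.days_per_month}")


@dataclass
class BetaDrawSpec:
    """Normal sampling distribution of the drought coefficient."""

    mean: float = 1.55
    sd: float = 0.31
    n_draws: int = 1000
    seed: int = 0

    def __post_init__(self):
        if self.sd < 0:
            raise ValidationError(f"sd must be >= 0, got {self.sd}")
        if self.n_draws < 1:
            raise ValidationError(f"n_draws must be >= 1, got {self.n_draws}")

    def draw(self) -> np.ndarray:
        rng = np.random.default_rng(self.seed)
        return rng.normal(self.mean, self.sd, size=self.n_draws)


def excess_pm(beta: float, fhd) -> float | np.ndarray:
    """Excess concentration attributable to drought at a given FHD."""
    f = np.asarray(fhd, dtype=float)
    if np.any((f < 0) | (f > 1)):
        raise ValidationError("FHD values must lie in [0, 1]")
    out = beta * f
    return float(out) if np.ndim(fhd) == 0 else out


def deaths(excess, pop65, crf: CrfSpec) -> float | np.ndarray:
    """Monthly premature deaths among adults 65+.

    ``crf.rate x crf.days_per_month x excess x pop65 / 1e6``; linear in
    each argument. Negative values can arise only from negative beta
    draws, which are retained: the Monte Carlo represents estimation
    uncertainty, not a truncated physical quantity.
    """
    p = np.asarray(pop65, dtype=float)
    if np.any(p < 0):
        raise ValidationError("population must be >= 0")
    out = crf.rate * crf.days_per_month * np.asarray(excess, float) * p / 1e6
    return float(out) if np.ndim(excess) == 0 and np.ndim(pop65) == 0 else out


def _death_base(panel: pd.DataFrame, pop65: pd.DataFrame, plants: pd.DataFrame,
                crf: CrfSpec) -> pd.DataFrame:
    """Per-plant-month deaths per unit beta (everything except the draw)."""
    need = {"plant_id", "month", "fhd"}
    if not need <= set(panel.columns):
        raise ValidationError(f"fhd panel needs columns {sorted(need)}")
    df = panel.loc[panel["fhd"].notna(), ["plant_id", "month", "fhd"]].copy()
    df["year"] = df["month"].str[:4].astype(int)
    pop_long = pop65.stack()
    pop_long.index.names = ["plant_id", "year"]
    pop_long.name = "pop65"
    df = df.join(pop_long, on=["plant_id", "year"], how="left")
    if df["pop65"].isna().any():
        bad = df.loc[df["pop65"].isna(), ["plant_id", "year"]].drop_duplicates()
        raise ValidationError(f"missing 65+ population for plant-years "
                              f"{bad.values.tolist()[:5]}...")
    country = plants.set_index("plant_id")["market"]
    df["country"] = df["plant_id"].map(country)
    df["base"] = crf.rate * crf.days_per_month * df["fhd"] * df["pop65"] / 1e6
    return df


_LEVEL_KEYS = {"plant_month": ["plant_id", "country", "month", "year"],
               "plant": ["plant_id", "country"],
               "country_year": ["country", "year"],
               "region_year": ["year"]}


def monte_carlo(panel: pd.DataFrame, pop65: pd.DataFrame, plants: pd.DataFrame,
                crf: CrfSpec, draws: BetaDrawSpec,
                level: str = "plant_month") -> pd.DataFrame:
    """Draw table: one row per (draw x key) with excess PM and deaths.

    Because deaths are linear in the drawn coefficient, aggregation over
    plant-months commutes with the draw: for coarser ``level`` the
    per-unit-beta base is summed over keys first and then crossed with
    the draws, which is exactly equivalent to aggregating the full
    plant-month draw table. ``excess_pm`` is reported at plant-month
    level only (it is a concentration and does not sum).
    """
    if level not in _LEVEL_KEYS:
        raise ValidationError(f"unknown aggregation level {level!r}; "
                              f"choose from {sorted(_LEVEL_KEYS)}")
    base = _death_base(panel, pop65, plants, crf)
    b = draws.draw()
    keys = _LEVEL_KEYS[level]
    if level == "plant_month":
        agg = base[keys + ["fhd", "base"]]
    else:
        agg = base.groupby(keys, as_index=False)["base"].sum()
    n = len(agg)
    out = agg.loc[agg.index.repeat(len(b))].reset_index(drop=True)
    out["draw"] = np.tile(np.arange(len(b)), n)
    out["beta_draw"] = np.tile(b, n)
    if level == "plant_month":
        out["excess_pm"] = out["beta_draw"] * out["fhd"]
    out["deaths"] = out["beta_draw"] * out["base"]
    return out.drop(columns=["base"])


def aggregate_draws(draw_table: pd.DataFrame, level: str = "region_year",
                    statistics=("mean", "median")) -> pd.DataFrame:
    """Summaries of deaths (and losses when present) over draws per key."""
    keys = [k for k in _LEVEL_KEYS.get(level, []) if k in draw_table.columns]
    if level not in _LEVEL_KEYS or not keys:
        raise ValidationError(f"unknown or unavailable aggregation level {level!r}")
    value_cols = [c for c in ("deaths", "losses_usd2019") if c in draw_table.columns]
    per_draw = draw_table.groupby(keys + ["draw"], as_index=False)[value_cols].sum()
    out = per_draw.groupby(keys)[value_cols].agg(list(statistics))
    out.columns = ["_".join(c) for c in out.columns]
    return out.reset_index()
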