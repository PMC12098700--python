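"""Serialization of worlds and run artifacts.

Tabular artifacts are CSV; gridded fields are NetCDF (scipy backend);
the generator truth is JSON. Floats are written with ``repr`` precision
so that re-running a stage with the same inputs reproduces identical
bytes, which the run manifests check via SHA-256.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd
import xarray as xr

from . import drought, synthetic
from .errors import ValidationError
from .grids import read_netcdf, write_netcdf

MET_KEYS = ("temp", "precip", "rh", "pressure", "wind10", "wind100")


def sha256_file(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as f:
        for chunk in iter(lambda: f.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def write_csv(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index=False, float_format="%.12g")


def save_world(world: synthetic.World, outdir, write_grids: bool = False) -> list[str]:
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    written = []

    def _w(df, name):
        write_csv(df, out / name)
        written.append(name)

    _w(world.plants, "plants.csv")
    _w(world.country, "country_tables.csv")
    edges = pd.DataFrame([{"basin_id": b, "downstream_id": d or ""}
                          for b, d in world.basins.downstream.items()])
    _w(edges, "basin_edges.csv")
    cells = pd.DataFrame([{"basin_id": b, "cell_flat_index": int(c)}
                          for b, arr in world.basins.cells.items() for c in arr])
    _w(cells, "basin_cells.csv")
    _w(world.truth.episodes, "episodes.csv")
    _w(world.truth.fhd, "truth_fhd.csv")
    from dataclasses import asdict
    cfg_dict = asdict(world.config)
    params = {"true_beta": world.truth.true_beta,
              "true_gamma": world.truth.true_gamma,
              "config": cfg_dict}
    (out / "truth_params.json").write_text(json.dumps(params, indent=2))
    written.append("truth_params.json")
    if write_grids:
        write_netcdf(world.runoff, out / "runoff.nc")
        write_netcdf(world.pm25, out / "pm25.nc")
        write_netcdf(world.fire, out / "fire.nc")
        for k in MET_KEYS:
            write_netcdf(world.met[k], out / f"met_{k}.nc")
        world.population.to_dataset(name="population").to_netcdf(
            out / "population.nc", engine="scipy")
        written += ["runoff.nc", "pm25.nc", "fire.nc",
                    *[f"met_{k}.nc" for k in MET_KEYS], "population.nc"]
    return written


def load_basins(outdir) -> drought.BasinGraph:
    out = Path(outdir)
    edges = pd.read_csv(out / "basin_edges.csv", keep_default_na=False)
    cells_df = pd.read_csv(out / "basin_cells.csv")
    downstream = {r["basin_id"]: (r["downstream_id"] or None)
                  for _, r in edges.iterrows()}
    cells = {b: g["cell_flat_index"].to_numpy()
             for b, g in cells_df.groupby("basin_id")}
    return drought.BasinGraph(downstream=downstream, cells=cells)


def load_world(outdir) -> synthetic.World:
    """Rehydrate a saved world (requires grids to have been written)."""
    out = Path(outdir)
    missing = [n for n in ("plants.csv", "runoff.nc", "pm25.nc", "fire.nc")
               if not (out / n).exists()]
    if missing:
        raise ValidationError(f"missing upstream artifacts in {out}: {missing} "
                              "(run the generate stage with write_grids: true)")
    plants = pd.read_csv(out / "plants.csv")
    country = pd.read_csv(out / "country_tables.csv")
    basins = load_basins(out)
    params = json.loads((out / "truth_params.json").read_text())
    episodes = pd.read_csv(out / "episodes.csv") if (out / "episodes.csv").exists() \
        else pd.DataFrame(columns=["plant_id", "start", "end", "depth"])
    truth_fhd = pd.read_csv(out / "truth_fhd.csv")
    runoff = read_netcdf(out / "runoff.nc")
    pm25 = read_netcdf(out / "pm25.nc")
    fire = read_netcdf(out / "fire.nc")
    met = {k: read_netcdf(out / f"met_{k}.nc") for k in MET_KEYS}
    pop_ds = xr.open_dataset(out / "population.nc", engine="scipy")
    population = pop_ds["population"].load()
    cfg_dict = dict(params["config"])
    for key in ("reference_period", "episode_depth_range"):
        cfg_dict[key] = tuple(cfg_dict[key])
    cfg = synthetic.WorldConfig(**cfg_dict)
    truth = synthetic.WorldTruth(
        true_beta=params["true_beta"], true_gamma=params["true_gamma"],
        beta_by_plant=pd.Series(dtype=float), plant_effects=pd.Series(dtype=float),
        time_effects=pd.Series(dtype=float), seasonal_effects=pd.Series(dtype=float),
        episodes=episodes, fhd=truth_fhd, mu_panel=pd.DataFrame(),
        noise_panel=pd.DataFrame(), runoff_base=np.zeros(1), seasonal_amp=0.0,
        market_phase={})
    return synthetic.World(config=cfg, plants=plants, basins=basins,
                           runoff=runoff, pm25=pm25, fire=fire, met=met,
                           population=population, country=country, truth=truth)
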