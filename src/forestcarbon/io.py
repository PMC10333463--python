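"""File formats: NetCDF cubes and grids, CSV tables, YAML configs,
joblib model bundles with JSON sidecars.

All rasters travel as NetCDF (classic format via the scipy backend, so no
compiled NetCDF library is needed); geometry and units ride along as
attributes so write-then-read is the identity on values, mask, geometry
and metadata.
"""
from __future__ import annotations

import json
from pathlib import Path

import joblib
import numpy as np
import pandas as pd
import xarray as xr
import yaml

from .ensemble import MMRFEConfig, TrainedEnsemble
from .grids import GridCube, GridGeometry, ModelStack

__all__ = [
    "write_cube",
    "read_cube",
    "write_grid",
    "read_grid",
    "read_stack",
    "write_plots",
    "read_plots",
    "save_model",
    "load_model",
    "load_yaml",
]

_ENGINE = "scipy"


def _geom_attrs(geom: GridGeometry) -> dict:
    return {
        "origin_lat": geom.origin_lat,
        "origin_lon": geom.origin_lon,
        "cell_size": geom.cell_size,
    }


def _geom_from_attrs(attrs, nrows: int, ncols: int) -> GridGeometry:
    return GridGeometry(
        float(attrs["origin_lat"]),
        float(attrs["origin_lon"]),
        float(attrs["cell_size"]),
        nrows,
        ncols,
    )


def write_cube(path, cube: GridCube) -> None:
    name = cube.name or "value"
    ds = xr.Dataset(
        {name: (("year", "row", "col"), cube.data)},
        coords={"year": cube.years},
        attrs=_geom_attrs(cube.geometry),
    )
    ds[name].attrs["units"] = cube.units
    ds.to_netcdf(path, engine=_ENGINE)


def read_cube(path) -> GridCube:
    with xr.open_dataset(path, engine=_ENGINE) as ds:
        ds.load()
    names = list(ds.data_vars)
    if len(names) != 1:
        raise ValueError(f"{path}: expected one variable, found {names}")
    var = ds[names[0]]
    if var.dims != ("year", "row", "col"):
        raise ValueError(f"{path}: malformed cube dims {var.dims}")
    geom = _geom_from_attrs(ds.attrs, var.sizes["row"], var.sizes["col"])
    return GridCube(
        years=ds["year"].values,
        data=var.values,
        geometry=geom,
        units=str(var.attrs.get("units", "")),
        name=names[0],
    )


def write_grid(path, grid: np.ndarray, geometry: GridGeometry,
               units: str = "", name: str = "value") -> None:
    ds = xr.Dataset(
        {name: (("row", "col"), np.asarray(grid, dtype=float))},
        attrs=_geom_attrs(geometry),
    )
    ds[name].attrs["units"] = units
    ds.to_netcdf(path, engine=_ENGINE)


def read_grid(path) -> tuple[np.ndarray, GridGeometry]:
    with xr.open_dataset(path, engine=_ENGINE) as ds:
        ds.load()
    names = list(ds.data_vars)
    if len(names) != 1:
        raise ValueError(f"{path}: expected one variable, found {names}")
    var = ds[names[0]]
    geom = _geom_from_attrs(ds.attrs, var.sizes["row"], var.sizes["col"])
    return var.values, geom


def read_stack(paths: dict[str, Path | str], variable: str = "") -> ModelStack:
    """Load one cube per model; all files must agree on geometry."""
    names, cubes = [], []
    for name, p in paths.items():
        cube = read_cube(p)
        names.append(name)
        cubes.append(cube)
    geoms = {c.geometry for c in cubes}
    if len(geoms) > 1:
        raise ValueError(f"geometry mismatch across stack files: {sorted(paths)}")
    return ModelStack(names=names, cubes=cubes, variable=variable)


def write_plots(path, plots: pd.DataFrame) -> None:
    plots.to_csv(path, index=False)


def read_plots(path) -> pd.DataFrame:
    return pd.read_csv(path)


def save_model(path, model: TrainedEnsemble) -> None:
    """Joblib bundle plus a human-readable JSON sidecar of the metadata."""
    path = Path(path)
    joblib.dump(model, path)
    meta = {
        "feature_names": model.feature_names,
        "target_name": model.target_name,
        "best_params": model.best_params,
        "holdout_r": model.holdout_r,
        "holdout_rmse": model.holdout_rmse,
        "train_r2": model.train_r2,
        "n_train": model.n_train,
        "n_holdout": model.n_holdout,
        "seed": model.config.seed,
    }
    path.with_suffix(path.suffix + ".json").write_text(json.dumps(meta, indent=2))


def load_model(path) -> TrainedEnsemble:
    model = joblib.load(path)
    if not isinstance(model, TrainedEnsemble):
        raise ValueError(f"{path} is not a trained ensemble bundle")
    return model


def load_yaml(path) -> dict:
    with open(path) as fh:
        out = yaml.safe_load(fh)
    if not isinstance(out, dict):
        raise ValueError(f"{path}: expected a mapping at top level")
    return out
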