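"""End-to-end pipeline: simulate -> fuse NDVI -> train -> predict ->
validate -> account -> zone.

The run mirrors a national forest-carbon assessment: a historical era where
fused NDVI joins the process-model features, and two future scenarios
(moderate and high forcing) whose ensembles share the historical spatial
structure but diverge in trend.  Every stage is seeded from one root seed;
rerunning with the same config reproduces every numeric output exactly,
which the manifest digest makes checkable.
"""
from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as fio
from .accounting import (
    CO2_PER_PGC,
    cell_areas,
    span_table,
    stock_series,
    trend_slope_map,
)
from .ensemble import (
    MMRFEConfig,
    extract_training_table,
    mmem_mean,
    predict_grid,
    total_carbon,
    train_mmrfe,
)
from .fusion import annual_series_from_biweekly, fuse_series
from .grids import GridCube, ModelStack
from .synthetic import (
    EnsembleConfig,
    TruthConfig,
    gen_model_ensemble,
    gen_ndvi,
    gen_plots,
    gen_truth,
)
from .validation import taylor_table
from .zoning import csindex, kmeans_zones, zone_masks

logger = logging.getLogger(__name__)

SCENARIOS = ("rcp45", "rcp85")


@dataclass(frozen=True)
class PipelineConfig:
    """Everything a full run needs.

    The future era never sees NDVI features (no future NDVI exists); the
    runner enforces this.  ``ref_year`` defaults to the midpoint of the
    historical range — the year the plot campaign is anchored to.
    """

    seed: int = 0
    nrows: int = 32
    ncols: int = 32
    hist_start: int = 1982
    hist_end: int = 2021
    future_start: int = 2022
    future_end: int = 2081
    ref_year: int | None = None
    n_models: int = 7
    n_plots: int = 300
    obs_noise_sd: float = 5.0
    ndvi_coarsen: int = 4
    ndvi_noise_sd: float = 0.02
    trend_hist: float = 0.07
    trend_rcp45: float = 0.07
    trend_rcp85: float = 0.10
    co2_factor: float = CO2_PER_PGC
    span: int = 5
    k_zones: int = 3
    use_ndvi_hist: bool = True
    rf: MMRFEConfig = field(default_factory=MMRFEConfig)

    def __post_init__(self) -> None:
        if not (self.hist_start < self.hist_end < self.future_start < self.future_end):
            raise ValueError("year ranges must be well-ordered: hist before future")
        ref = self.reference_year
        if not self.hist_start <= ref <= self.hist_end:
            raise ValueError(f"reference year {ref} outside historical range")

    @property
    def reference_year(self) -> int:
        if self.ref_year is not None:
            return self.ref_year
        return (self.hist_start + self.hist_end) // 2

    def scenario_trend(self, scenario: str) -> float:
        return {"rcp45": self.trend_rcp45, "rcp85": self.trend_rcp85}[scenario]


@dataclass
class PipelineResult:
    """In-memory handles to every product of one run."""

    config: PipelineConfig
    truth_cveg: GridCube
    truth_csoil: GridCube
    ndvi_fused: GridCube
    hist_stacks: dict[str, ModelStack]
    models: dict[str, object]  # (target, era[, scenario]) key -> TrainedEnsemble
    ecd_hist: GridCube
    ecd_future: dict[str, GridCube]
    validation: pd.DataFrame
    hist_table: pd.DataFrame
    future_tables: dict[str, pd.DataFrame]
    zonal_tables: dict[str, dict[str, pd.DataFrame]]
    csindex_map: object
    zones: object
    zone_fractions: dict[str, float]
    trend_map: np.ndarray
    manifest: dict


def _subseed(root: int, k: int) -> int:
    return int(np.random.SeedSequence([root, k]).generate_state(1)[0] % (2**31))


def _predict_cube(model, stack: ModelStack, years, ndvi_cube=None) -> GridCube:
    geom = stack.geometry
    out = np.empty((len(years), *geom.shape))
    for i, y in enumerate(years):
        nd = ndvi_cube.at_year(y) if ndvi_cube is not None else None
        out[i] = predict_grid(model, stack, y, ndvi=nd)
    return GridCube(np.asarray(years), out, geom, units="Mg C/ha")


def run_pipeline(cfg: PipelineConfig, out_dir: str | Path | None = None) -> PipelineResult:
    t0 = time.time()
    ref = cfg.reference_year
    hist_years = np.arange(cfg.hist_start, cfg.hist_end + 1)
    future_years = np.arange(cfg.future_start, cfg.future_end + 1)

    # --- simulate -------------------------------------------------------
    truth_cfg = TruthConfig(
        seed=_subseed(cfg.seed, 0),
        nrows=cfg.nrows,
        ncols=cfg.ncols,
        year_start=cfg.hist_start,
        year_end=cfg.hist_end,
        trend=cfg.trend_hist,
    )
    truth_cveg, truth_csoil = gen_truth(truth_cfg)

    ens_cfg = EnsembleConfig(seed=_subseed(cfg.seed, 1), n_models=cfg.n_models)
    hist_stacks = {
        "cveg": gen_model_ensemble(truth_cveg, ens_cfg),
        "csoil": gen_model_ensemble(truth_csoil, replace(ens_cfg, seed=_subseed(cfg.seed, 2))),
    }

    coarse, fine = gen_ndvi(
        truth_cveg, cfg.ndvi_coarsen, cfg.ndvi_noise_sd, seed=_subseed(cfg.seed, 3)
    )
    plots = gen_plots(
        truth_cveg, truth_csoil, ref, cfg.n_plots, cfg.obs_noise_sd,
        seed=_subseed(cfg.seed, 4),
    )

    # --- NDVI fusion ----------------------------------------------------
    coarse_annual = annual_series_from_biweekly(coarse)
    fine_annual = annual_series_from_biweekly(fine)
    overlap = (max(cfg.hist_start, cfg.hist_end - 15), cfg.hist_end)
    ndvi_fused = fuse_series(coarse_annual, fine_annual, overlap)

    # --- train + predict, historical era --------------------------------
    rf_cfg = replace(cfg.rf, seed=_subseed(cfg.seed, 5))
    models: dict[str, object] = {}
    preds_hist: dict[str, GridCube] = {}
    nd_ref = ndvi_fused.at_year(ref) if cfg.use_ndvi_hist else None
    for target in ("cveg", "csoil"):
        table = extract_training_table(
            plots, hist_stacks[target], ref, f"obs_{target}", ndvi=nd_ref
        )
        model = train_mmrfe(table, rf_cfg)
        models[f"{target}_hist"] = model
        preds_hist[target] = _predict_cube(
            model, hist_stacks[target], hist_years,
            ndvi_cube=ndvi_fused if cfg.use_ndvi_hist else None,
        )
    ecd_hist = GridCube(
        hist_years,
        total_carbon(preds_hist["cveg"].data, preds_hist["csoil"].data),
        truth_cveg.geometry,
        units="Mg C/ha",
        name="ecd_hist",
    )

    # --- validation at the reference year -------------------------------
    ref_rows, ref_cols = truth_cveg.geometry.pixel_of(
        plots["lon"].to_numpy(), plots["lat"].to_numpy()
    )
    val_frames = []
    for target in ("cveg", "csoil"):
        stack = hist_stacks[target]
        series = {
            name: cube.at_year(ref)[ref_rows, ref_cols] for name, cube in stack
        }
        series["MMEM"] = mmem_mean(stack).at_year(ref)[ref_rows, ref_cols]
        series["MMRFE"] = preds_hist[target].at_year(ref)[ref_rows, ref_cols]
        tbl = taylor_table(series, plots[f"obs_{target}"].to_numpy())
        tbl.insert(0, "variable", target)
        val_frames.append(tbl)
    validation = pd.concat(val_frames, ignore_index=True)

    # --- future scenarios -----------------------------------------------
    ecd_future: dict[str, GridCube] = {}
    for si, scen in enumerate(SCENARIOS):
        scen_truth_cfg = replace(
            truth_cfg,
            year_end=cfg.future_end,
            trend=cfg.scenario_trend(scen),
            trend_csoil=cfg.scenario_trend(scen),
        )
        t_cveg, t_csoil = gen_truth(scen_truth_cfg)
        scen_ens = replace(
            ens_cfg, seed=_subseed(cfg.seed, 10 + si), name_prefix="CM"
        )
        preds_scen = {}
        for ti, target in enumerate(("cveg", "csoil")):
            truth = t_cveg if target == "cveg" else t_csoil
            stack = gen_model_ensemble(
                truth, replace(scen_ens, seed=_subseed(cfg.seed, 20 + 2 * si + ti))
            )
            table = extract_training_table(plots, stack, ref, f"obs_{target}")
            model = train_mmrfe(table, replace(rf_cfg, seed=_subseed(cfg.seed, 30 + 2 * si + ti)))
            models[f"{target}_future_{scen}"] = model
            preds_scen[target] = _predict_cube(model, stack, future_years)
        ecd_future[scen] = GridCube(
            future_years,
            total_carbon(preds_scen["cveg"].data, preds_scen["csoil"].data),
            truth_cveg.geometry,
            units="Mg C/ha",
            name=f"ecd_{scen}",
        )

    # --- accounting -----------------------------------------------------
    areas = cell_areas(truth_cveg.geometry)
    hist_series = stock_series(ecd_hist, areas)
    hist_table = span_table(hist_series, cfg.span, "first-span", cfg.co2_factor)
    hist_mean = float(hist_series.mean())
    future_tables = {
        scen: span_table(stock_series(ecd_future[scen], areas), cfg.span,
                         hist_mean, cfg.co2_factor)
        for scen in SCENARIOS
    }
    trend_map = trend_slope_map(ecd_hist)

    # --- carbon-sink index and zones ------------------------------------
    csmap = csindex(ecd_hist)
    zones = kmeans_zones(csmap, cfg.k_zones, seed=_subseed(cfg.seed, 40))
    masks, fracs = zone_masks(zones, areas)
    zonal_tables: dict[str, dict[str, pd.DataFrame]] = {}
    for scen in SCENARIOS:
        zonal_tables[scen] = {}
        for zname, zmask in masks.items():
            zser_hist = stock_series(ecd_hist, areas, mask=~zmask)
            zser = stock_series(ecd_future[scen], areas, mask=~zmask)
            zonal_tables[scen][zname] = span_table(
                zser, cfg.span, float(zser_hist.mean()), cfg.co2_factor
            )

    # --- manifest -------------------------------------------------------
    digest = hashlib.sha256()
    for arr in (
        ecd_hist.data, ecd_future["rcp45"].data, ecd_future["rcp85"].data,
        ndvi_fused.data, csmap.values, zones.labels.astype(float), trend_map,
        validation.select_dtypes("number").to_numpy(),
        hist_table.select_dtypes("number").to_numpy(),
        future_tables["rcp45"].select_dtypes("number").to_numpy(),
        future_tables["rcp85"].select_dtypes("number").to_numpy(),
    ):
        digest.update(np.ascontiguousarray(arr, dtype=np.float64).tobytes())
    cfg_dict = asdict(cfg)
    manifest = {
        "config": cfg_dict,
        "config_hash": hashlib.sha256(
            json.dumps(cfg_dict, sort_keys=True, default=str).encode()
        ).hexdigest(),
        "numeric_digest": digest.hexdigest(),
        "seed": cfg.seed,
        "reference_year": ref,
        "n_plots": cfg.n_plots,
        "elapsed_s": round(time.time() - t0, 2),
    }

    result = PipelineResult(
        config=cfg,
        truth_cveg=truth_cveg,
        truth_csoil=truth_csoil,
        ndvi_fused=ndvi_fused,
        hist_stacks=hist_stacks,
        models=models,
        ecd_hist=ecd_hist,
        ecd_future=ecd_future,
        validation=validation,
        hist_table=hist_table,
        future_tables=future_tables,
        zonal_tables=zonal_tables,
        csindex_map=csmap,
        zones=zones,
        zone_fractions=fracs,
        trend_map=trend_map,
        manifest=manifest,
    )
    if out_dir is not None:
        _write_outputs(result, Path(out_dir))
    return result


def _write_outputs(res: PipelineResult, out: Path) -> None:
    out.mkdir(parents=True, exist_ok=True)
    fio.write_cube(out / "ecd_hist.nc", res.ecd_hist)
    for scen, cube in res.ecd_future.items():
        fio.write_cube(out / f"ecd_{scen}.nc", cube)
    fio.write_cube(out / "ndvi_fused.nc", res.ndvi_fused)
    geom = res.ecd_hist.geometry
    fio.write_grid(out / "csindex.nc", res.csindex_map.values, geom, units="%", name="csindex")
    fio.write_grid(out / "zones.nc", res.zones.labels.astype(float), geom, name="zone")
    fio.write_grid(out / "trend.nc", res.trend_map, geom, units="Mg C/ha/yr", name="trend")
    res.validation.to_csv(out / "validation.csv", index=False)
    res.hist_table.to_csv(out / "account_hist.csv", index=False)
    for scen, tbl in res.future_tables.items():
        tbl.to_csv(out / f"account_{scen}.csv", index=False)
    for scen, per_zone in res.zonal_tables.items():
        for zname, tbl in per_zone.items():
            tbl.to_csv(out / f"account_{scen}_{zname}.csv", index=False)
    zone_info = {
        "centroids": res.zones.centroids.tolist(),
        "boundaries": res.zones.boundaries.tolist(),
        "cluster_edges": res.zones.cluster_edges.tolist(),
        "area_fractions_pct": res.zone_fractions,
    }
    (out / "zones.json").write_text(json.dumps(zone_info, indent=2))
    (out / "manifest.json").write_text(json.dumps(res.manifest, indent=2, default=str))
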