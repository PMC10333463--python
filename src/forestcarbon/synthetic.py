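"""Synthetic study inputs with the statistical structure the analysis assumes.

The generator emulates the data constellation of a national forest-carbon
assessment: an unobservable "true" carbon-density field with spatial
autocorrelation and a slow secular trend; an ensemble of process-model
outputs that are biased, noisy distortions of that truth; NDVI observed by
two sensors at coarse and fine resolution as a saturating function of
vegetation carbon; and sparse field plots measuring truth with noise.

Everything is driven by explicit seeds: identical configs give bit-identical
outputs.  Sub-generators are derived from the config seed with
``numpy.random.SeedSequence.spawn`` so operations stay independent.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage

from .grids import BiweeklyCube, GridCube, GridGeometry, ModelStack

__all__ = [
    "TruthConfig",
    "EnsembleConfig",
    "gen_truth",
    "gen_model_ensemble",
    "gen_ndvi",
    "gen_plots",
    "correlated_field",
]


@dataclass(frozen=True)
class TruthConfig:
    """Parameters of the latent true carbon field.

    Densities are in Mg C/ha, the trend in Mg C/ha/yr.  ``spatial_corr_len``
    is the Gaussian smoothing sigma in grid cells; ``mask_fraction`` is the
    share of the domain carved out as non-forest (masked everywhere).
    """

    seed: int = 0
    nrows: int = 48
    ncols: int = 48
    year_start: int = 1982
    year_end: int = 2021
    mean_cveg: float = 43.0
    mean_csoil: float = 147.0
    spatial_sd_cveg: float = 15.0
    spatial_sd_csoil: float = 40.0
    trend: float = 0.07
    trend_csoil: float | None = None
    spatial_corr_len: float = 3.0
    interannual_sd: float = 1.0
    mask_fraction: float = 0.1
    origin_lat: float = 45.0
    origin_lon: float = 100.0
    cell_size: float = 0.01

    def __post_init__(self) -> None:
        if self.nrows < 8 or self.ncols < 8:
            raise ValueError("grid must be at least 8x8")
        if self.year_end - self.year_start + 1 < 5:
            raise ValueError("year range must span at least 5 years")
        for name in ("spatial_sd_cveg", "spatial_sd_csoil", "interannual_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not 0 <= self.mask_fraction < 1:
            raise ValueError("mask_fraction must be in [0, 1)")

    @property
    def years(self) -> np.ndarray:
        return np.arange(self.year_start, self.year_end + 1)

    @property
    def geometry(self) -> GridGeometry:
        return GridGeometry(
            self.origin_lat, self.origin_lon, self.cell_size, self.nrows, self.ncols
        )


@dataclass(frozen=True)
class EnsembleConfig:
    """Per-model distortions applied to the truth.

    ``mult_bias`` (a_k), ``add_bias`` (b_k, Mg C/ha) and ``noise_sd``
    (Mg C/ha) each have one entry per model; defaults span the kind of
    spread seen across process-based land models.
    """

    seed: int = 1
    n_models: int = 7
    mult_bias: tuple[float, ...] = (0.7, 0.8, 0.9, 1.0, 1.1, 1.2, 1.3)
    add_bias: tuple[float, ...] = (-30.0, -20.0, -10.0, 0.0, 10.0, 20.0, 30.0)
    noise_sd: tuple[float, ...] = (10.0, 15.0, 20.0, 25.0, 30.0, 35.0, 40.0)
    noise_corr_len: float = 3.0
    name_prefix: str = "M"

    def __post_init__(self) -> None:
        if self.n_models < 2:
            raise ValueError("need at least 2 models")
        for name in ("mult_bias", "add_bias", "noise_sd"):
            if len(getattr(self, name)) != self.n_models:
                raise ValueError(f"{name} must have n_models={self.n_models} entries")
        if any(s < 0 for s in self.noise_sd):
            raise ValueError("noise_sd entries must be >= 0")

    @property
    def names(self) -> list[str]:
        return [f"{self.name_prefix}{k + 1}" for k in range(self.n_models)]


def correlated_field(
    rng: np.random.Generator, shape: tuple[int, int], corr_len: float, sd: float
) -> np.ndarray:
    """Zero-mean Gaussian random field with unit-variance-then-scaled values
    and correlation length ~ corr_len cells (Gaussian-kernel smoothing of
    white noise, renormalized to the requested pointwise SD)."""
    white = rng.standard_normal(shape)
    if corr_len <= 0 or sd == 0:
        return sd * white
    smooth = ndimage.gaussian_filter(white, sigma=corr_len, mode="wrap")
    s = smooth.std()
    if s == 0:  # degenerate tiny grid
        return np.zeros(shape)
    return sd * smooth / s


def _forest_mask(rng: np.random.Generator, cfg: TruthConfig) -> np.ndarray:
    """True on masked (non-forest) pixels; contiguous blobs via thresholding
    a smooth field at the requested area quantile."""
    if cfg.mask_fraction == 0:
        return np.zeros((cfg.nrows, cfg.ncols), dtype=bool)
    f = correlated_field(rng, (cfg.nrows, cfg.ncols), cfg.spatial_corr_len, 1.0)
    thresh = np.quantile(f, cfg.mask_fraction)
    return f < thresh


def gen_truth(cfg: TruthConfig) -> tuple[GridCube, GridCube]:
    """Generate the latent true cVeg and cSoil cubes.

    Each variable is a fixed spatial base pattern plus a linear trend in
    time plus spatially correlated interannual noise, clipped at zero.
    Both variables share one non-forest mask.
    """
    ss = np.random.SeedSequence(cfg.seed)
    rng_mask, rng_v, rng_s = (np.random.default_rng(s) for s in ss.spawn(3))
    masked = _forest_mask(rng_mask, cfg)
    years = cfg.years
    t = years - years[0]
    geom = cfg.geometry
    trend_s = cfg.trend if cfg.trend_csoil is None else cfg.trend_csoil

    cubes = []
    for rng, mean, sd, trend, name in (
        (rng_v, cfg.mean_cveg, cfg.spatial_sd_cveg, cfg.trend, "cveg"),
        (rng_s, cfg.mean_csoil, cfg.spatial_sd_csoil, trend_s, "csoil"),
    ):
        base = mean + correlated_field(rng, geom.shape, cfg.spatial_corr_len, sd)
        data = np.empty((years.size, *geom.shape))
        for i, ti in enumerate(t):
            noise = correlated_field(
                rng, geom.shape, cfg.spatial_corr_len, cfg.interannual_sd
            )
            data[i] = base + trend * ti + noise
        np.clip(data, 0.0, None, out=data)
        data[:, masked] = np.nan
        cubes.append(GridCube(years, data, geom, units="Mg C/ha", name=name))
    return cubes[0], cubes[1]


def gen_model_ensemble(truth: GridCube, cfg: EnsembleConfig) -> ModelStack:
    """Distort the truth into an ensemble of process-model-like outputs:
    model_k = a_k * truth + b_k + spatially correlated noise(sd_k), clipped
    at zero.  The truth's mask propagates to every model."""
    if not np.all(np.isfinite(truth.data[~truth.mask])):
        raise ValueError("truth must be finite on unmasked pixels")
    ss = np.random.SeedSequence(cfg.seed)
    masked = truth.mask
    cubes = []
    for k, child in enumerate(ss.spawn(cfg.n_models)):
        rng = np.random.default_rng(child)
        data = cfg.mult_bias[k] * truth.data + cfg.add_bias[k]
        for i in range(truth.n_years):
            data[i] += correlated_field(
                rng, truth.geometry.shape, cfg.noise_corr_len, cfg.noise_sd[k]
            )
        np.clip(data, 0.0, None, out=data)
        data[masked] = np.nan
        cubes.append(
            GridCube(truth.years, data, truth.geometry, units=truth.units,
                     name=f"{cfg.names[k]}_{truth.name}")
        )
    return ModelStack(names=cfg.names, cubes=cubes, variable=truth.name)


def gen_ndvi(
    truth_cveg: GridCube,
    coarsen_factor: int,
    noise_sd: float = 0.02,
    *,
    v_max: float = 0.9,
    half_const: float | None = None,
    seasonal_amp: float = 0.15,
    seed: int = 2,
) -> tuple[BiweeklyCube, BiweeklyCube]:
    """Two-resolution biweekly NDVI from the true vegetation carbon.

    NDVI saturates with carbon density, v_max * c / (c + h), modulated by a
    sinusoidal seasonal cycle over the 24 biweekly layers of each year plus
    sensor noise, clipped to the physical range [-0.2, 1].  The fine cube is
    on the truth geometry; the coarse cube is the block mean of the fine
    cube, perturbed by its own sensor noise.

    Returns (coarse, fine).
    """
    if coarsen_factor < 2:
        raise ValueError("coarsen_factor must be >= 2")
    geom = truth_cveg.geometry
    coarse_geom = geom.coarsen(coarsen_factor)  # validates divisibility
    h = half_const if half_const is not None else float(np.nanmean(truth_cveg.data))
    if h <= 0:
        raise ValueError("saturation half-constant must be positive")
    rng = np.random.default_rng(np.random.SeedSequence(seed))

    years = truth_cveg.years
    nlay = BiweeklyCube.LAYERS_PER_YEAR
    c = truth_cveg.data  # (y, r, cpx)
    sat = v_max * c / (c + h)
    # additive seasonal cycle in [0, seasonal_amp], peaking mid-year
    phase = (np.arange(nlay) + 0.5) / nlay
    season = 0.5 * seasonal_amp * (1.0 - np.cos(2 * np.pi * phase))
    fine = sat[:, None, :, :] + season[None, :, None, None]
    if noise_sd > 0:
        fine = fine + rng.normal(0.0, noise_sd, fine.shape)
    fine = np.clip(fine, -0.2, 1.0)
    fine[np.broadcast_to(truth_cveg.mask[:, None], fine.shape)] = np.nan

    f = coarsen_factor
    ny, _, nr, nc = fine.shape
    blocks = fine.reshape(ny, nlay, nr // f, f, nc // f, f)
    import warnings as _warnings
    with _warnings.catch_warnings():
        _warnings.simplefilter("ignore", RuntimeWarning)
        coarse = np.nanmean(blocks, axis=(3, 5))
    if noise_sd > 0:
        pert = rng.normal(0.0, noise_sd, coarse.shape)
        coarse = np.clip(coarse + pert, -0.2, 1.0)

    fine_cube = BiweeklyCube(years, fine, geom, units="1", name="ndvi_fine")
    coarse_cube = BiweeklyCube(years, coarse, coarse_geom, units="1", name="ndvi_coarse")
    return coarse_cube, fine_cube


def gen_plots(
    truth_cveg: GridCube,
    truth_csoil: GridCube,
    reference_year: int,
    n_plots: int,
    obs_noise_sd: float = 5.0,
    seed: int = 3,
) -> pd.DataFrame:
    """Field plots at uniformly sampled unmasked pixel centers.

    Observed densities are truth at the reference year plus independent
    Normal(0, obs_noise_sd) measurement error (negative draws kept — field
    estimates are unbiased, not censored).  The returned table also carries
    the noiseless truth columns for diagnostics; a real campaign would not
    have them.
    """
    if n_plots < 1:
        raise ValueError("n_plots must be >= 1")
    geom = truth_cveg.geometry
    tv = truth_cveg.at_year(reference_year)
    ts = truth_csoil.at_year(reference_year)
    valid = np.flatnonzero(~(np.isnan(tv) | np.isnan(ts)).ravel())
    if n_plots > valid.size:
        raise ValueError(
            f"requested {n_plots} plots but only {valid.size} unmasked pixels"
        )
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    chosen = rng.choice(valid, size=n_plots, replace=False)
    rows, cols = np.unravel_index(chosen, geom.shape)
    lat = geom.lat_centers()[rows]
    lon = geom.lon_centers()[cols]
    noise_v = rng.normal(0.0, obs_noise_sd, n_plots)
    noise_s = rng.normal(0.0, obs_noise_sd, n_plots)
    return pd.DataFrame(
        {
            "plot_id": np.arange(1, n_plots + 1),
            "lon": lon,
            "lat": lat,
            "obs_cveg": tv[rows, cols] + noise_v,
            "obs_csoil": ts[rows, cols] + noise_s,
            "true_cveg": tv[rows, cols],
            "true_csoil": ts[rows, cols],
        }
    )
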