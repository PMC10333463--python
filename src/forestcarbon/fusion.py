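"""Fusing a long coarse NDVI record with a short fine record.

The goal is one continuous fine-resolution annual NDVI series spanning the
whole coarse-sensor era.  The recipe: maximum-value compositing of biweekly
layers into months, a vegetation-thresholded annual mean, per-sensor
climatologies over the years both sensors observed, bilinear resampling of
the coarse annual grid onto the fine geometry, and a ratio correction that
rescales the coarse signal into the fine sensor's radiometry:

    fused = (1 + (NDVI_G - ANDVI_M) / ANDVI_M) * NDVI_G / V,
    V = ANDVI_G / ANDVI_M

where NDVI_G is the resampled coarse annual value and ANDVI_G / ANDVI_M the
coarse / fine climatologies on the fine grid.  Algebraically the fine
climatology cancels — the expression reduces to NDVI_G^2 / ANDVI_G — so the
fine sensor influences the result only through masking and diagnostics;
both the literal composition and the simplified form are kept and tested
for equality.
"""
from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np

from .grids import GridCube, GridGeometry

__all__ = [
    "FusionInputs",
    "mvc_composite",
    "bilinear_resample",
    "annual_mean_ndvi",
    "climatology",
    "fuse_ndvi",
    "annual_series_from_biweekly",
]

logger = logging.getLogger(__name__)

NDVI_RANGE = (-0.2, 1.0)
VEG_THRESHOLD = 0.1


def mvc_composite(layers: list[np.ndarray]) -> np.ndarray:
    """Maximum-value composite: per-pixel maximum over non-missing layers.

    Compositing suppresses cloud and atmospheric depression of NDVI, which
    only ever biases the signal downward.  All-missing pixels stay missing.
    """
    if len(layers) == 0:
        raise ValueError("need at least one layer")
    shapes = {l.shape for l in layers}
    if len(shapes) > 1:
        raise ValueError(f"layers disagree on shape: {shapes}")
    stack = np.stack(layers)
    all_nan = np.all(np.isnan(stack), axis=0)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        out = np.nanmax(stack, axis=0)
    out[all_nan] = np.nan
    return out


def bilinear_resample(
    grid: np.ndarray, source: GridGeometry, target: GridGeometry
) -> np.ndarray:
    """Bilinear interpolation from the 4 surrounding source-cell centers.

    Target points beyond the outermost source centers are clamped to the
    edge row/column (no extrapolation).  Missing neighbors drop out and the
    remaining weights renormalize; all four missing leaves the pixel missing.
    """
    if grid.shape != source.shape:
        raise ValueError("grid shape does not match source geometry")
    src_lat = source.lat_centers()  # descending
    src_lon = source.lon_centers()  # ascending
    tgt_lat = target.lat_centers()
    tgt_lon = target.lon_centers()

    # fractional index along each axis, clamped to [0, n-1]
    fi = (src_lat[0] - tgt_lat) / source.cell_size  # lat decreases with row
    fj = (tgt_lon - src_lon[0]) / source.cell_size
    fi = np.clip(fi, 0.0, source.nrows - 1.0)
    fj = np.clip(fj, 0.0, source.ncols - 1.0)

    i0 = np.floor(fi).astype(int)
    j0 = np.floor(fj).astype(int)
    i1 = np.minimum(i0 + 1, source.nrows - 1)
    j1 = np.minimum(j0 + 1, source.ncols - 1)
    di = (fi - i0)[:, None]
    dj = (fj - j0)[None, :]

    I0, I1 = i0[:, None], i1[:, None]
    J0, J1 = j0[None, :], j1[None, :]
    vals = np.stack(
        [grid[I0, J0], grid[I0, J1], grid[I1, J0], grid[I1, J1]]
    )
    w = np.stack(
        [(1 - di) * (1 - dj), (1 - di) * dj, di * (1 - dj), di * dj]
    )
    w = np.broadcast_to(w, vals.shape).copy()
    w[np.isnan(vals)] = 0.0
    wsum = w.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        out = np.where(wsum > 0, np.nansum(w * vals, axis=0) / wsum, np.nan)
    return out


def annual_mean_ndvi(
    monthly: list[np.ndarray], veg_threshold: float = VEG_THRESHOLD
) -> np.ndarray:
    """Annual NDVI: per-pixel mean over the months that clear the
    vegetation threshold.  Pixels where no month qualifies are masked as
    non-vegetated.  The divisor is the count of qualifying months — a fixed
    1/12 would drag vegetated means toward zero in short growing seasons.
    """
    if len(monthly) != 12:
        raise ValueError(f"need 12 monthly grids, got {len(monthly)}")
    stack = np.stack(monthly)
    qual = stack > veg_threshold
    n = qual.sum(axis=0)
    s = np.where(qual, stack, 0.0).sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        return np.where(n > 0, s / n, np.nan)


def climatology(annual: list[np.ndarray]) -> np.ndarray:
    """Per-pixel mean over unmasked years of the window."""
    if len(annual) == 0:
        raise ValueError("empty climatology window")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        return np.nanmean(np.stack(annual), axis=0)


@dataclass
class FusionInputs:
    """Everything `fuse_ndvi` needs, all on the fine geometry.

    ``coarse_annual`` is the coarse sensor's annual cube already bilinearly
    resampled onto the fine grid; ``clim_coarse`` / ``clim_fine`` are the
    two sensors' annual-NDVI climatologies over the shared overlap window.
    """

    coarse_annual: GridCube
    clim_coarse: np.ndarray
    clim_fine: np.ndarray

    def __post_init__(self) -> None:
        shape = self.coarse_annual.geometry.shape
        if self.clim_coarse.shape != shape or self.clim_fine.shape != shape:
            raise ValueError("climatologies must be on the cube's geometry")


def fuse_ndvi(inputs: FusionInputs, year: int) -> np.ndarray:
    """One fused fine-resolution annual NDVI grid.

    Pixels where either climatology is missing or non-positive are masked
    and counted in the log — the ratio correction is undefined there.
    Output is clipped to the physical NDVI range [-0.2, 1].
    """
    g = inputs.coarse_annual.at_year(year)
    ag = inputs.clim_coarse
    am = inputs.clim_fine
    bad = ~(ag > 0) | ~(am > 0)  # catches NaN, zero and negative
    n_bad = int(np.count_nonzero(bad & ~np.isnan(g)))
    if n_bad:
        logger.info("fuse_ndvi year %d: %d pixels masked (bad climatology)", year, n_bad)
    with np.errstate(invalid="ignore", divide="ignore"):
        v = ag / am
        fused = (1.0 + (g - am) / am) * g / v
    fused = np.where(bad, np.nan, fused)
    return np.clip(fused, *NDVI_RANGE)


def annual_series_from_biweekly(cube, veg_threshold: float = VEG_THRESHOLD) -> GridCube:
    """Biweekly stack -> MVC monthly -> thresholded annual mean, per year."""
    out = np.empty((cube.years.size, *cube.geometry.shape))
    for yi, year in enumerate(cube.years):
        monthly = [
            mvc_composite(cube.monthly_layers(year, m)) for m in range(1, 13)
        ]
        out[yi] = annual_mean_ndvi(monthly, veg_threshold)
    return GridCube(cube.years, out, cube.geometry, units="1", name=f"{cube.name}_annual")


def fuse_series(
    coarse: GridCube,
    fine: GridCube,
    overlap_years: tuple[int, int],
) -> GridCube:
    """Full fusion of an annual coarse cube onto a fine cube's geometry.

    The coarse cube is resampled year by year onto the fine geometry, both
    climatologies are taken over ``overlap_years`` (inclusive), and every
    coarse year is fused.  Years the fine sensor observed are still fused
    from the coarse record so the series is radiometrically homogeneous.
    """
    y0, y1 = overlap_years
    fine_geom = fine.geometry
    res = np.empty((coarse.years.size, *fine_geom.shape))
    for yi in range(coarse.years.size):
        res[yi] = bilinear_resample(coarse.data[yi], coarse.geometry, fine_geom)
    coarse_on_fine = GridCube(coarse.years, res, fine_geom, units="1", name="coarse_on_fine")

    ov = (coarse.years >= y0) & (coarse.years <= y1)
    if not ov.any():
        raise ValueError("overlap window contains no coarse years")
    ov_f = (fine.years >= y0) & (fine.years <= y1)
    if not ov_f.any():
        raise ValueError("overlap window contains no fine years")
    clim_g = climatology(list(res[ov]))
    clim_m = climatology(list(fine.data[ov_f]))

    inputs = FusionInputs(coarse_on_fine, clim_g, clim_m)
    fused = np.empty_like(res)
    for yi, year in enumerate(coarse.years):
        fused[yi] = fuse_ndvi(inputs, year)
    return GridCube(coarse.years, fused, fine_geom, units="1", name="ndvi_fused")
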