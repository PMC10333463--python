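"""From density grids to carbon stocks, increments and CO2 equivalents.

Densities (Mg C/ha) integrate over spherical-Earth cell areas to national
or zonal stocks in Pg C (1 Pg = 1e9 Mg).  Stock series are summarized in
5-year spans: per-span mean and SD of the annual stocks, the increment
over the previous span, the cumulative increment over a baseline, and the
CO2 equivalent of the cumulative increment.

The CO2 conversion factor defaults to 36.67 Bt CO2 per Pg C.  Note this is
ten times the molar C->CO2 ratio (44/12 = 3.667); it is kept as the default
so accounting tables reproduce the source convention, and it is a plain
argument everywhere for users who want the molar factor.
"""
from __future__ import annotations

import numpy as np
import pandas as pd

from .grids import GridCube, GridGeometry

__all__ = [
    "CO2_PER_PGC",
    "EARTH_RADIUS_M",
    "cell_areas",
    "total_stock",
    "stock_series",
    "span_table",
    "co2_equivalent",
    "trend_slope_map",
    "area_fraction",
    "scenario_envelope",
]

EARTH_RADIUS_M = 6_371_000.0
CO2_PER_PGC = 36.67  # Bt CO2 per Pg C (see module docstring)
M2_PER_HA = 1e4
MG_PER_PG = 1e9


def cell_areas(geometry: GridGeometry) -> np.ndarray:
    """Cell areas in hectares on a spherical Earth.

    A lat/lon cell spanning [phi_b, phi_t] x dlambda has area
    R^2 * dlambda * (sin phi_t - sin phi_b); it depends on latitude only,
    shrinking toward the poles, so one value per row is broadcast across
    columns.
    """
    edges = np.deg2rad(geometry.lat_edges())  # north to south
    dlam = np.deg2rad(geometry.cell_size)
    band = EARTH_RADIUS_M**2 * dlam * (np.sin(edges[:-1]) - np.sin(edges[1:]))
    return np.broadcast_to(band[:, None] / M2_PER_HA, geometry.shape).copy()


def total_stock(
    density: np.ndarray, areas: np.ndarray, mask: np.ndarray | None = None
) -> float:
    """Area-integrated stock in Pg C over unmasked pixels."""
    if density.shape != areas.shape:
        raise ValueError(f"geometry mismatch: {density.shape} vs {areas.shape}")
    valid = ~np.isnan(density)
    if mask is not None:
        valid &= ~mask
    return float(np.sum(density[valid] * areas[valid]) / MG_PER_PG)


def stock_series(
    cube: GridCube, areas: np.ndarray | None = None, mask: np.ndarray | None = None
) -> pd.Series:
    """Annual national (or zonal, via mask) stock series, Pg C."""
    if areas is None:
        areas = cell_areas(cube.geometry)
    vals = [total_stock(cube.data[i], areas, mask) for i in range(cube.n_years)]
    return pd.Series(vals, index=cube.years, name="stock_pgc")


def span_table(
    series: pd.Series,
    span: int = 5,
    baseline: float | str = "first-span",
    co2_factor: float = CO2_PER_PGC,
) -> pd.DataFrame:
    """Summarize an annual stock series in consecutive spans.

    ``baseline`` selects what "cumulative increment" is measured against:
    the first span's mean (historical convention), the series' own overall
    mean ('series-mean'), or any explicit stock value (e.g. the historical-
    period mean when summarizing a future scenario).  Increments always
    compare adjacent spans; cumulative columns compare each span with the
    baseline; cumulative CO2 is the cumulative increment times co2_factor.
    The series must cover whole spans.
    """
    years = np.asarray(series.index, dtype=int)
    if years.size % span:
        raise ValueError(f"series length {years.size} is not a whole number of {span}-year spans")
    if not np.all(np.diff(years) == 1):
        raise ValueError("years must be contiguous")
    vals = series.to_numpy(dtype=float)
    n_spans = years.size // span
    means = vals.reshape(n_spans, span).mean(axis=1)
    sds = vals.reshape(n_spans, span).std(axis=1, ddof=0)

    if baseline == "first-span":
        base = means[0]
    elif baseline == "series-mean":
        base = vals.mean()
    else:
        base = float(baseline)

    increments = np.diff(means, prepend=means[0])
    cumulative = means - base
    labels = [f"{years[i * span]}-{years[i * span + span - 1]}" for i in range(n_spans)]
    return pd.DataFrame(
        {
            "period": labels,
            "mean_stock_pgc": means,
            "sd_pgc": sds,
            "increment_pgc": increments,
            "cumulative_increment_pgc": cumulative,
            "cumulative_co2_bt": cumulative * co2_factor,
        }
    )


def co2_equivalent(pgc: float | np.ndarray, factor: float = CO2_PER_PGC):
    """Carbon mass (Pg C) to CO2 mass (Bt CO2); linear, sign-preserving."""
    return pgc * factor


def trend_slope_map(cube: GridCube, min_years: int = 3) -> np.ndarray:
    """Per-pixel OLS slope of density against year, Mg C/ha/yr.

    Pixels with fewer than ``min_years`` valid years are masked.  The
    closed-form slope cov(t, x)/var(t) is evaluated with per-pixel valid
    counts so intermittent masking is handled exactly.
    """
    if cube.n_years < min_years:
        raise ValueError(f"cube has {cube.n_years} years; need >= {min_years}")
    t = cube.years.astype(float)[:, None, None]
    x = cube.data
    ok = ~np.isnan(x)
    n = ok.sum(axis=0)
    tm = np.where(ok, t, 0.0)
    xm = np.where(ok, x, 0.0)
    with np.errstate(invalid="ignore", divide="ignore"):
        tbar = tm.sum(axis=0) / n
        xbar = xm.sum(axis=0) / n
        cov = (np.where(ok, (t - tbar) * (x - xbar), 0.0)).sum(axis=0)
        var = (np.where(ok, (t - tbar) ** 2, 0.0)).sum(axis=0)
        slope = cov / var
    slope[(n < min_years) | (var == 0)] = np.nan
    return slope


def area_fraction(
    grid: np.ndarray, predicate, areas: np.ndarray
) -> float:
    """Area-weighted percentage of the unmasked domain where the predicate
    holds.  ``predicate`` is a callable on the grid values or a precomputed
    boolean array."""
    if grid.shape != areas.shape:
        raise ValueError("geometry mismatch")
    valid = ~np.isnan(grid)
    if not valid.any():
        raise ValueError("no unmasked pixels")
    sel = predicate(grid) if callable(predicate) else np.asarray(predicate, dtype=bool)
    total = areas[valid].sum()
    return float(100.0 * areas[valid & sel].sum() / total)


def scenario_envelope(
    series_lo: pd.Series, series_hi: pd.Series, co2_factor: float = CO2_PER_PGC
) -> pd.DataFrame:
    """Uncertainty envelope between two scenario stock series.

    Treats the high-forcing scenario as the upper limit: amplitude is
    hi - lo per period, also expressed in CO2 units and as a percentage of
    the low scenario's CO2 absorption (flagging periods where scenario
    spread exceeds half the low-scenario signal).
    """
    if not series_lo.index.equals(series_hi.index):
        raise ValueError("scenario series must share the same periods")
    amp = series_hi - series_lo
    amp_co2 = amp * co2_factor
    lo_co2 = series_lo * co2_factor
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(lo_co2 != 0, 100.0 * amp_co2 / lo_co2, np.nan)
    return pd.DataFrame(
        {
            "amplitude_pgc": amp,
            "amplitude_co2_bt": amp_co2,
            "ratio_pct": ratio,
            "exceeds_half": ratio > 50.0,
        },
        index=series_lo.index,
    )
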