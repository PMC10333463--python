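"""Gridded data containers shared by every stage of the pipeline.

All rasters are rectangular lat/lon grids, cell-registered, with row 0 the
northernmost row.  Missing data is encoded as NaN throughout; a separate
boolean mask is always derived, never stored.
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterator

import numpy as np


@dataclass(frozen=True)
class GridGeometry:
    """Description of a regular lat/lon raster.

    ``origin_lat`` is the latitude of the *north* edge and ``origin_lon`` the
    longitude of the *west* edge.  The center of pixel (r, c) is at

        lat = origin_lat - (r + 0.5) * cell_size
        lon = origin_lon + (c + 0.5) * cell_size

    so row index increases southward and column index eastward.
    """

    origin_lat: float
    origin_lon: float
    cell_size: float
    nrows: int
    ncols: int

    def __post_init__(self) -> None:
        if self.cell_size <= 0:
            raise ValueError(f"cell_size must be positive, got {self.cell_size}")
        if self.nrows < 1 or self.ncols < 1:
            raise ValueError(f"grid dims must be >= 1, got {self.nrows}x{self.ncols}")

    @property
    def shape(self) -> tuple[int, int]:
        return (self.nrows, self.ncols)

    def lat_centers(self) -> np.ndarray:
        return self.origin_lat - (np.arange(self.nrows) + 0.5) * self.cell_size

    def lon_centers(self) -> np.ndarray:
        return self.origin_lon + (np.arange(self.ncols) + 0.5) * self.cell_size

    def lat_edges(self) -> np.ndarray:
        """North-to-south cell edges, length nrows + 1."""
        return self.origin_lat - np.arange(self.nrows + 1) * self.cell_size

    def pixel_of(self, lon: np.ndarray, lat: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Containing pixel (row, col) for points; half-open cells
        [west, east) x (south, north].  Points outside the extent get -1."""
        lon = np.asarray(lon, dtype=float)
        lat = np.asarray(lat, dtype=float)
        col = np.floor((lon - self.origin_lon) / self.cell_size).astype(int)
        # row: (south, north] — a point exactly on the north edge of row r
        # belongs to row r, hence ceil-minus-one on the downward axis.
        row = np.ceil((self.origin_lat - lat) / self.cell_size).astype(int) - 1
        row = np.where(lat == self.origin_lat, 0, row)
        bad = (col < 0) | (col >= self.ncols) | (row < 0) | (row >= self.nrows)
        return np.where(bad, -1, row), np.where(bad, -1, col)

    def coarsen(self, factor: int) -> "GridGeometry":
        if self.nrows % factor or self.ncols % factor:
            raise ValueError(
                f"coarsen factor {factor} does not divide dims {self.nrows}x{self.ncols}"
            )
        return GridGeometry(
            self.origin_lat,
            self.origin_lon,
            self.cell_size * factor,
            self.nrows // factor,
            self.ncols // factor,
        )


@dataclass
class GridCube:
    """A (year, row, col) stack of one gridded variable.

    ``data`` is float with NaN marking missing/unforested pixels; ``years``
    is the integer year of each leading-axis slice.
    """

    years: np.ndarray
    data: np.ndarray
    geometry: GridGeometry
    units: str = ""
    name: str = ""

    def __post_init__(self) -> None:
        self.years = np.asarray(self.years, dtype=int)
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 3:
            raise ValueError(f"cube data must be 3-D (year, row, col), got {self.data.shape}")
        if self.data.shape[0] != self.years.size:
            raise ValueError("leading axis length must match number of years")
        if self.data.shape[1:] != self.geometry.shape:
            raise ValueError(
                f"data shape {self.data.shape[1:]} != geometry {self.geometry.shape}"
            )

    @property
    def mask(self) -> np.ndarray:
        """True where data is missing."""
        return np.isnan(self.data)

    @property
    def n_years(self) -> int:
        return self.years.size

    def at_year(self, year: int) -> np.ndarray:
        idx = np.flatnonzero(self.years == year)
        if idx.size == 0:
            raise KeyError(f"year {year} not in cube ({self.years[0]}..{self.years[-1]})")
        return self.data[idx[0]]

    def copy(self) -> "GridCube":
        return replace(self, years=self.years.copy(), data=self.data.copy())


@dataclass
class BiweeklyCube:
    """NDVI-style stack with 24 sub-annual layers per year:
    data has shape (n_years, 24, nrows, ncols)."""

    years: np.ndarray
    data: np.ndarray
    geometry: GridGeometry
    units: str = ""
    name: str = "ndvi"

    LAYERS_PER_YEAR = 24

    def __post_init__(self) -> None:
        self.years = np.asarray(self.years, dtype=int)
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 4 or self.data.shape[1] != self.LAYERS_PER_YEAR:
            raise ValueError(
                f"biweekly data must be (years, 24, rows, cols), got {self.data.shape}"
            )
        if self.data.shape[0] != self.years.size:
            raise ValueError("leading axis length must match number of years")
        if self.data.shape[2:] != self.geometry.shape:
            raise ValueError("spatial dims do not match geometry")

    def monthly_layers(self, year: int, month: int) -> list[np.ndarray]:
        """The two biweekly layers of one month (month in 1..12)."""
        (yi,) = np.flatnonzero(self.years == year)
        b0 = (month - 1) * 2
        return [self.data[yi, b0], self.data[yi, b0 + 1]]


@dataclass
class ModelStack:
    """Per-model cubes of one variable under one scenario.

    Feature extraction and prediction key on model *names*, never position.
    """

    names: list[str]
    cubes: list[GridCube]
    variable: str = ""
    scenario: str = ""

    def __post_init__(self) -> None:
        if len(self.names) != len(self.cubes):
            raise ValueError("one name per cube required")
        if len(set(self.names)) != len(self.names):
            raise ValueError("model names must be unique")
        geoms = {c.geometry for c in self.cubes}
        if len(geoms) > 1:
            raise ValueError("all cubes in a stack must share a geometry")

    def __len__(self) -> int:
        return len(self.names)

    def __iter__(self) -> Iterator[tuple[str, GridCube]]:
        return iter(zip(self.names, self.cubes))

    @property
    def geometry(self) -> GridGeometry:
        return self.cubes[0].geometry

    @property
    def years(self) -> np.ndarray:
        return self.cubes[0].years

    def grids_at(self, year: int) -> dict[str, np.ndarray]:
        return {name: cube.at_year(year) for name, cube in self}

    def reordered(self, names: list[str]) -> "ModelStack":
        """Same stack with models permuted into the given name order."""
        if sorted(names) != sorted(self.names):
            raise ValueError("names must be a permutation of the stack's names")
        idx = [self.names.index(n) for n in names]
        return ModelStack(
            names=list(names),
            cubes=[self.cubes[i] for i in idx],
            variable=self.variable,
            scenario=self.scenario,
        )
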