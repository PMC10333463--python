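"""Carbon-sink index and K-means intensity zoning.

A pixel that gains carbon in most years is a persistent sink even if its
net gain is modest; a pixel with one large gain and many losses is not.
The carbon-sink index captures this persistence: over an N-step window of
annual stocks it is the percentage of strictly positive year-to-year
increments,

    CSindex = 100 * #{k : C_{k+1} - C_k > 0} / N,

so a 40-year record gives N = 39 increments.  A zero increment counts as
a non-sink year.  The index depends only on the *signs* of the increments,
making it invariant to adding a constant and to any positive-slope affine
rescaling of the series.

Zoning clusters the 1-D index values into weak / medium / strong classes
with K-means (k-means++ init, multiple restarts, fixed seed), relabeled by
ascending centroid so the class order is meaningful regardless of the
clustering's arbitrary label assignment.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.cluster import KMeans

from .accounting import area_fraction, cell_areas
from .grids import GridCube

__all__ = ["CSindexMap", "ZoneMap", "ZONE_NAMES", "csindex", "kmeans_zones", "zone_masks"]

ZONE_NAMES = ("weak", "medium", "strong")


@dataclass
class CSindexMap:
    """Per-pixel carbon-sink index in [0, 100] percent."""

    values: np.ndarray
    n_years: int  # number of increments N
    geometry: object

    def __post_init__(self) -> None:
        v = self.values[~np.isnan(self.values)]
        if v.size and (v.min() < 0 or v.max() > 100):
            raise ValueError("CSindex must lie in [0, 100]")

    @property
    def mask(self) -> np.ndarray:
        return np.isnan(self.values)


def csindex(cube: GridCube) -> CSindexMap:
    """Percentage of strictly positive annual first differences per pixel.

    Pixels with no valid consecutive-year pair are masked; pixels with an
    intermittent mask use only their valid pairs (N varies per pixel in
    that case, but the common case — a static land mask — gives every
    pixel the same N = years - 1).
    """
    if cube.n_years < 2:
        raise ValueError("need at least 2 years of stocks")
    diffs = np.diff(cube.data, axis=0)
    valid = ~np.isnan(diffs)
    n_valid = valid.sum(axis=0)
    n_pos = np.count_nonzero(np.where(valid, diffs > 0, False), axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        vals = np.where(n_valid > 0, 100.0 * n_pos / n_valid, np.nan)
    return CSindexMap(values=vals, n_years=cube.n_years - 1, geometry=cube.geometry)


@dataclass
class ZoneMap:
    """Weak/medium/strong sink classes from 1-D K-means on the index.

    ``labels`` holds 0 (weak), 1 (medium), 2 (strong), NaN-masked via -1.
    ``boundaries`` are the midpoints between adjacent sorted centroids;
    ``cluster_edges`` the empirical [min, max] of each class — the lower
    edge of a class is the operative threshold between it and the class
    below.
    """

    labels: np.ndarray  # int, -1 = masked
    centroids: np.ndarray  # ascending, len k
    boundaries: np.ndarray  # len k-1
    cluster_edges: np.ndarray  # (k, 2) empirical min/max
    geometry: object

    def mask_of(self, zone: int | str) -> np.ndarray:
        if isinstance(zone, str):
            zone = ZONE_NAMES.index(zone)
        return self.labels == zone


def kmeans_zones(csmap: CSindexMap, k: int = 3, seed: int = 0) -> ZoneMap:
    """Cluster the index values into k ordered intensity classes."""
    vals = csmap.values
    finite = ~np.isnan(vals)
    x = vals[finite]
    if np.unique(x).size < k:
        raise ValueError(f"need >= {k} distinct index values, got {np.unique(x).size}")
    km = KMeans(n_clusters=k, n_init=10, random_state=int(seed) % (2**31))
    raw = km.fit_predict(x[:, None])
    order = np.argsort(km.cluster_centers_.ravel())
    relabel = np.empty(k, dtype=int)
    relabel[order] = np.arange(k)
    lab = relabel[raw]

    centroids = np.sort(km.cluster_centers_.ravel())
    boundaries = 0.5 * (centroids[:-1] + centroids[1:])
    edges = np.array([[x[lab == z].min(), x[lab == z].max()] for z in range(k)])

    labels = np.full(vals.shape, -1, dtype=int)
    labels[finite] = lab
    return ZoneMap(
        labels=labels,
        centroids=centroids,
        boundaries=boundaries,
        cluster_edges=edges,
        geometry=csmap.geometry,
    )


def zone_masks(
    zones: ZoneMap, areas: np.ndarray | None = None
) -> tuple[dict[str, np.ndarray], dict[str, float]]:
    """Disjoint per-zone pixel masks and their area-weighted percentages.

    The masks partition the unmasked domain exactly, so the fractions sum
    to 100% by construction (up to rounding in the weights).
    """
    if areas is None:
        areas = cell_areas(zones.geometry)
    k = zones.centroids.size
    names = ZONE_NAMES if k == 3 else tuple(f"zone{z}" for z in range(k))
    masks = {names[z]: zones.labels == z for z in range(k)}
    valid = zones.labels >= 0
    total = areas[valid].sum()
    fracs = {name: float(100.0 * areas[m].sum() / total) for name, m in masks.items()}
    return masks, fracs
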