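"""IDW interpolation of station statistics onto a regular grid and
percentile-based value clipping for shared display scales."""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy.spatial import cKDTree

from .errors import ConfigurationError, DataError

__all__ = ["RasterSpec", "Raster", "idw_interpolate", "clip_for_display"]


@dataclass(frozen=True)
class RasterSpec:
    """Regular lon/lat grid: origin = lower-left cell center."""

    origin_lon: float
    origin_lat: float
    cell_size: float = 0.1
    n_lon: int = 1
    n_lat: int = 1

    def __post_init__(self) -> None:
        if self.cell_size <= 0:
            raise ConfigurationError("cell_size must be > 0")
        if self.n_lon < 1 or self.n_lat < 1:
            raise ConfigurationError("grid must have >= 1 cell per axis")

    @classmethod
    def covering(
        cls,
        lons: Sequence[float],
        lats: Sequence[float],
        cell_size: float = 0.1,
    ) -> "RasterSpec":
        lon0, lon1 = float(np.min(lons)), float(np.max(lons))
        lat0, lat1 = float(np.min(lats)), float(np.max(lats))
        n_lon = int(np.ceil((lon1 - lon0) / cell_size)) + 1
        n_lat = int(np.ceil((lat1 - lat0) / cell_size)) + 1
        return cls(lon0, lat0, cell_size, n_lon, n_lat)

    @property
    def lons(self) -> np.ndarray:
        return self.origin_lon + self.cell_size * np.arange(self.n_lon)

    @property
    def lats(self) -> np.ndarray:
        return self.origin_lat + self.cell_size * np.arange(self.n_lat)


@dataclass
class Raster:
    spec: RasterSpec
    values: np.ndarray  # shape (n_lat, n_lon), NaN = nodata

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (self.spec.n_lat, self.spec.n_lon):
            raise DataError("raster values shape does not match its spec")


def _haversine(lon1, lat1, lon2, lat2) -> np.ndarray:
    r = 6371.0
    p1, p2 = np.radians(lat1), np.radians(lat2)
    dlat = p2 - p1
    dlon = np.radians(lon2) - np.radians(lon1)
    a = np.sin(dlat / 2) ** 2 + np.cos(p1) * np.cos(p2) * np.sin(dlon / 2) ** 2
    return 2 * r * np.arcsin(np.sqrt(a))


def idw_interpolate(
    points: Sequence[tuple[float, float, float]],
    grid: RasterSpec,
    k_neighbors: int = 4,
    power: float = 2.0,
    metric: str = "planar",
) -> Raster:
    """Inverse-distance-weighted interpolation from the k nearest stations.

    Each cell value is sum(w_i v_i) / sum(w_i) with w_i = d_i**(-power)
    over the k nearest points; a cell coinciding with a station takes the
    station's value exactly. Distances are planar in degrees by default
    (``metric="haversine"`` for great-circle km).
    """
    pts = np.asarray([(p[0], p[1]) for p in points], dtype=float)
    vals = np.asarray([p[2] for p in points], dtype=float)
    if len(pts) < k_neighbors:
        raise ConfigurationError(
            f"need >= {k_neighbors} points, got {len(pts)}"
        )
    glon, glat = np.meshgrid(grid.lons, grid.lats)
    cells = np.column_stack([glon.ravel(), glat.ravel()])

    if metric == "planar":
        tree = cKDTree(pts)
        dist, idx = tree.query(cells, k=k_neighbors)
        if k_neighbors == 1:
            dist, idx = dist[:, None], idx[:, None]
    elif metric == "haversine":
        d = _haversine(
            cells[:, None, 0], cells[:, None, 1], pts[None, :, 0], pts[None, :, 1]
        )
        idx = np.argsort(d, axis=1)[:, :k_neighbors]
        dist = np.take_along_axis(d, idx, axis=1)
    else:
        raise ConfigurationError(f"unknown metric {metric!r}")

    out = np.empty(len(cells))
    exact = dist[:, 0] == 0.0
    out[exact] = vals[idx[exact, 0]]
    w = dist[~exact] ** (-power)
    out[~exact] = np.sum(w * vals[idx[~exact]], axis=1) / np.sum(w, axis=1)
    return Raster(grid, out.reshape(grid.n_lat, grid.n_lon))


def clip_for_display(
    rasters: Sequence[Raster],
    signed: bool = False,
    percentiles: tuple[float, float] = (2.0, 98.0),
) -> tuple[float, float]:
    """Shared color-bar limits pooled over all rasters' finite cells.

    Unsigned: (p2, p98). Signed: (-M, +M) with M = max(|p2|, |p98|) so
    the scale is centered on zero.
    """
    if not rasters:
        raise DataError("no rasters supplied")
    pooled = np.concatenate([r.values.ravel() for r in rasters])
    pooled = pooled[np.isfinite(pooled)]
    if pooled.size == 0:
        raise DataError("all cells are nodata")
    lo, hi = np.percentile(pooled, percentiles)
    if signed:
        m = max(abs(lo), abs(hi))
        return (-float(m), float(m))
    return (float(lo), float(hi))
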