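"""Ordinary kriging of per-island statistics onto regular lat/lon grids.

Diversity or age values observed at island coordinates are interpolated
into continuous surfaces with ordinary kriging under a linear variogram
(gamma(h) = slope * h, nugget 0) — the convention of the classic
gridding tools used for such maps.  Kriging with a zero nugget is an
exact interpolator: the surface passes through every data point.
Coordinates are treated as planar Euclidean degrees by default (again
matching the classic tools at Pacific scale); great-circle distances
are available behind a flag.  Longitudes are expected on a continuous
scale (use 0-360 across the dateline).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np

logger = logging.getLogger(__name__)

EARTH_RADIUS_KM = 6371.0


class DegenerateInputError(ValueError):
    """All points share one location: the kriging system is singular."""


@dataclass(frozen=True)
class GeoPoint:
    island: str
    lat: float
    lon: float
    value: float

    def __post_init__(self):
        if not (np.isfinite(self.lat) and np.isfinite(self.lon) and np.isfinite(self.value)):
            raise ValueError(f"non-finite GeoPoint for {self.island!r}")


@dataclass
class GeoSurface:
    lons: np.ndarray  # 1-D grid longitudes
    lats: np.ndarray  # 1-D grid latitudes
    values: np.ndarray  # shape (len(lats), len(lons))
    method: str = "ordinary-kriging-linear"

    def at(self, lat: float, lon: float) -> float:
        i = int(np.argmin(np.abs(self.lats - lat)))
        j = int(np.argmin(np.abs(self.lons - lon)))
        return float(self.values[i, j])

    def to_csv(self, path) -> None:
        import pandas as pd

        rows = [
            {"lat": la, "lon": lo, "value": self.values[i, j]}
            for i, la in enumerate(self.lats)
            for j, lo in enumerate(self.lons)
        ]
        pd.DataFrame(rows).to_csv(path, index=False, float_format="%.6f")

    def to_surfer_grd(self, path) -> None:
        """Surfer-compatible ASCII grid (DSAA)."""
        z = self.values
        with open(path, "w") as fh:
            fh.write("DSAA\n")
            fh.write(f"{len(self.lons)} {len(self.lats)}\n")
            fh.write(f"{self.lons.min():.6f} {self.lons.max():.6f}\n")
            fh.write(f"{self.lats.min():.6f} {self.lats.max():.6f}\n")
            zmin = np.nanmin(z)
            zmax = np.nanmax(z)
            fh.write(f"{zmin:.6f} {zmax:.6f}\n")
            for row in z:
                fh.write(" ".join(f"{v:.6f}" for v in row) + "\n")


def _distances(a: np.ndarray, b: np.ndarray, great_circle: bool) -> np.ndarray:
    """Pairwise distances between rows of (lat, lon) arrays."""
    if not great_circle:
        d = a[:, None, :] - b[None, :, :]
        return np.sqrt((d ** 2).sum(axis=-1))
    lat1 = np.radians(a[:, 0])[:, None]
    lat2 = np.radians(b[:, 0])[None, :]
    dlat = lat2 - lat1
    dlon = np.radians(b[:, 1])[None, :] - np.radians(a[:, 1])[:, None]
    h = np.sin(dlat / 2) ** 2 + np.cos(lat1) * np.cos(lat2) * np.sin(dlon / 2) ** 2
    return 2 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(np.clip(h, 0, 1)))


def _average_duplicates(points: Sequence[GeoPoint]) -> list[GeoPoint]:
    by_coord: dict[tuple[float, float], list[GeoPoint]] = {}
    for p in points:
        by_coord.setdefault((p.lat, p.lon), []).append(p)
    out = []
    for (lat, lon), group in sorted(by_coord.items()):
        value = float(np.mean([p.value for p in group]))
        out.append(GeoPoint(group[0].island, lat, lon, value))
    return out


def krige(
    points: Sequence[GeoPoint],
    grid_spec: tuple[float, float, float, float, float] | None = None,
    variogram: str = "linear",
    slope: float = 1.0,
    great_circle: bool = False,
) -> GeoSurface:
    """Ordinary kriging of *points* onto a regular grid.

    ``grid_spec`` is (lon_min, lon_max, lat_min, lat_max, resolution);
    the default covers the data's bounding box padded by 2 degrees at
    0.5 degree resolution.  Only the linear variogram is supported.
    """
    if variogram != "linear":
        raise ValueError("only the linear variogram is supported")
    if not points:
        raise ValueError("krige requires at least one point")
    n_input = len(points)
    points = _average_duplicates(points)
    if n_input > 1 and len(points) == 1:
        raise DegenerateInputError("all points at one location")

    if grid_spec is None:
        lons = np.array([p.lon for p in points])
        lats = np.array([p.lat for p in points])
        grid_spec = (
            lons.min() - 2.0, lons.max() + 2.0,
            lats.min() - 2.0, lats.max() + 2.0, 0.5,
        )
    lon_min, lon_max, lat_min, lat_max, res = grid_spec
    glons = np.arange(lon_min, lon_max + res / 2, res)
    glats = np.arange(lat_min, lat_max + res / 2, res)

    values = np.array([p.value for p in points])
    if len(points) == 1:
        surf = np.full((len(glats), len(glons)), values[0])
        return GeoSurface(glons, glats, surf)

    coords = np.array([[p.lat, p.lon] for p in points])
    d = _distances(coords, coords, great_circle)
    if np.all(d[np.triu_indices(len(points), 1)] == 0):
        raise DegenerateInputError("all points at one location")

    n = len(points)
    # ordinary kriging system with gamma(h) = slope * h
    A = np.empty((n + 1, n + 1))
    A[:n, :n] = slope * d
    A[n, :n] = 1.0
    A[:n, n] = 1.0
    A[n, n] = 0.0

    gl, gg = np.meshgrid(glats, glons, indexing="ij")
    targets = np.column_stack([gl.ravel(), gg.ravel()])
    d0 = slope * _distances(coords, targets, great_circle)
    rhs = np.vstack([d0, np.ones(targets.shape[0])])
    lam = np.linalg.solve(A, rhs)  # (n+1, n_targets)
    pred = values @ lam[:n]
    return GeoSurface(glons, glats, pred.reshape(len(glats), len(glons)))


def exclude_outliers(
    points: Sequence[GeoPoint], exclusions: Sequence[str] = ("New Britain",)
) -> list[GeoPoint]:
    """Drop islands named in *exclusions* (e.g. heavy-drift outliers)."""
    present = {p.island for p in points}
    for name in exclusions:
        if name not in present:
            logger.info("exclude_outliers: %r not present; no-op", name)
        else:
            logger.info("exclude_outliers: removed %r", name)
    return [p for p in points if p.island not in set(exclusions)]
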