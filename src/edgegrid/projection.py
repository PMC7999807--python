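"""Equal-area projection and analysis-grid conventions.

All areal quantities (EOO, AOO, grid cells) are computed in an equal-area
plane. The projection is a spherical Lambert azimuthal equal-area (LAEA) on
the authalic sphere of WGS84, centred by default on the centroid of the
occurrence data; the sphere radius is chosen so that areas match the
ellipsoid's total area, and local areal distortion against the ellipsoid
stays well below 0.5% at mid latitudes.

Grid cells are half-open squares [x0+i*s, x0+(i+1)*s) x [y0+j*s, y0+(j+1)*s)
so that every point belongs to exactly one cell. Three cell sizes are used:
2 km for AOO (IUCN standard), 10 km for location counting, 5 km for the
mapping/hotspot grid.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: WGS84 authalic sphere radius in metres (equal-area sphere of the ellipsoid).
AUTHALIC_RADIUS_M = 6_371_007.181


@dataclass(frozen=True)
class LambertAzimuthalEqualArea:
    """Spherical LAEA projection centred at (lon0, lat0), metres output."""

    lon0: float
    lat0: float
    radius_m: float = AUTHALIC_RADIUS_M

    def forward(self, lon, lat):
        """Project lon/lat degrees to (x, y) metres. Vectorised."""
        lam = np.radians(np.asarray(lon, dtype=float) - self.lon0)
        phi = np.radians(np.asarray(lat, dtype=float))
        phi0 = np.radians(self.lat0)
        denom = 1.0 + np.sin(phi0) * np.sin(phi) + np.cos(phi0) * np.cos(phi) * np.cos(lam)
        k = np.sqrt(2.0 / denom)
        x = self.radius_m * k * np.cos(phi) * np.sin(lam)
        y = self.radius_m * k * (np.cos(phi0) * np.sin(phi) - np.sin(phi0) * np.cos(phi) * np.cos(lam))
        return x, y

    def inverse(self, x, y):
        """Unproject (x, y) metres back to lon/lat degrees. Vectorised."""
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        phi0 = np.radians(self.lat0)
        rho = np.hypot(x, y)
        c = 2.0 * np.arcsin(np.clip(rho / (2.0 * self.radius_m), -1.0, 1.0))
        with np.errstate(invalid="ignore"):
            sin_phi = np.cos(c) * np.sin(phi0) + np.where(rho > 0, y * np.sin(c) * np.cos(phi0) / rho, 0.0)
        phi = np.arcsin(np.clip(sin_phi, -1.0, 1.0))
        lam = np.arctan2(
            x * np.sin(c),
            rho * np.cos(phi0) * np.cos(c) - y * np.sin(phi0) * np.sin(c),
        )
        lam = np.where(rho > 0, lam, 0.0)
        return self.lon0 + np.degrees(lam), np.degrees(phi)


@dataclass(frozen=True)
class ProjectionSpec:
    """Projection plus grid-origin and cell-size conventions.

    ``aoo_cell_m`` (default 2000 m) is the IUCN-standard AOO cell;
    ``location_cell_m`` (default 10000 m) approximates IUCN "locations";
    ``map_cell_m`` (default 5000 m) is the richness/EDGE mapping grid.
    The grid origin defaults to the projection origin (0, 0).
    """

    projection: LambertAzimuthalEqualArea
    origin: tuple[float, float] = (0.0, 0.0)
    aoo_cell_m: float = 2000.0
    location_cell_m: float = 10000.0
    map_cell_m: float = 5000.0

    def __post_init__(self):
        for s in (self.aoo_cell_m, self.location_cell_m, self.map_cell_m):
            if s <= 0:
                raise ValueError("cell sizes must be positive")

    def cell_index(self, x, y, cell_m: float):
        """Half-open grid binning: (i, j) integer indices for points in metres."""
        x0, y0 = self.origin
        i = np.floor((np.asarray(x, dtype=float) - x0) / cell_m).astype(np.int64)
        j = np.floor((np.asarray(y, dtype=float) - y0) / cell_m).astype(np.int64)
        return i, j

    def cell_bounds(self, i: int, j: int, cell_m: float) -> tuple[float, float, float, float]:
        """(xmin, ymin, xmax, ymax) of cell (i, j) in metres."""
        x0, y0 = self.origin
        return (x0 + i * cell_m, y0 + j * cell_m, x0 + (i + 1) * cell_m, y0 + (j + 1) * cell_m)


def projection_for_records(lons, lats) -> LambertAzimuthalEqualArea:
    """Default projection: LAEA centred on the coordinate centroid."""
    return LambertAzimuthalEqualArea(lon0=float(np.mean(lons)), lat0=float(np.mean(lats)))


def occupied_cells(points_xy: np.ndarray, spec: ProjectionSpec, cell_m: float) -> set[tuple[int, int]]:
    """Set of (i, j) grid cells occupied by >=1 projected point."""
    if len(points_xy) == 0:
        return set()
    i, j = spec.cell_index(points_xy[:, 0], points_xy[:, 1], cell_m)
    return set(zip(i.tolist(), j.tolist()))
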