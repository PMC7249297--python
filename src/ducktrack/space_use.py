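"""Kernel utilization distributions (UDs) and probability contours.

A fixed bivariate-normal kernel density is estimated on a projected plane
(local azimuthal equidistant about the point centroid by default, or
plate-carree), with the "ad hoc" reference bandwidth

    h = sqrt((var_x + var_y) / 2) * n^(-1/6)

on a square grid of ``grid_cells`` cells per axis over the padded point
bounding box. Contours for a percentage level are the smallest
density-threshold region containing that share of total mass, exported as
polygons in geographic coordinates (GeoJSON-ready). 25/50/75% levels mirror
the conventional core-to-broad use areas.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from shapely.geometry import MultiPolygon, Polygon, mapping
from skimage import measure

from . import geo
from .sensor_io import KDEParams


class DegenerateBandwidthError(ValueError):
    pass


@dataclass
class UtilizationDistribution:
    """KDE surface on a projected grid plus cached contour polygons."""

    x: np.ndarray                         # grid cell-centre coords, km (nx,)
    y: np.ndarray
    density: np.ndarray                   # (ny, nx), integrates to 1
    bandwidth_km: float
    cell_area_km2: float
    projection: str
    origin: tuple                         # (lon0, lat0) of the projection
    contours: dict = field(default_factory=dict)   # level -> [Polygon] (lon/lat)

    def total_mass(self) -> float:
        return float(self.density.sum() * self.cell_area_km2)

    def to_geographic(self, x, y):
        if self.projection == "platecarree":
            lon0, lat0 = self.origin
            lon = lon0 + np.asarray(x) / (geo.KM_PER_DEG * np.cos(np.radians(lat0)))
            lat = lat0 + np.asarray(y) / geo.KM_PER_DEG
            return lon, lat
        return geo.aeqd_inverse(x, y, *self.origin)

    def contains(self, level: int, lon, lat) -> bool:
        """Whether a geographic point falls inside the level% contour
        (contour polygons are stored in geographic coordinates)."""
        from shapely.geometry import Point
        pt = Point(float(lon), float(lat))
        return any(pg.contains(pt) for pg in self.contours[level])

    def contour_area_km2(self, level: int) -> float:
        """Area of the level% region, from the density grid (km^2)."""
        thr = self._threshold_for(level)
        return float(np.sum(self.density >= thr) * self.cell_area_km2)

    def mass_above_threshold(self, level: int) -> float:
        thr = self._threshold_for(level)
        return float(self.density[self.density >= thr].sum() * self.cell_area_km2)

    def _threshold_for(self, level: int) -> float:
        flat = np.sort(self.density.ravel())[::-1]
        cum = np.cumsum(flat) * self.cell_area_km2
        k = int(np.searchsorted(cum, level / 100.0))
        return flat[min(k, flat.size - 1)]

    def contours_geojson(self) -> dict:
        feats = []
        for level, polys in sorted(self.contours.items()):
            geom = MultiPolygon(polys) if len(polys) != 1 else polys[0]
            feats.append({
                "type": "Feature",
                "properties": {"level_pct": int(level)},
                "geometry": mapping(geom),
            })
        return {"type": "FeatureCollection", "features": feats}


def kernel_ud(lons, lats, params: KDEParams | None = None,
              weights=None) -> UtilizationDistribution:
    """Kernel UD of a geographic point set.

    Needs >= 5 points; identical points raise a degenerate-bandwidth error
    suggesting a manual ``params.bandwidth``.
    """
    params = params or KDEParams()
    lons = np.asarray(lons, dtype=float)
    lats = np.asarray(lats, dtype=float)
    if lons.size < 5:
        raise ValueError("kernel_ud needs at least 5 points")
    if weights is None:
        weights = np.ones_like(lons)
    weights = np.asarray(weights, dtype=float)
    weights = weights / weights.sum()

    lon0 = float(np.median(lons))
    lat0 = float(np.median(lats))
    if params.projection == "platecarree":
        x = (lons - lon0) * geo.KM_PER_DEG * np.cos(np.radians(lat0))
        y = (lats - lat0) * geo.KM_PER_DEG
    else:
        x, y = geo.aeqd_forward(lons, lats, lon0, lat0)

    if isinstance(params.bandwidth, str):
        if params.bandwidth != "adhoc":
            raise ValueError(f"unknown bandwidth rule {params.bandwidth!r}")
        var = 0.5 * (np.var(x) + np.var(y))
        h = float(np.sqrt(var) * lons.size ** (-1.0 / 6.0))
    else:
        h = float(params.bandwidth)
    if h <= 1e-9:
        raise DegenerateBandwidthError(
            "all points identical; pass a manual bandwidth")

    pad = 3.5 * h
    gx = np.linspace(x.min() - pad, x.max() + pad, params.grid_cells)
    gy = np.linspace(y.min() - pad, y.max() + pad, params.grid_cells)
    dens = _gaussian_kde_grid(x, y, weights, gx, gy, h)
    cell_area = (gx[1] - gx[0]) * (gy[1] - gy[0])
    dens = dens / (dens.sum() * cell_area)

    ud = UtilizationDistribution(gx, gy, dens, h, cell_area,
                                 params.projection, (lon0, lat0))
    for level in params.levels:
        ud.contours[int(level)] = ud_contour(ud, level)
    return ud


def _gaussian_kde_grid(x, y, w, gx, gy, h):
    """Isotropic Gaussian KDE evaluated on a separable grid."""
    # (ny, n) and (nx, n) kernels combined -> O(n * cells) via outer products
    kx = np.exp(-0.5 * ((gx[:, None] - x[None, :]) / h) ** 2)
    ky = np.exp(-0.5 * ((gy[:, None] - y[None, :]) / h) ** 2)
    dens = ky @ (w[:, None] * kx.T)       # (ny, nx)
    return dens / (2 * np.pi * h ** 2)


def ud_contour(ud: UtilizationDistribution, level: float) -> list:
    """Polygons of the smallest region holding ``level``% of total mass.

    Well-separated modes may yield several disjoint polygons; all are
    returned, in geographic coordinates.
    """
    if not (0 < level < 100):
        raise ValueError("contour level must be in (0, 100)")
    thr = ud._threshold_for(level)
    dx = ud.x[1] - ud.x[0]
    dy = ud.y[1] - ud.y[0]
    polys = []
    for ring in measure.find_contours(ud.density, thr):
        if len(ring) < 4:
            continue
        px = ud.x[0] + ring[:, 1] * dx    # ring columns are (row, col)
        py = ud.y[0] + ring[:, 0] * dy
        plon, plat = ud.to_geographic(px, py)
        poly = Polygon(np.column_stack([plon, plat]))
        if poly.is_valid and poly.area > 0:
            polys.append(poly)
    # drop holes' duplicates: keep outer shells, subtract contained rings
    outers = []
    for pg in polys:
        hole_of = [q for q in polys if q is not pg and q.contains(pg)]
        if not hole_of:
            outers.append(pg)
    return outers if outers else polys


def points_in_level(ud: UtilizationDistribution, level: int,
                    lons, lats) -> np.ndarray:
    """Vectorized membership of geographic points in the level% region,
    evaluated on the density grid (cheaper than polygon tests)."""
    thr = ud._threshold_for(level)
    if ud.projection == "platecarree":
        lon0, lat0 = ud.origin
        px = (np.asarray(lons) - lon0) * geo.KM_PER_DEG * np.cos(np.radians(lat0))
        py = (np.asarray(lats) - lat0) * geo.KM_PER_DEG
    else:
        px, py = geo.aeqd_forward(lons, lats, *ud.origin)
    ix = np.clip(np.searchsorted(ud.x, px), 0, ud.x.size - 1)
    iy = np.clip(np.searchsorted(ud.y, py), 0, ud.y.size - 1)
    inside = (px >= ud.x[0]) & (px <= ud.x[-1]) & (py >= ud.y[0]) & (py <= ud.y[-1])
    return inside & (ud.density[iy, ix] >= thr)
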