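"""Small spherical-geometry helpers shared across the pipeline.

All angles are decimal degrees on WGS84 (treated as a sphere of mean radius
``EARTH_RADIUS_KM``), longitudes positive east and normalized to [-180, 180).
"""

from __future__ import annotations

import numpy as np

EARTH_RADIUS_KM = 6371.0088
KM_PER_DEG = 2 * np.pi * EARTH_RADIUS_KM / 360.0  # ~111.195 km


def normalize_lon(lon):
    """Wrap longitudes into [-180, 180)."""
    return (np.asarray(lon, dtype=float) + 180.0) % 360.0 - 180.0


def haversine_km(lon1, lat1, lon2, lat2):
    """Great-circle distance in km between points (vectorized)."""
    lon1, lat1, lon2, lat2 = (np.radians(np.asarray(a, dtype=float))
                              for a in (lon1, lat1, lon2, lat2))
    dlat = lat2 - lat1
    dlon = lon2 - lon1
    a = np.sin(dlat / 2) ** 2 + np.cos(lat1) * np.cos(lat2) * np.sin(dlon / 2) ** 2
    return 2 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(np.clip(a, 0.0, 1.0)))


def track_length_km(lons, lats):
    """Summed great-circle length of a polyline; 0 for fewer than 2 points."""
    lons = np.asarray(lons, dtype=float)
    lats = np.asarray(lats, dtype=float)
    if lons.size < 2:
        return 0.0
    return float(np.sum(haversine_km(lons[:-1], lats[:-1], lons[1:], lats[1:])))


def to_unit_vectors(lon, lat):
    """(lon, lat) degrees -> unit vectors, shape (..., 3)."""
    lam = np.radians(np.asarray(lon, dtype=float))
    phi = np.radians(np.asarray(lat, dtype=float))
    return np.stack([np.cos(phi) * np.cos(lam),
                     np.cos(phi) * np.sin(lam),
                     np.sin(phi)], axis=-1)


def from_unit_vectors(v):
    """Unit vectors (..., 3) -> (lon, lat) degrees."""
    v = np.asarray(v, dtype=float)
    lon = np.degrees(np.arctan2(v[..., 1], v[..., 0]))
    lat = np.degrees(np.arcsin(np.clip(v[..., 2], -1.0, 1.0)))
    return normalize_lon(lon), lat


def slerp(lon1, lat1, lon2, lat2, frac):
    """Point(s) a fraction ``frac`` along the great circle from p1 to p2."""
    p1 = to_unit_vectors(lon1, lat1)
    p2 = to_unit_vectors(lon2, lat2)
    omega = np.arccos(np.clip(np.dot(p1, p2), -1.0, 1.0))
    frac = np.asarray(frac, dtype=float)
    if omega < 1e-12:
        v = np.broadcast_to(p1, frac.shape + (3,)) if frac.ndim else p1
        return from_unit_vectors(v)
    s = np.sin(omega)
    a = np.sin((1.0 - frac) * omega) / s
    b = np.sin(frac * omega) / s
    v = a[..., None] * p1 + b[..., None] * p2
    v = v / np.linalg.norm(v, axis=-1, keepdims=True)
    return from_unit_vectors(v)


def aeqd_forward(lon, lat, lon0, lat0):
    """Azimuthal equidistant projection about (lon0, lat0), returns km (x, y)."""
    lam = np.radians(normalize_lon(np.asarray(lon, dtype=float) - lon0))
    phi = np.radians(np.asarray(lat, dtype=float))
    phi0 = np.radians(lat0)
    cos_c = np.sin(phi0) * np.sin(phi) + np.cos(phi0) * np.cos(phi) * np.cos(lam)
    c = np.arccos(np.clip(cos_c, -1.0, 1.0))
    sin_c = np.sin(c)
    with np.errstate(invalid="ignore", divide="ignore"):
        k = np.where(sin_c > 1e-12, c / np.where(sin_c > 1e-12, sin_c, 1.0), 1.0)
    x = EARTH_RADIUS_KM * k * np.cos(phi) * np.sin(lam)
    y = EARTH_RADIUS_KM * k * (np.cos(phi0) * np.sin(phi)
                               - np.sin(phi0) * np.cos(phi) * np.cos(lam))
    return x, y


def aeqd_inverse(x, y, lon0, lat0):
    """Inverse azimuthal equidistant projection; input km, output degrees."""
    x = np.asarray(x, dtype=float) / EARTH_RADIUS_KM
    y = np.asarray(y, dtype=float) / EARTH_RADIUS_KM
    c = np.sqrt(x ** 2 + y ** 2)
    phi0 = np.radians(lat0)
    with np.errstate(invalid="ignore", divide="ignore"):
        safe_c = np.where(c > 1e-12, c, 1.0)
        phi = np.where(
            c > 1e-12,
            np.arcsin(np.clip(np.cos(c) * np.sin(phi0)
                              + y * np.sin(c) * np.cos(phi0) / safe_c, -1.0, 1.0)),
            phi0,
        )
        lam = np.where(
            c > 1e-12,
            np.arctan2(x * np.sin(c),
                       safe_c * np.cos(phi0) * np.cos(c) - y * np.sin(phi0) * np.sin(c)),
            0.0,
        )
    return normalize_lon(lon0 + np.degrees(lam)), np.degrees(phi)


def destination(lon, lat, bearing_deg, dist_km):
    """Destination point given start, initial bearing and distance."""
    phi1 = np.radians(np.asarray(lat, dtype=float))
    lam1 = np.radians(np.asarray(lon, dtype=float))
    theta = np.radians(np.asarray(bearing_deg, dtype=float))
    delta = np.asarray(dist_km, dtype=float) / EARTH_RADIUS_KM
    phi2 = np.arcsin(np.sin(phi1) * np.cos(delta)
                     + np.cos(phi1) * np.sin(delta) * np.cos(theta))
    lam2 = lam1 + np.arctan2(np.sin(theta) * np.sin(delta) * np.cos(phi1),
                             np.cos(delta) - np.sin(phi1) * np.sin(phi2))
    return normalize_lon(np.degrees(lam2)), np.degrees(phi2)
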