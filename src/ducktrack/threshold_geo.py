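"""Threshold-method light-level geolocation.

Positions are derived from sunrise/sunset pairs: longitude from the timing of
local solar noon (or midnight for night/polar pairs), latitude by inverting
the day-length equation at a calibrated sun-elevation angle. Three calibration
schemes for that angle are provided: known-site ("rooftop") calibration, a
fixed angle, and Hill-Ekstrom calibration (latitude-variance minimization over
a stationary period).

Solar geometry follows the NOAA/Meeus low-precision formulas (declination,
equation of time), accurate to well under 0.1 degree over the satellite-tag
era, which is far below the intrinsic noise of threshold geolocation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .geo import normalize_lon

LAT_FLAG_OK = "ok"
LAT_FLAG_EQUINOX = "equinox_undefined"
LAT_FLAG_POLAR = "polar_undefined"

#: latitude search bounds for the day-length inversion
LAT_BOUNDS = (-85.0, 85.0)
#: |day-length residual| above which latitude is declared undefined (minutes)
RESIDUAL_LIMIT_MIN = 10.0


def _unix_seconds(times) -> np.ndarray:
    """UTC timestamps (pandas/np/str) -> seconds since the Unix epoch."""
    idx = pd.DatetimeIndex(pd.to_datetime(np.atleast_1d(times), utc=True))
    return idx.view("int64").astype(float) / 1e9


def solar_ephemeris(times):
    """Solar declination (deg) and equation of time (minutes) at UTC times."""
    t = _unix_seconds(times)
    jc = (t / 86400.0 + 2440587.5 - 2451545.0) / 36525.0

    l0 = np.remainder(280.46646 + jc * (36000.76983 + 0.0003032 * jc), 360.0)
    m = np.radians(357.52911 + jc * (35999.05029 - 0.0001537 * jc))
    ecc = 0.016708634 - jc * (0.000042037 + 0.0000001267 * jc)
    c = (np.sin(m) * (1.914602 - jc * (0.004817 + 0.000014 * jc))
         + np.sin(2 * m) * (0.019993 - 0.000101 * jc)
         + np.sin(3 * m) * 0.000289)
    true_lon = l0 + c
    omega = np.radians(125.04 - 1934.136 * jc)
    app_lon = np.radians(true_lon - 0.00569 - 0.00478 * np.sin(omega))

    eps0 = 23.0 + (26.0 + (21.448 - jc * (46.815 + jc * (0.00059 - 0.001813 * jc))) / 60.0) / 60.0
    eps = np.radians(eps0 + 0.00256 * np.cos(omega))

    dec = np.degrees(np.arcsin(np.sin(eps) * np.sin(app_lon)))

    y = np.tan(eps / 2.0) ** 2
    l0r = np.radians(l0)
    eot = 4.0 * np.degrees(
        y * np.sin(2 * l0r) - 2.0 * ecc * np.sin(m)
        + 4.0 * ecc * y * np.sin(m) * np.cos(2 * l0r)
        - 0.5 * y ** 2 * np.sin(4 * l0r) - 1.25 * ecc ** 2 * np.sin(2 * m)
    )
    return dec, eot


def solar_position(times, lon, lat):
    """Solar elevation and azimuth (degrees) at UTC times and location(s).

    Elevation is geometric (no atmospheric refraction): the sun-elevation
    angle of threshold geolocation is an empirical constant that absorbs
    refraction, sensor response and habitat shading.
    """
    t = _unix_seconds(times)
    dec, eot = solar_ephemeris(times)
    lon = np.asarray(lon, dtype=float)
    lat = np.asarray(lat, dtype=float)

    minutes_utc = np.remainder(t, 86400.0) / 60.0
    tst = np.remainder(minutes_utc + eot + 4.0 * lon, 1440.0)
    ha = np.radians(tst / 4.0 - 180.0)
    phi = np.radians(lat)
    decr = np.radians(dec)

    sin_elev = np.sin(phi) * np.sin(decr) + np.cos(phi) * np.cos(decr) * np.cos(ha)
    elev = np.degrees(np.arcsin(np.clip(sin_elev, -1.0, 1.0)))

    cos_elev = np.cos(np.radians(elev))
    with np.errstate(invalid="ignore", divide="ignore"):
        cos_az = (np.sin(decr) - np.sin(phi) * sin_elev) / np.where(
            np.abs(np.cos(phi) * cos_elev) > 1e-12, np.cos(phi) * cos_elev, 1.0)
    az = np.degrees(np.arccos(np.clip(cos_az, -1.0, 1.0)))
    az = np.where(ha > 0, 360.0 - az, az)
    if np.ndim(times) == 0 and np.ndim(lon) == 0:
        return float(elev[0]), float(az[0])
    return elev, az


def day_length_hours(lat, dec, angle):
    """Modelled day length (h) between threshold crossings at ``angle``.

    Returns 0 for polar night and 24 for polar day. Vectorized over ``lat``.
    """
    phi = np.radians(np.asarray(lat, dtype=float))
    decr = np.radians(np.asarray(dec, dtype=float))
    a = np.radians(angle)
    with np.errstate(invalid="ignore", divide="ignore"):
        cos_h0 = (np.sin(a) - np.sin(phi) * np.sin(decr)) / (np.cos(phi) * np.cos(decr))
    h0 = np.degrees(np.arccos(np.clip(cos_h0, -1.0, 1.0)))
    return 2.0 * h0 / 15.0


def latitude_from_day_length(observed_hours, dec, angle):
    """Invert day length -> latitude by bounded root search.

    For a negative sun-elevation angle near the equinoxes the day-length
    profile is U-shaped in latitude (24-h "day" at both poles at the chosen
    angle), so two mirror solutions can exist; the northern branch is
    returned, matching the Arctic-breeding domain of the analysis.

    Returns ``(lat, residual_minutes)``; ``lat`` is NaN when no latitude in
    [-85, 85] reproduces the observed day length to within 10 minutes (the
    near-equinox / polar degeneracies) or the profile is flat (latitude
    unidentifiable).
    """
    lo, hi = LAT_BOUNDS
    grid = np.linspace(lo, hi, 341)
    prof = day_length_hours(grid, dec, angle)
    # flat profile: latitude unidentifiable
    if float(np.ptp(prof)) < 2.0 / 60.0:
        return np.nan, float(abs(prof[0] - observed_hours)) * 60.0

    def f(lat):
        return day_length_hours(lat, dec, angle) - observed_hours

    i0 = int(np.argmin(prof))
    u_shaped = (0 < i0 < len(grid) - 1
                and prof[i0] < prof[0] - 1e-9 and prof[i0] < prof[-1] - 1e-9)
    if u_shaped:
        b_lo, b_hi = float(grid[i0]), hi          # northern branch
        bprof = prof[i0:]
        boff = i0
    else:
        b_lo, b_hi = lo, hi
        bprof = prof
        boff = 0
    flo, fhi = f(b_lo), f(b_hi)
    if flo * fhi < 0:
        lat = brentq(f, b_lo, b_hi, xtol=1e-5)
        resid = abs(f(lat)) * 60.0
    else:
        # no sign change on the branch: report the best branch point
        j = int(np.argmin(np.abs(bprof - observed_hours)))
        lat = float(grid[boff + j])
        resid = abs(f(lat)) * 60.0
    if resid > RESIDUAL_LIMIT_MIN:
        return np.nan, float(resid)
    # identifiability: if day length barely moves with latitude at the
    # solution (deep equinox, shallow angle), the fit is meaningless
    l1, l2 = max(lat - 1.0, lo), min(lat + 1.0, hi)
    sens_min_per_deg = abs(float(day_length_hours(l2, dec, angle))
                           - float(day_length_hours(l1, dec, angle))) \
        / (l2 - l1) * 60.0
    if sens_min_per_deg < 0.5:
        return np.nan, float(resid)
    return float(lat), float(resid)


def longitude_from_transit(transit_time, transit="noon"):
    """Longitude from the UTC time of local solar noon or midnight."""
    t = _unix_seconds(transit_time)[0]
    _, eot = solar_ephemeris(transit_time)
    hours_utc = np.remainder(t, 86400.0) / 3600.0
    offset = 12.0 if transit == "noon" else 0.0
    return float(normalize_lon(15.0 * (offset - hours_utc - eot[0] / 60.0)))


def position_from_pair(sunrise, sunset, angle, polar_day=False):
    """Threshold-method position from one twilight pair.

    A sunrise-before-sunset pair is a day pair: longitude from the timing of
    local solar noon, latitude from the day length. A sunset-before-sunrise
    pair is a night pair, handled symmetrically (longitude from local
    midnight, day length = 24 h - night length). ``polar_day`` pairs carry
    longitude only (both events at the estimated midnight).

    Returns a dict with time (pair midpoint), lon, lat, lat_flag.
    """
    sr = pd.Timestamp(sunrise)
    ss = pd.Timestamp(sunset)
    t1, t2 = (sr, ss) if sr <= ss else (ss, sr)
    span_h = (t2 - t1).total_seconds() / 3600.0
    if span_h > 24.0:
        raise ValueError(f"twilight pair spans {span_h:.1f} h > 24 h")
    mid = t1 + (t2 - t1) / 2

    if polar_day:
        lon = longitude_from_transit(mid, transit="midnight")
        return {"time": mid, "lon": lon, "lat": np.nan, "lat_flag": LAT_FLAG_POLAR}

    dec, _ = solar_ephemeris(mid)
    if sr <= ss:                         # day pair
        lon = longitude_from_transit(mid, transit="noon")
        obs_day = span_h
    else:                                # night pair
        lon = longitude_from_transit(mid, transit="midnight")
        obs_day = 24.0 - span_h
    lat, resid = latitude_from_day_length(obs_day, float(dec[0]), angle)
    flag = LAT_FLAG_OK if np.isfinite(lat) else LAT_FLAG_EQUINOX
    return {"time": mid, "lon": lon, "lat": lat if np.isfinite(lat) else np.nan,
            "lat_flag": flag, "residual_min": resid}


def twilight_pairs(twilights: pd.DataFrame) -> pd.DataFrame:
    """Pair consecutive twilight events.

    Consecutive sunrise->sunset events form day pairs and sunset->sunrise
    events night pairs; every adjacent pair closer than 24 h yields one
    entry, so a full day contributes up to two. Polar-day sunrise+sunset
    events at the same estimated midnight form one 'polar' pair.

    Returns columns pair_id, kind ('day'/'night'/'polar'), t_first, t_second,
    time (midpoint), day_length_h (NaN for polar pairs).
    """
    tw = twilights.sort_values("time", kind="stable").reset_index(drop=True)
    rows = []
    pair_id = 0
    used_polar = set()
    for i in range(len(tw) - 1):
        a, b = tw.iloc[i], tw.iloc[i + 1]
        ta, tb = pd.Timestamp(a.time), pd.Timestamp(b.time)
        if bool(a.polar_day) and bool(b.polar_day) and ta == tb:
            if ta in used_polar:
                continue
            used_polar.add(ta)
            rows.append((pair_id, "polar", ta, tb, ta, np.nan))
            pair_id += 1
            continue
        if bool(a.polar_day) or bool(b.polar_day) or a.kind == b.kind:
            continue
        span_h = (tb - ta).total_seconds() / 3600.0
        if span_h >= 24.0 or span_h <= 0:
            continue
        mid = ta + (tb - ta) / 2
        if a.kind == "sunrise":
            rows.append((pair_id, "day", ta, tb, mid, span_h))
        else:
            rows.append((pair_id, "night", ta, tb, mid, 24.0 - span_h))
        pair_id += 1
    return pd.DataFrame(rows, columns=["pair_id", "kind", "t_first",
                                       "t_second", "time", "day_length_h"])


def positions_from_twilights(twilights: pd.DataFrame, angle: float,
                             method: str = "threshold") -> pd.DataFrame:
    """Threshold-method positions for every usable twilight pair.

    ``twilights`` must have columns time, kind ('sunrise'/'sunset'), quality,
    polar_day (see :mod:`ducktrack.twilights`).
    """
    pairs = twilight_pairs(twilights)
    rows = []
    for p in pairs.itertuples():
        if p.kind == "polar":
            lon = longitude_from_transit(p.time, transit="midnight")
            rows.append((p.pair_id, p.time, lon, np.nan, LAT_FLAG_POLAR, method))
            continue
        dec, _ = solar_ephemeris(p.time)
        transit = "noon" if p.kind == "day" else "midnight"
        lon = longitude_from_transit(p.time, transit=transit)
        lat, _resid = latitude_from_day_length(p.day_length_h, float(dec[0]), angle)
        flag = LAT_FLAG_OK if np.isfinite(lat) else LAT_FLAG_EQUINOX
        rows.append((p.pair_id, p.time, lon,
                     lat if np.isfinite(lat) else np.nan, flag, method))
    return pd.DataFrame(rows, columns=["pair_id", "time", "lon", "lat",
                                       "lat_flag", "method"])


@dataclass
class SunAngleCalibration:
    """A calibrated sun-elevation angle and how it was obtained."""

    method: str                      # known_site | fixed | hill_ekstrom
    angle: float                     # degrees, sun elevation at the light threshold
    window: tuple = ()               # (start, end) of the calibration window
    diagnostics: dict = field(default_factory=dict)

    def __post_init__(self):
        if not np.isfinite(self.angle):
            raise ValueError("calibration angle must be finite")


class CalibrationError(RuntimeError):
    pass


def calibrate_known_site(twilights: pd.DataFrame, lon: float, lat: float,
                         min_days: int = 7) -> SunAngleCalibration:
    """Known-site ("rooftop") calibration.

    The sun-elevation angle is the median solar elevation at the detected
    threshold crossings, evaluated at the known deployment location. Requires
    at least ``min_days`` distinct days of twilights.
    """
    tw = twilights[~twilights["polar_day"].astype(bool)]
    if tw.empty:
        raise CalibrationError("no usable twilights for known-site calibration")
    days = pd.DatetimeIndex(tw["time"]).floor("D").nunique()
    if days < min_days:
        raise CalibrationError(
            f"known-site calibration needs >= {min_days} days, got {days}")
    elev, _ = solar_position(tw["time"].values, lon, lat)
    angle = float(np.median(elev))
    return SunAngleCalibration(
        method="known_site", angle=angle,
        window=(pd.Timestamp(tw["time"].min()), pd.Timestamp(tw["time"].max())),
        diagnostics={"n_events": int(len(tw)), "n_days": int(days),
                     "elev_sd": float(np.std(elev))})


def calibrate_hill_ekstrom(twilights: pd.DataFrame, window,
                           angle_grid=None, min_days: int = 30,
                           equinox_buffer_days: int = 15) -> SunAngleCalibration:
    """Hill-Ekstrom calibration over a stationary (e.g. wintering) window.

    For every candidate angle the latitude series over the window is computed
    with the threshold method; the selected angle minimizes the latitude
    variance. The full variance-vs-angle profile is returned in diagnostics.
    The window must span >= 30 days and should exclude equinoxes +/- 15 days
    (enforced by trimming).
    """
    if angle_grid is None:
        angle_grid = np.arange(-10.0, 0.0 + 1e-9, 0.25)
    start, end = (pd.Timestamp(window[0]), pd.Timestamp(window[1]))
    tw = twilights[(twilights["time"] >= start) & (twilights["time"] < end)]
    tw = tw[~tw["polar_day"].astype(bool)]
    tw = _trim_equinox(tw, equinox_buffer_days)
    if tw.empty:
        raise CalibrationError("no twilights in the stationary window")
    span = (pd.Timestamp(tw["time"].max()) - pd.Timestamp(tw["time"].min())).days
    if span < min_days:
        raise CalibrationError(
            f"Hill-Ekstrom window spans {span} d after equinox trimming; "
            f"needs >= {min_days} d")

    variances = np.full(len(angle_grid), np.nan)
    for i, ang in enumerate(angle_grid):
        lats = positions_from_twilights(tw, ang)["lat"].dropna()
        if len(lats) >= 5:
            variances[i] = float(np.var(lats, ddof=1))
    if not np.isfinite(variances).any():
        raise CalibrationError("all candidate angles give undefined latitudes")
    best = int(np.nanargmin(variances))
    return SunAngleCalibration(
        method="hill_ekstrom", angle=float(angle_grid[best]),
        window=(start, end),
        diagnostics={"angle_grid": np.asarray(angle_grid),
                     "variance_profile": variances})


def _trim_equinox(tw: pd.DataFrame, buffer_days: int) -> pd.DataFrame:
    """Drop twilights within +/- buffer_days of an equinox (|declination| rule)."""
    if tw.empty:
        return tw
    dec, _ = solar_ephemeris(tw["time"].values)
    # declination changes ~0.4 deg/day near the equinoxes
    return tw[np.abs(dec) > 0.4 * buffer_days].reset_index(drop=True)
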