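"""Probabilistic particle track model with a conductivity/water-type term.

Per twilight pair the model (1) samples twilight-timing errors and a
sun-elevation angle from a configured band, producing candidate positions
(longitude from the perturbed transit time, latitude by inverting day
length; during equinox/polar gaps latitude is drawn from the movement prior
alone); (2) rejects candidates on land or ice; (3) weights by movement
feasibility against each particle's ancestor (truncated-lognormal speed
likelihoods, flight speeds while dry, swim/drift speeds while wet);
(4) weights by sea-surface-temperature agreement while the bird was wet and
not in fresh water; (5) weights by agreement between the logger-derived
water type (dry/fresh/brackish/sea, from conductivity and wet/dry data) and
the water-type raster - the freshwater/brackish/marine discrimination that
plain SST weighting cannot provide; and (6) resamples systematically. The
median track is the per-pair geographic (great-circle) median of the cloud.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import geo
from .sensor_io import PipelineConfig, SpeedModel, WET_SUM_MAX
from .synthetic_data import BRACKISH_SEA, LAND_FRESH, OPEN_SEA, WorldModel
from .threshold_geo import solar_ephemeris, day_length_hours, twilight_pairs

WATER_CLASSES = ("dry", "fresh", "brackish", "sea")
_CLASS_TO_CODE = {"fresh": LAND_FRESH, "brackish": BRACKISH_SEA, "sea": OPEN_SEA}

LAT_GRID = np.arange(-85.0, 85.0 + 1e-9, 0.5)
ANGLE_GRID_STEP = 0.75


class TrackError(RuntimeError):
    pass


def classify_water_type(blocks: pd.DataFrame, config: PipelineConfig) -> pd.Series:
    """Dry/fresh/brackish/sea class per sensor block.

    Rule order: dry if the wet fraction is below the dry threshold,
    regardless of conductivity; otherwise conductivity classes are
    half-open: fresh = [0, c_fresh_brackish), brackish =
    [c_fresh_brackish, c_brackish_sea), sea = [c_brackish_sea, 127].
    """
    wet_frac = blocks["wet_sum"].to_numpy(dtype=float) / WET_SUM_MAX
    cond = blocks["cond_max"].to_numpy(dtype=float)
    out = np.full(len(blocks), "sea", dtype=object)
    out[cond < config.c_brackish_sea] = "brackish"
    out[cond < config.c_fresh_brackish] = "fresh"
    out[wet_frac < config.wet_fraction_dry_threshold] = "dry"
    return pd.Series(out, index=blocks.index, name="water_class")


def geographic_median(lons, lats, weights=None, tol_km=0.1, max_iter=100):
    """Weighted geometric median on the sphere (great-circle distances).

    Weiszfeld iteration in the local tangent plane. A single point returns
    itself; for two points the minimizer is the heavier point, or the
    geodesic midpoint on equal weights (documented tie-break).
    """
    lons = np.atleast_1d(np.asarray(lons, dtype=float))
    lats = np.atleast_1d(np.asarray(lats, dtype=float))
    if lons.size == 0:
        raise ValueError("geographic_median needs at least one point")
    if weights is None:
        weights = np.ones_like(lons)
    weights = np.asarray(weights, dtype=float)
    weights = weights / weights.sum()
    if lons.size == 1:
        return float(lons[0]), float(lats[0])
    if lons.size == 2:
        if np.isclose(weights[0], weights[1]):
            lo, la = geo.slerp(lons[0], lats[0], lons[1], lats[1], np.array(0.5))
            return float(lo), float(la)
        i = int(np.argmax(weights))
        return float(lons[i]), float(lats[i])

    # start at the weighted mean direction
    v = (weights[:, None] * geo.to_unit_vectors(lons, lats)).sum(axis=0)
    v /= np.linalg.norm(v)
    cur_lon, cur_lat = geo.from_unit_vectors(v)
    for _ in range(max_iter):
        x, y = geo.aeqd_forward(lons, lats, cur_lon, cur_lat)
        d = np.hypot(x, y)
        at_point = d < 1e-9
        if at_point.any() and weights[at_point].sum() >= 0.5:
            break
        w = np.where(at_point, 0.0, weights / np.where(at_point, 1.0, np.maximum(d, 1e-9)))
        if w.sum() <= 0:
            break
        nx = float(np.sum(w * x) / w.sum())
        ny = float(np.sum(w * y) / w.sum())
        step = float(np.hypot(nx, ny))
        cur_lon, cur_lat = (float(a) for a in geo.aeqd_inverse(nx, ny, cur_lon, cur_lat))
        if step < tol_km:
            break
    return float(geo.normalize_lon(cur_lon)), float(cur_lat)


# ---------------------------------------------------------------------------


@dataclass
class ParticleCloud:
    pair_id: int
    time: pd.Timestamp
    lons: np.ndarray
    lats: np.ndarray
    weights: np.ndarray                   # normalized, post-resampling equal
    ess: float
    flag: str = "ok"                      # ok | degenerate


def _lognormal_speed_pdf(speed_ms, model: SpeedModel):
    """Unnormalized truncated-lognormal speed likelihood."""
    s = np.maximum(np.asarray(speed_ms, dtype=float), 1e-3)
    mu = np.log(model.mode) + model.sigma ** 2
    pdf = np.exp(-((np.log(s) - mu) ** 2) / (2 * model.sigma ** 2)) / s
    return np.where(s <= model.max, pdf, 0.0)


def _systematic_resample(weights, n, rng):
    pos = (rng.random() + np.arange(n)) / n
    return np.searchsorted(np.cumsum(weights), pos).clip(0, len(weights) - 1)


def _invert_latitude(targets_h, dec, angles, rng_band):
    """Vectorized day-length -> latitude inversion.

    Day length is monotone in latitude for fixed declination and angle; a
    coarse angle grid over the sampling band is inverted exactly and each
    particle is linearly blended between its two bracketing grid angles.
    Returns latitudes with NaN where the observed day length is unattainable.
    """
    lo, hi = rng_band
    agrid = np.arange(lo, hi + 1e-9, ANGLE_GRID_STEP)
    if agrid[-1] < hi - 1e-9:
        agrid = np.append(agrid, hi)
    lat_by_angle = np.empty((len(agrid), len(targets_h)))
    ok_by_angle = np.empty((len(agrid), len(targets_h)), dtype=bool)
    for i, ang in enumerate(agrid):
        dl = day_length_hours(LAT_GRID, dec, ang)
        # near the equinoxes the profile is U-shaped (24-h day at both poles
        # at a negative angle): invert on the northern branch only, the
        # analysis domain; elsewhere the profile is monotone
        i0 = int(np.argmin(dl))
        if 0 < i0 < len(LAT_GRID) - 1 and dl[i0] < dl[0] - 1e-9 \
                and dl[i0] < dl[-1] - 1e-9:
            dl_b, lat_b = dl[i0:], LAT_GRID[i0:]
        else:
            dl_b, lat_b = dl, LAT_GRID
        if dl_b[0] > dl_b[-1]:
            dl_m, lat_m = dl_b[::-1], lat_b[::-1]
        else:
            dl_m, lat_m = dl_b, lat_b
        interior = (targets_h > dl_m[0] + 1e-6) & (targets_h < dl_m[-1] - 1e-6)
        lat_by_angle[i] = np.interp(targets_h, dl_m, lat_m)
        ok_by_angle[i] = interior
    if len(agrid) == 1:
        lats = lat_by_angle[0]
        ok = ok_by_angle[0]
    else:
        ia = np.clip(np.searchsorted(agrid, angles) - 1, 0, len(agrid) - 2)
        frac = (angles - agrid[ia]) / (agrid[ia + 1] - agrid[ia])
        cols = np.arange(len(targets_h))
        lats = (1 - frac) * lat_by_angle[ia, cols] + frac * lat_by_angle[ia + 1, cols]
        ok = ok_by_angle[ia, cols] & ok_by_angle[ia + 1, cols]
    return np.where(ok, lats, np.nan)


def _interval_summary(blocks, classes, t0, t1):
    """Wet fraction, modal water class and mean wet temperature in [t0, t1)."""
    if blocks.empty:
        return 1.0, "sea", np.nan
    starts = blocks["block_start"]
    sel = (starts >= t0 - pd.Timedelta(hours=4)) & (starts < t1)
    if not sel.any():
        i = int(np.argmin(np.abs((starts - t0).dt.total_seconds())))
        sel = blocks.index == blocks.index[i]
    sub = blocks[sel]
    cls = classes[sel]
    wet_frac = float(sub["wet_sum"].mean() / WET_SUM_MAX)
    wet_cls = cls[cls != "dry"]
    modal = wet_cls.mode().iloc[0] if len(wet_cls) else "dry"
    wet_temp = float(sub.loc[cls != "dry", "temp_mean"].mean()) if len(wet_cls) else np.nan
    return wet_frac, modal, wet_temp


def run_prob_track(twilights: pd.DataFrame, blocks: pd.DataFrame,
                   world: WorldModel, config: PipelineConfig,
                   deploy_lon: float, deploy_lat: float,
                   deploy_start=None, seed: int = 0):
    """Particle-filter track -> (list[ParticleCloud], TrackEstimate frame).

    The cloud is initialized at the tagging location. Reproducible under
    ``seed``. The conductivity/water-type term is controlled by
    ``config.particle.conductivity_mode`` ('hard', 'soft' or 'off').
    """
    p = config.particle
    rng = np.random.default_rng(seed)
    pairs = twilight_pairs(twilights)
    if pairs.empty:
        raise TrackError("no twilight pairs to model")
    classes = classify_water_type(blocks, config) if len(blocks) else pd.Series(dtype=object)

    n = p.n_particles
    prev_lon = np.full(n, float(deploy_lon))
    prev_lat = np.full(n, float(deploy_lat))
    # the effective sun-elevation angle is a quasi-static property of the
    # tag (threshold + shading regime): each particle carries its own angle,
    # initialized across the band and jittered slightly so the filter can
    # learn it during well-constrained periods and keep it through
    # equinox/polar gaps and rapid migrations
    prev_ang = rng.uniform(p.angle_band[0], p.angle_band[1], size=n)
    prev_time = pd.Timestamp(deploy_start) if deploy_start is not None \
        else pairs["time"].iloc[0] - pd.Timedelta(hours=12)

    clouds = []
    rows = []
    for pr in pairs.itertuples():
        dt_h = max((pr.time - prev_time).total_seconds() / 3600.0, 1.0)
        wet_frac, block_class, wet_temp = _interval_summary(
            blocks, classes, prev_time, pr.time)
        dec, _ = solar_ephemeris(pr.time)
        dec = float(dec[0])
        base_lon = _pair_longitude(pr)

        sigma_prior_deg = _prior_lat_sigma(dt_h, wet_frac, p)
        # threshold latitude assumes a bird at rest between its twilights; an
        # interval spent mostly dry (sustained flight) breaks that, so the
        # day length is not inverted and latitude follows the movement prior
        in_flight = wet_frac < 0.3
        flag = "ok"
        for attempt in range(p.max_retries + 1):
            inflate = 2.0 ** attempt
            lon_c, lat_c, angles = _propose(pr, base_lon, dec, prev_lat,
                                            prev_ang, n, p,
                                            sigma_prior_deg * inflate, inflate,
                                            rng, force_prior_lat=in_flight)
            w = _weigh(lon_c, lat_c, angles, prev_lon, prev_lat, dt_h,
                       wet_frac, block_class, wet_temp, pr.time, world, config)
            if w.sum() > 0:
                break
        else:
            attempt = None
        if w.sum() <= 0:
            if not clouds:
                raise TrackError(
                    f"all particles rejected at the first pair ({pr.time})")
            lon_c, lat_c = prev_lon.copy(), prev_lat.copy()
            angles = prev_ang.copy()
            w = np.full(n, 1.0 / n)
            flag = "degenerate"

        w = w / w.sum()
        ess = float(1.0 / np.sum(w ** 2))
        keep = _systematic_resample(w, n, rng)
        lon_r, lat_r = lon_c[keep], lat_c[keep]
        ang_r = angles[keep]
        med_lon, med_lat = geographic_median(lon_r, lat_r)
        clouds.append(ParticleCloud(int(pr.pair_id), pr.time, lon_r, lat_r,
                                    np.full(n, 1.0 / n), ess, flag))
        rows.append((int(pr.pair_id), pr.time, med_lon, med_lat,
                     float(np.median(ang_r)), block_class, ess, flag))
        prev_lon, prev_lat, prev_ang, prev_time = lon_r, lat_r, ang_r, pr.time

    track = pd.DataFrame(rows, columns=["pair_id", "time", "lon", "lat",
                                        "angle", "water_class", "ess", "flag"])
    return clouds, track


def _pair_longitude(pr):
    from .threshold_geo import longitude_from_transit
    transit = "noon" if pr.kind == "day" else "midnight"
    return longitude_from_transit(pr.time, transit=transit)


def _prior_lat_sigma(dt_h, wet_frac, p):
    max_kmh = 3.6 * (wet_frac * p.wet_speed.max + (1 - wet_frac) * p.dry_speed.max)
    return max(0.5 * max_kmh * dt_h / geo.KM_PER_DEG, 0.2)


def _propose(pr, base_lon, dec, prev_lat, prev_ang, n, p,
             sigma_prior_deg, inflate, rng, force_prior_lat=False):
    angles = np.clip(prev_ang + rng.normal(0.0, 0.1, size=n),
                     p.angle_band[0], p.angle_band[1])
    if pr.kind == "polar":
        # midnight estimate is itself noisy; scatter longitude generously
        lon_c = base_lon + rng.normal(0.0, 3.0 * inflate, size=n)
        lat_c = prev_lat + rng.normal(0.0, sigma_prior_deg, size=n)
        return geo.normalize_lon(lon_c), lat_c, angles
    e1 = rng.normal(0.0, p.twilight_sd_min * inflate, size=n)   # first twilight, min
    e2 = rng.normal(0.0, p.twilight_sd_min * inflate, size=n)
    lon_c = base_lon - 15.0 * ((e1 + e2) / 2.0) / 60.0
    if force_prior_lat or abs(dec) < p.equinox_dec_deg:
        # around the equinoxes day length is nearly 12 h at every latitude:
        # the inversion's sensitivity collapses and any asymmetric timing
        # error (shading shortens the apparent day) maps to a large,
        # *systematic* latitude excursion. Same |dec| window the
        # Hill-Ekstrom calibration trims; latitude follows the movement
        # prior (and the sea-surface-temperature weight) instead.
        lat_c = prev_lat + rng.normal(0.0, sigma_prior_deg, size=n)
        return geo.normalize_lon(lon_c), lat_c, angles
    if pr.kind == "day":
        targets = pr.day_length_h + (e2 - e1) / 60.0
    else:
        targets = pr.day_length_h - (e2 - e1) / 60.0
    lat_c = _invert_latitude(targets, dec, angles, p.angle_band)
    # equinox guard: when the timing noise maps to an absurd latitude spread
    # the day length carries no usable latitude information - treat as a
    # missing value and fall back to the movement prior
    eps_h = np.sqrt(2.0) * p.twilight_sd_min / 60.0
    lat_hi = _invert_latitude(targets + eps_h, dec, angles, p.angle_band)
    lat_lo = _invert_latitude(targets - eps_h, dec, angles, p.angle_band)
    spread = np.abs(lat_hi - lat_lo)
    missing = (~np.isfinite(lat_c)) | (~np.isfinite(spread)) \
        | (spread > p.lat_info_cap_deg)
    if missing.any():
        lat_c[missing] = prev_lat[missing] + rng.normal(
            0.0, sigma_prior_deg, size=int(missing.sum()))
    return geo.normalize_lon(lon_c), lat_c, angles


def _weigh(lon_c, lat_c, angles, prev_lon, prev_lat, dt_h, wet_frac,
           block_class, wet_temp, when, world: WorldModel, config: PipelineConfig):
    p = config.particle
    w = np.ones(lon_c.shape)

    w *= world.contains(lon_c, lat_c)
    cell = world.water_type(lon_c, lat_c)
    wet = wet_frac >= config.wet_fraction_dry_threshold

    # land and ice exclusion: a wet bird cannot sit on land (unless the
    # logger says fresh water, i.e. tundra lakes) nor on ice
    if wet:
        w *= ~world.is_ice(lon_c, lat_c, when)
        if block_class != "fresh":
            w *= cell != LAND_FRESH

    # movement feasibility from each particle's ancestor
    dist_km = geo.haversine_km(prev_lon, prev_lat, lon_c, lat_c)
    speed = dist_km * 1000.0 / (dt_h * 3600.0)
    w *= (wet_frac * _lognormal_speed_pdf(speed, p.wet_speed)
          + (1 - wet_frac) * _lognormal_speed_pdf(speed, p.dry_speed))

    # SST agreement while wet and not in fresh water
    if wet and block_class in ("brackish", "sea") and np.isfinite(wet_temp):
        sst = world.sst(lon_c, lat_c, when)
        w *= np.exp(-0.5 * ((wet_temp - sst) / p.sst_tolerance) ** 2)

    # conductivity/water-type extension
    if p.conductivity_mode != "off" and block_class in _CLASS_TO_CODE:
        match = cell == _CLASS_TO_CODE[block_class]
        if p.conductivity_mode == "hard":
            w *= match
        else:
            w *= np.where(match, 1.0, p.soft_mismatch_weight)
    return w


def wrong_basin_occupancy(clouds, world: WorldModel, expected_code: int,
                          wrong_code: int, start=None, end=None) -> float:
    """Fraction of particle mass sitting in the wrong basin over a window."""
    tot = 0.0
    wrong = 0.0
    for c in clouds:
        if start is not None and c.time < start:
            continue
        if end is not None and c.time >= end:
            continue
        cell = world.water_type(c.lons, c.lats)
        inside = (cell == expected_code) | (cell == wrong_code)
        tot += float(np.sum(c.weights[inside]))
        wrong += float(np.sum(c.weights[cell == wrong_code]))
    return wrong / tot if tot > 0 else np.nan
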