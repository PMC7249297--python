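"""Synthetic bird-year generator: truth tracks and forward-modelled sensors.

The generator scripts an annual itinerary with the six-stage structure of an
Arctic-breeding sea duck (tundra freshwater breeding near 69.138 N 48.848 E,
marine post-moult, rapid autumn migration, Baltic-like or White-Sea-like
wintering, rapid spring migration, coastal pre-breeding), then forward-models
the logger sensors: per-minute light from solar elevation with stochastic
shading (max-pooled to 5 min), 4-hour conductivity/wet-dry blocks consistent
with the water type, and logger temperature tracking a synthetic SST field.

The synthetic world is an abstract rectangle, not real coastlines: a
brackish "Baltic" polygon, a saline "White Sea" embayment, a freshwater
tundra island around the breeding anchor and a land barrier band between the
Baltic and the Arctic seas. The SST field has the closed form

    SST(lat, doy) = 14.0 - 0.45 (lat - 50) + 6.0 cos(2 pi (doy - 225) / 365.25)

(deg C) so tests can compute it independently; ice is SST < 0 deg C.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from . import geo
from .sensor_io import (BLOCK_COLUMNS, LIGHT_MAX, LoggerDataset, WET_SUM_MAX)
from .threshold_geo import solar_position

# water-type raster codes
LAND_FRESH, BRACKISH_SEA, OPEN_SEA = 0, 1, 2
WATER_NAMES = {LAND_FRESH: "land_fresh", BRACKISH_SEA: "brackish_sea",
               OPEN_SEA: "open_sea"}

STAGE_LABELS = ("breeding", "post_moult", "autumn_migration",
                "wintering", "spring_migration", "pre_breeding")

#: longitudinal range of the White-Sea-like embayment (deg E)
WHITE_SEA_LON = (33.9, 41.6)

BREEDING_SITE = (48.848, 69.138)        # lon, lat of the tundra capture site


class ScenarioError(ValueError):
    pass


# ---------------------------------------------------------------------------
# world


@dataclass
class WorldModel:
    """Water-type raster + closed-form SST and ice fields."""

    lon_min: float
    lon_max: float
    lat_min: float
    lat_max: float
    cell_deg: float
    raster: np.ndarray                    # [ilat, ilon] int8 water codes
    sst_base: float = 14.0
    sst_lat_slope: float = 0.45           # deg C per deg lat from lat 50
    sst_amp: float = 6.0
    sst_peak_doy: float = 225.0
    ice_threshold: float = 0.0

    def contains(self, lon, lat):
        lon = np.asarray(lon, dtype=float)
        lat = np.asarray(lat, dtype=float)
        return ((lon >= self.lon_min) & (lon < self.lon_max)
                & (lat >= self.lat_min) & (lat < self.lat_max))

    def water_type(self, lon, lat):
        """Raster class at (lon, lat); out-of-bounds reported as open sea."""
        lon = np.asarray(lon, dtype=float)
        lat = np.asarray(lat, dtype=float)
        i = np.clip(((lat - self.lat_min) / self.cell_deg).astype(int),
                    0, self.raster.shape[0] - 1)
        j = np.clip(((lon - self.lon_min) / self.cell_deg).astype(int),
                    0, self.raster.shape[1] - 1)
        out = self.raster[i, j].astype(int)
        return np.where(self.contains(lon, lat), out, OPEN_SEA)

    def sst(self, lon, lat, times):
        """Sea-surface temperature (deg C) at positions and UTC times."""
        lat = np.asarray(lat, dtype=float)
        doy = pd.DatetimeIndex(pd.to_datetime(np.atleast_1d(times), utc=True)).dayofyear
        doy = np.asarray(doy, dtype=float)
        seasonal = self.sst_amp * np.cos(2 * np.pi * (doy - self.sst_peak_doy) / 365.25)
        out = self.sst_base - self.sst_lat_slope * (lat - 50.0) + seasonal
        if np.ndim(lat) == 0 and np.size(out) == 1:
            return float(np.ravel(out)[0])
        return out

    def is_ice(self, lon, lat, times):
        return self.sst(lon, lat, times) < self.ice_threshold


def _box(raster, lon_min, cell, lat_min, box, code):
    lo_lon, hi_lon, lo_lat, hi_lat = box
    j0 = int((lo_lon - lon_min) / cell)
    j1 = int(np.ceil((hi_lon - lon_min) / cell))
    i0 = int((lo_lat - lat_min) / cell)
    i1 = int(np.ceil((hi_lat - lat_min) / cell))
    raster[max(i0, 0):i1, max(j0, 0):j1] = code


def default_world(cell_deg: float = 0.25) -> WorldModel:
    """Abstract study region: Baltic-like brackish polygon, White-Sea-like
    saline embayment, tundra island with freshwater lakes, land barrier."""
    lon_min, lon_max, lat_min, lat_max = 5.0, 75.0, 50.0, 78.0
    nlat = int(round((lat_max - lat_min) / cell_deg))
    nlon = int(round((lon_max - lon_min) / cell_deg))
    raster = np.full((nlat, nlon), OPEN_SEA, dtype=np.int8)
    # Scandinavian/Finnish land barrier between the Baltic and the Arctic seas
    _box(raster, lon_min, cell_deg, lat_min, (5.0, 33.0, 61.0, 63.0), LAND_FRESH)
    # brackish "Baltic"
    _box(raster, lon_min, cell_deg, lat_min, (14.0, 30.0, 54.0, 60.5), BRACKISH_SEA)
    # tundra island with freshwater lakes around the breeding site
    lats = lat_min + (np.arange(nlat) + 0.5) * cell_deg
    lons = lon_min + (np.arange(nlon) + 0.5) * cell_deg
    glon, glat = np.meshgrid(lons, lats)
    d = geo.haversine_km(glon, glat, BREEDING_SITE[0], BREEDING_SITE[1])
    raster[d < 100.0] = LAND_FRESH
    return WorldModel(lon_min, lon_max, lat_min, lat_max, cell_deg, raster)


def two_basin_world(cell_deg: float = 0.25) -> WorldModel:
    """Two adjacent basins with identical (flat) SST: brackish south of 58 N,
    open sea north of it. Only conductivity can tell them apart."""
    lon_min, lon_max, lat_min, lat_max = 10.0, 30.0, 50.0, 68.0
    nlat = int(round((lat_max - lat_min) / cell_deg))
    nlon = int(round((lon_max - lon_min) / cell_deg))
    raster = np.full((nlat, nlon), OPEN_SEA, dtype=np.int8)
    _box(raster, lon_min, cell_deg, lat_min, (lon_min, lon_max, lat_min, 58.0),
         BRACKISH_SEA)
    return WorldModel(lon_min, lon_max, lat_min, lat_max, cell_deg, raster,
                      sst_base=8.0, sst_lat_slope=0.0, sst_amp=0.0)


# ---------------------------------------------------------------------------
# scenarios


@dataclass
class StagePlan:
    label: str
    start: pd.Timestamp
    end: pd.Timestamp
    anchor: tuple                          # (lon, lat); migration: origin
    end_anchor: tuple | None = None        # migration destination
    style: str = "stationary"              # stationary | migration
    step_sd_km_day: float = 15.0
    speed_kmh: float = 40.0
    allowed_water: int | None = None
    wet_prob: float = 0.9
    stopovers: tuple = ()                  # ((lon, lat, duration_days), ...)


@dataclass
class TrackScenario:
    """Ordered, contiguous stage plan covering one deployment."""

    bird_id: str
    deploy_lon: float
    deploy_lat: float
    stages: list

    @property
    def deploy_start(self):
        return self.stages[0].start

    @property
    def deploy_end(self):
        return self.stages[-1].end

    def stage_table(self) -> pd.DataFrame:
        return pd.DataFrame(
            [(s.label, s.start, s.end) for s in self.stages],
            columns=["label", "start", "end"])

    def validate(self, world: WorldModel):
        prev_end = None
        for s in self.stages:
            if s.end <= s.start:
                raise ScenarioError(f"stage {s.label} has non-positive duration")
            if prev_end is not None and s.start != prev_end:
                raise ScenarioError(f"stage {s.label} not contiguous")
            prev_end = s.end
            anchors = [s.anchor] + ([s.end_anchor] if s.end_anchor else [])
            anchors += [(so[0], so[1]) for so in s.stopovers]
            for lon, lat in anchors:
                if not bool(world.contains(lon, lat)):
                    raise ScenarioError(
                        f"anchor ({lon}, {lat}) of stage {s.label} outside world")
        return self


def _utc(x):
    return pd.Timestamp(x, tz="UTC")


def default_scenario(bird_id: str = "bird01", rng=None, world=None,
                     white_sea_winter: bool = False,
                     autumn_stopover: tuple | None = None,
                     jitter: bool = True) -> TrackScenario:
    """One scripted bird-year with the cohort's mean itinerary.

    With ``jitter`` the stage boundaries and anchors are drawn with the
    cohort's between-bird spreads (post-moult start SD 11 d, end SD 9 d,
    winter end SD 5 d, pre-breeding end SD 9 d; wintering anchor 21 +/- 4 E,
    58 +/- 1.5 N); without it the means are used verbatim.
    ``autumn_stopover`` is (longitude_deg_E, duration_days).
    """
    rng = np.random.default_rng(rng)
    world = world or default_world()
    jit = (lambda sd, lim: float(np.clip(round(rng.normal(0.0, sd)), -lim, lim))) \
        if jitter else (lambda sd, lim: 0.0)

    deploy_start = _utc("2017-06-25")
    deploy_end = _utc("2018-07-08")
    t_postmoult = _utc("2017-09-12") + pd.Timedelta(days=jit(11, 20))
    t_autumn = _utc("2017-10-14") + pd.Timedelta(days=jit(9, 16))
    if t_autumn - t_postmoult < pd.Timedelta(days=12):
        t_autumn = t_postmoult + pd.Timedelta(days=12)
    t_winter_end = _utc("2018-05-17") + pd.Timedelta(days=jit(5, 10))
    t_prebreed_end = _utc("2018-06-12") + pd.Timedelta(days=jit(9, 14))
    if t_prebreed_end - t_winter_end < pd.Timedelta(days=15):
        t_prebreed_end = t_winter_end + pd.Timedelta(days=15)

    breed = _stationary_anchor(rng, world, BREEDING_SITE, LAND_FRESH, 25.0,
                               jitter)
    post = _sea_anchor(rng, world, (48.8, 68.0), (4.0, 0.7), jitter)
    if white_sea_winter:
        winter = (37.5, 64.8)
    else:
        winter = (float(np.clip(21.0 + jit(4.0, 7.5), 15.5, 29.0)),
                  float(np.clip(58.0 + jit(1.5, 2.5), 55.0, 60.0)))
    prebreed = _sea_anchor(rng, world, (44.0, 67.4), (3.0, 0.4), jitter)

    speed = 40.0
    stop_a = ()
    stop_hours_a = 0.0
    if autumn_stopover is not None:
        so_lon, so_days = autumn_stopover
        so_pt = _point_on_leg_at_lon(post, winter, so_lon)
        stop_a = ((so_pt[0], so_pt[1], float(so_days)),)
        stop_hours_a = so_days * 24.0
    fly_a = geo.haversine_km(post[0], post[1], winter[0], winter[1]) / speed
    t_winter = t_autumn + pd.Timedelta(hours=float(fly_a + stop_hours_a))
    fly_s = geo.haversine_km(winter[0], winter[1], prebreed[0], prebreed[1]) / speed
    t_prebreed = t_winter_end + pd.Timedelta(hours=float(fly_s))

    winter_code = int(world.water_type(winter[0], winter[1]))
    stages = [
        StagePlan("breeding", deploy_start, t_postmoult, breed,
                  allowed_water=LAND_FRESH, wet_prob=0.7),
        StagePlan("post_moult", t_postmoult, t_autumn, post,
                  allowed_water=OPEN_SEA),
        StagePlan("autumn_migration", t_autumn, t_winter, post,
                  end_anchor=winter, style="migration", speed_kmh=speed,
                  stopovers=stop_a),
        StagePlan("wintering", t_winter, t_winter_end, winter,
                  allowed_water=winter_code),
        StagePlan("spring_migration", t_winter_end, t_prebreed, winter,
                  end_anchor=prebreed, style="migration", speed_kmh=speed),
        StagePlan("pre_breeding", t_prebreed, t_prebreed_end, prebreed,
                  allowed_water=OPEN_SEA),
        StagePlan("breeding", t_prebreed_end, deploy_end, breed,
                  allowed_water=LAND_FRESH, wet_prob=0.7),
    ]
    scen = TrackScenario(bird_id, BREEDING_SITE[0], BREEDING_SITE[1], stages)
    return scen.validate(world)


def _stationary_anchor(rng, world, center, code, max_km, jitter):
    if not jitter:
        return center
    for _ in range(100):
        brg = rng.uniform(0, 360)
        d = rng.uniform(0, max_km)
        lon, lat = geo.destination(center[0], center[1], brg, d)
        if int(world.water_type(lon, lat)) == code:
            return (float(lon), float(lat))
    return center


def _sea_anchor(rng, world, center, sds, jitter):
    if not jitter:
        if int(world.water_type(*center)) == OPEN_SEA:
            return center
    for _ in range(200):
        lon = float(rng.normal(center[0], sds[0])) if jitter else center[0]
        lat = float(rng.normal(center[1], sds[1])) if jitter else center[1]
        if int(world.water_type(lon, lat)) == OPEN_SEA and bool(world.contains(lon, lat)):
            return (lon, lat)
    raise ScenarioError(f"could not place a sea anchor near {center}")


def _point_on_leg_at_lon(origin, dest, lon_target):
    fr = np.linspace(0.0, 1.0, 501)
    lons, lats = geo.slerp(origin[0], origin[1], dest[0], dest[1], fr)
    i = int(np.argmin(np.abs(lons - lon_target)))
    return float(lons[i]), float(lats[i])


def default_cohort(n: int = 19, seed: int = 0, world=None) -> list:
    """The study-design cohort: n birds, one White-Sea winterer, four autumn
    stopovers at White-Sea longitudes (35, 39, 38, 38 E for 4, 7, 6, 3 days)."""
    world = world or default_world()
    rng = np.random.default_rng(seed)
    stopover_birds = {1: (35.0, 4), 5: (39.0, 7), 9: (38.0, 6), 13: (38.0, 3)}
    scens = []
    for i in range(n):
        scens.append(default_scenario(
            bird_id=f"sim{i:02d}", rng=rng, world=world,
            white_sea_winter=(i == n - 1),
            autumn_stopover=stopover_birds.get(i)))
    return scens


# ---------------------------------------------------------------------------
# truth track


def simulate_track(scenario: TrackScenario, world: WorldModel, seed=0) -> pd.DataFrame:
    """Hourly truth track: timestamp, lon, lat, stage, wet, water_type.

    Stationary stages are a mean-reverting bounded random walk around the
    anchor (daily step SD ``step_sd_km_day``, hard cap at 3 step-SDs,
    rejected if the step leaves the stage's allowed water type). Migration
    stages move along the great circle at constant ground speed with scripted
    stopovers held verbatim.
    """
    scenario.validate(world)
    rng = np.random.default_rng(seed)
    times = pd.date_range(scenario.deploy_start, scenario.deploy_end,
                          freq="1h", inclusive="left")
    n = len(times)
    lon = np.empty(n)
    lat = np.empty(n)
    wet = np.zeros(n, dtype=bool)
    stage = np.empty(n, dtype=object)

    cur = None                            # bird's actual position at stage end
    for plan in scenario.stages:
        sel = (times >= plan.start) & (times < plan.end)
        idx = np.nonzero(sel)[0]
        if idx.size == 0:
            continue
        stage[idx] = plan.label
        if plan.style == "stationary":
            plon, plat, pwet = _walk_stationary(plan, world, rng, idx.size, cur)
        else:
            plon, plat, pwet = _fly_migration(plan, rng, idx.size, cur)
        lon[idx], lat[idx], wet[idx] = plon, plat, pwet
        cur = (float(plon[-1]), float(plat[-1]))

    return pd.DataFrame({
        "timestamp": times, "lon": geo.normalize_lon(lon), "lat": lat,
        "stage": stage, "wet": wet,
        "water_type": world.water_type(lon, lat),
    })


def _walk_stationary(plan: StagePlan, world, rng, n_hours, start=None):
    a_lon, a_lat = plan.anchor
    lons = np.empty(n_hours)
    lats = np.empty(n_hours)
    wet = rng.random(n_hours) < plan.wet_prob
    t0 = 0
    # approach flight from the previous stage's last position (same day)
    if start is not None:
        d0 = float(geo.haversine_km(start[0], start[1], a_lon, a_lat))
        if d0 > 5.0:
            fly_h = min(int(np.ceil(d0 / 40.0)), n_hours)
            fr = (np.arange(fly_h) + 1.0) / fly_h
            alons, alats = geo.slerp(start[0], start[1], a_lon, a_lat, fr)
            lons[:fly_h], lats[:fly_h] = alons, alats
            wet[:fly_h] = False
            t0 = fly_h
    sd_h = plan.step_sd_km_day / np.sqrt(24.0)
    cap = 3.0 * plan.step_sd_km_day
    rho = 0.98                            # hourly mean reversion
    x = np.zeros(2)                       # km offsets in local aeqd plane
    steps = rng.normal(0.0, sd_h, size=(n_hours, 2))
    for t in range(t0, n_hours):
        prop = rho * x + steps[t]
        r = np.hypot(prop[0], prop[1])
        if r > cap:
            prop *= cap / r
        plon, plat = geo.aeqd_inverse(prop[0], prop[1], a_lon, a_lat)
        if plan.allowed_water is None or int(world.water_type(plon, plat)) == plan.allowed_water:
            x = prop
        plon, plat = geo.aeqd_inverse(x[0], x[1], a_lon, a_lat)
        lons[t] = plon
        lats[t] = plat
    return lons, lats, wet


def _fly_migration(plan: StagePlan, rng, n_hours, start=None):
    origin = start if start is not None else plan.anchor
    dest = plan.end_anchor
    total_km = float(geo.haversine_km(origin[0], origin[1], dest[0], dest[1]))
    # schedule: fly -> (stopover) -> fly ... ; stopovers pin the position
    fly_hours = max(total_km / plan.speed_kmh, 1e-9)
    stop_fracs = []
    for so_lon, so_lat, so_days in plan.stopovers:
        fr = np.linspace(0, 1, 501)
        lons, lats = geo.slerp(origin[0], origin[1], dest[0], dest[1], fr)
        i = int(np.argmin((lons - so_lon) ** 2 + (lats - so_lat) ** 2))
        stop_fracs.append((fr[i], so_days * 24.0))
    stop_fracs.sort()

    hours = np.arange(n_hours, dtype=float) + 0.5
    frac = np.empty(n_hours)
    t0 = 0.0
    f0 = 0.0
    for sf, sh in stop_fracs:
        t_arr = t0 + (sf - f0) * fly_hours
        seg = (hours >= t0) & (hours < t_arr)
        frac[seg] = f0 + (hours[seg] - t0) / fly_hours
        hold = (hours >= t_arr) & (hours < t_arr + sh)
        frac[hold] = sf
        t0 = t_arr + sh
        f0 = sf
    t_end = t0 + (1.0 - f0) * fly_hours
    seg = hours >= t0
    frac[seg] = np.clip(f0 + (hours[seg] - t0) / fly_hours, None, 1.0)
    frac = np.clip(frac, 0.0, 1.0)

    lons, lats = geo.slerp(origin[0], origin[1], dest[0], dest[1], frac)
    moving = np.empty(n_hours, dtype=bool)
    moving[0] = True
    moving[1:] = np.abs(np.diff(frac)) > 1e-9
    wet = np.where(moving, False, rng.random(n_hours) < 0.9)
    return lons, lats, wet


# ---------------------------------------------------------------------------
# light


@dataclass
class LightModel:
    """Monotone saturating light response + Bernoulli/lognormal shading."""

    e0_deg: float = -3.5                  # elevation of half-saturation
    k_deg: float = 1.2                    # softness of the response
    shade_prob: float = 0.15              # per-minute shading probability
    shade_depth_median: float = 1.0       # attenuation factor exp(-depth)
    shade_depth_sigma: float = 0.7


def sun_angle_for_threshold(threshold: float, model: LightModel | None = None) -> float:
    """Closed-form truth sun-elevation angle at which noise-free light
    crosses ``threshold``: the oracle for calibration-recovery tests."""
    m = model or LightModel()
    return m.e0_deg + m.k_deg * float(np.log(threshold / (LIGHT_MAX - threshold)))


def simulate_light(truth: pd.DataFrame, model: LightModel | None = None,
                   seed=0) -> pd.DataFrame:
    """Per-minute light from solar elevation at the truth position, shaded,
    max-pooled to the 5-min storage cadence, on the integer 0-255 scale."""
    model = model or LightModel()
    rng = np.random.default_rng(seed)
    t0 = truth["timestamp"].iloc[0]
    t1 = truth["timestamp"].iloc[-1] + pd.Timedelta(hours=1)
    minutes = pd.date_range(t0, t1, freq="1min", inclusive="left")
    tt = truth["timestamp"].astype("int64").to_numpy() / 1e9
    mt = minutes.view("int64") / 1e9
    lon = np.interp(mt, tt, truth["lon"].to_numpy())
    lat = np.interp(mt, tt, truth["lat"].to_numpy())

    elev, _ = solar_position(minutes, lon, lat)
    light = LIGHT_MAX / (1.0 + np.exp(-(elev - model.e0_deg) / model.k_deg))
    if model.shade_prob > 0:
        shaded = rng.random(len(minutes)) < model.shade_prob
        depth = rng.lognormal(np.log(model.shade_depth_median),
                              model.shade_depth_sigma, size=len(minutes))
        light = np.where(shaded, light * np.exp(-depth), light)
    n5 = len(minutes) // 5
    pooled = light[:n5 * 5].reshape(n5, 5).max(axis=1)
    # attribute the stored maximum to the centre of the five sampled minutes
    # (offsets 0..4 -> +2 min): on a monotone dawn (dusk) ramp the max sits
    # at the window's last (first) minute, so centre stamping makes the
    # timing error symmetric (+/- 2 min), which the twilight detector's
    # max-recording correction then removes
    stamps = minutes[:n5 * 5:5] + pd.Timedelta(minutes=2)
    stored = np.clip(np.round(pooled), 0, LIGHT_MAX).astype(int)
    return pd.DataFrame({"timestamp": stamps, "light": stored})


# ---------------------------------------------------------------------------
# sensor blocks


@dataclass
class BlockModel:
    """Forward model for the 4-h conductivity/wet-dry/temperature blocks."""

    cond_levels: dict = field(default_factory=lambda: {
        LAND_FRESH: 3.0, BRACKISH_SEA: 35.0, OPEN_SEA: 95.0})
    cond_sd: float = 3.0
    temp_sd: float = 0.25
    air_warm: float = 2.0                 # dry exposure widens the temp range
    air_cool: float = 1.0


def simulate_blocks(truth: pd.DataFrame, world: WorldModel,
                    model: BlockModel | None = None, seed=0) -> pd.DataFrame:
    """4-h sensor blocks from the hourly truth track."""
    model = model or BlockModel()
    rng = np.random.default_rng(seed)
    t0 = truth["timestamp"].iloc[0].floor("4h")
    if t0 < truth["timestamp"].iloc[0]:
        t0 += pd.Timedelta(hours=4)
    t_last = truth["timestamp"].iloc[-1] + pd.Timedelta(hours=1)
    starts = pd.date_range(t0, t_last - pd.Timedelta(hours=4), freq="4h")

    tns = truth["timestamp"].astype("int64").to_numpy()
    rows = []
    four_h = int(4 * 3600 * 1e9)
    for bs in starts:
        b0 = bs.value
        sel = (tns >= b0) & (tns < b0 + four_h)
        sub = truth[sel]
        if sub.empty:
            continue
        wet_frac = float(sub["wet"].mean())
        wet_sum = int(rng.binomial(WET_SUM_MAX, wet_frac))
        if wet_frac > 0:
            wet_types = sub.loc[sub["wet"], "water_type"]
            if len(wet_types) == 0:
                wet_types = sub["water_type"]
            level = max(model.cond_levels[int(t)] for t in wet_types)
            cond = int(np.clip(round(level + rng.normal(0, model.cond_sd)), 0, 127))
        else:
            cond = int(np.clip(round(abs(rng.normal(0, model.cond_sd / 2))), 0, 127))
        sst = world.sst(sub["lon"].to_numpy(), sub["lat"].to_numpy(),
                        sub["timestamp"].values)
        samples = sst + (rng.normal(0, model.temp_sd, len(sst))
                         if model.temp_sd > 0 else 0.0)
        dry_frac = 1.0 - wet_frac
        tmin = float(np.min(samples) - model.air_cool * dry_frac)
        tmax = float(np.max(samples) + model.air_warm * dry_frac)
        tmean = float(np.clip(np.mean(samples), tmin, tmax))
        rows.append((bs, cond, wet_sum, tmin, tmean, tmax))
    return pd.DataFrame(rows, columns=BLOCK_COLUMNS)


# ---------------------------------------------------------------------------
# one-call bird generator


def make_logger_dataset(scenario: TrackScenario, world: WorldModel,
                        light_model: LightModel | None = None,
                        block_model: BlockModel | None = None,
                        seed=0):
    """Simulate one bird end to end -> (LoggerDataset, truth track)."""
    seeds = np.random.SeedSequence(seed).spawn(3)
    truth = simulate_track(scenario, world,
                           seed=int(seeds[0].generate_state(1)[0] % (2 ** 31)))
    light = simulate_light(truth, light_model,
                           seed=int(seeds[1].generate_state(1)[0] % (2 ** 31)))
    blocks = simulate_blocks(truth, world, block_model,
                             seed=int(seeds[2].generate_state(1)[0] % (2 ** 31)))
    ds = LoggerDataset(
        bird_id=scenario.bird_id,
        deploy_start=scenario.deploy_start, deploy_end=scenario.deploy_end,
        deploy_lon=scenario.deploy_lon, deploy_lat=scenario.deploy_lat,
        light=light, blocks=blocks,
        metadata={"synthetic": True})
    return ds, truth
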