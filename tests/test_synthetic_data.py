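import numpy as np
import pandas as pd
import pytest

from ducktrack import geo
from ducktrack import synthetic_data as sd
from ducktrack import prob_track as ptm
from ducktrack.sensor_io import PipelineConfig
from tests.conftest import THRESHOLD, NOISE_FREE


def _one_stage(label, start, end, anchor, **kw):
    plan = sd.StagePlan(label, pd.Timestamp(start, tz="UTC"),
                        pd.Timestamp(end, tz="UTC"), anchor, **kw)
    return sd.TrackScenario("t", anchor[0], anchor[1], [plan])


def test_world_geography(world):
    assert int(world.water_type(*sd.BREEDING_SITE)) == sd.LAND_FRESH
    assert int(world.water_type(21.0, 58.0)) == sd.BRACKISH_SEA
    assert int(world.water_type(37.5, 64.8)) == sd.OPEN_SEA
    # closed-form SST is reproducible independently
    sst = float(world.sst(21.0, 58.0, pd.Timestamp("2018-02-01", tz="UTC")))
    doy = pd.Timestamp("2018-02-01").dayofyear
    expect = 14.0 - 0.45 * 8.0 + 6.0 * np.cos(2 * np.pi * (doy - 225.0) / 365.25)
    assert sst == pytest.approx(expect, abs=1e-9)
    # winter ice sits at high latitudes only
    feb = pd.Timestamp("2018-02-01", tz="UTC")
    assert bool(world.is_ice(48.0, 75.0, feb))
    assert not bool(world.is_ice(21.0, 58.0, feb))


def test_stationary_stage_bounded_by_three_step_sds(world):
    scen = _one_stage("breeding", "2017-07-01", "2017-08-15",
                      sd.BREEDING_SITE, allowed_water=sd.LAND_FRESH,
                      step_sd_km_day=15.0)
    truth = sd.simulate_track(scen, world, seed=1)
    d = geo.haversine_km(truth["lon"], truth["lat"],
                         sd.BREEDING_SITE[0], sd.BREEDING_SITE[1])
    assert float(np.max(d)) <= 3 * 15.0 + 1.0


def test_simulate_track_deterministic_under_seed(world):
    scen = sd.default_scenario(jitter=False, world=world)
    a = sd.simulate_track(scen, world, seed=4)
    b = sd.simulate_track(scen, world, seed=4)
    pd.testing.assert_frame_equal(a, b)
    c = sd.simulate_track(scen, world, seed=5)
    assert not np.allclose(a["lon"], c["lon"])


def test_migration_leg_duration_from_speed(world):
    # 1200-km leg at 60 km/h with no stopover -> underway less than 2 days
    origin = (43.0, 69.0)
    dest = geo.destination(43.0, 69.0, 225.0, 1200.0)
    plan = sd.StagePlan("autumn_migration", pd.Timestamp("2017-10-01", tz="UTC"),
                        pd.Timestamp("2017-10-04", tz="UTC"), origin,
                        end_anchor=(float(dest[0]), float(dest[1])),
                        style="migration", speed_kmh=60.0)
    scen = sd.TrackScenario("m", origin[0], origin[1], [plan])
    truth = sd.simulate_track(scen, world, seed=1)
    arrived = geo.haversine_km(truth["lon"], truth["lat"],
                               dest[0], dest[1]) < 10.0
    t_arrive = truth.loc[arrived.argmax(), "timestamp"]
    assert (t_arrive - truth["timestamp"].iloc[0]) < pd.Timedelta(days=2)


def test_polar_day_light_never_crosses_threshold(world):
    scen = _one_stage("breeding", "2017-06-22", "2017-06-29",
                      sd.BREEDING_SITE, allowed_water=sd.LAND_FRESH)
    truth = sd.simulate_track(scen, world, seed=2)
    light = sd.simulate_light(truth, NOISE_FREE, seed=2)
    assert int(light["light"].min()) > THRESHOLD


def test_heavier_shading_biases_summer_latitude_equatorward(world):
    """Shading shortens the apparent day; in summer that reads as a latitude
    closer to the equator (sign-only property)."""
    from ducktrack import twilights as tw
    from ducktrack import threshold_geo as tg

    scen = _one_stage("wintering", "2017-07-05", "2017-07-25", (21.0, 58.0),
                      allowed_water=sd.BRACKISH_SEA, step_sd_km_day=0.0)
    truth = sd.simulate_track(scen, world, seed=3)
    angle = sd.sun_angle_for_threshold(THRESHOLD)
    lats = {}
    for label, prob in (("clear", 0.0), ("shaded", 0.75)):
        light = sd.simulate_light(
            truth, sd.LightModel(shade_prob=prob, shade_depth_median=2.0), seed=3)
        ev = tw.validate_twilights(tw.detect_twilights(light, THRESHOLD, 21.0))
        pos = tg.positions_from_twilights(ev, angle).dropna(subset=["lat"])
        lats[label] = float(pos["lat"].mean())
    assert lats["shaded"] < lats["clear"]


def test_blocks_fully_wet_at_sea(world):
    scen = _one_stage("wintering", "2017-11-01", "2017-11-03", (45.0, 70.0),
                      allowed_water=sd.OPEN_SEA, wet_prob=1.0)
    truth = sd.simulate_track(scen, world, seed=4)
    blocks = sd.simulate_blocks(truth, world, sd.BlockModel(cond_sd=0.0), seed=4)
    cfg = PipelineConfig()
    assert (blocks["wet_sum"] == 480).all()
    assert (blocks["cond_max"] >= cfg.c_brackish_sea).all()


def test_blocks_fully_dry(world):
    scen = _one_stage("breeding", "2017-08-01", "2017-08-03",
                      sd.BREEDING_SITE, allowed_water=sd.LAND_FRESH, wet_prob=0.0)
    truth = sd.simulate_track(scen, world, seed=5)
    blocks = sd.simulate_blocks(truth, world, seed=5)
    assert (blocks["wet_sum"] == 0).all()


def test_block_temperature_noise_free_limit():
    """Fully wet at a flat 8 degC SST with zero noise -> temp_mean = SST."""
    world2 = sd.two_basin_world()     # flat SST field at 8 degC
    scen = _one_stage("wintering", "2017-11-01", "2017-11-03", (20.0, 55.0),
                      allowed_water=sd.BRACKISH_SEA, wet_prob=1.0,
                      step_sd_km_day=0.0)
    truth = sd.simulate_track(scen, world2, seed=6)
    blocks = sd.simulate_blocks(truth, world2,
                                sd.BlockModel(temp_sd=0.0, cond_sd=0.0), seed=6)
    assert np.allclose(blocks["temp_mean"], 8.0, atol=1e-9)


def test_conductivity_classes_match_scripted_water_types(default_bird, config):
    """Block classes agree with the scripted stage water regime >= 95%."""
    ds = default_bird["dataset"]
    truth = default_bird["truth"]
    classes = ptm.classify_water_type(ds.blocks, config)
    tns = truth["timestamp"].astype("int64").to_numpy()
    stage_of = truth["stage"].to_numpy()
    bns = ds.blocks["block_start"].astype("int64").to_numpy()
    idx = np.clip(np.searchsorted(tns, bns), 0, len(tns) - 1)
    stages_b = stage_of[idx]
    expected = {"breeding": {"fresh", "dry"},
                "post_moult": {"sea", "dry"},
                "wintering": {"brackish", "dry"},
                "pre_breeding": {"sea", "dry"}}
    for stage, allowed in expected.items():
        m = stages_b == stage
        ok = np.isin(classes[m], list(allowed))
        assert ok.mean() >= 0.95, stage


def test_anchor_outside_world_rejected(world):
    scen = _one_stage("wintering", "2017-11-01", "2017-12-01", (120.0, 58.0))
    with pytest.raises(sd.ScenarioError):
        scen.validate(world)


def test_cohort_structure(world):
    scens = sd.default_cohort(n=19, seed=1, world=world)
    assert len(scens) == 19
    winters = [s.stages[3].anchor for s in scens]
    basins = [int(world.water_type(lo, la)) for lo, la in winters]
    assert basins.count(sd.BRACKISH_SEA) == 18
    assert basins.count(sd.OPEN_SEA) == 1
    with_stop = [s for s in scens if s.stages[2].stopovers]
    assert len(with_stop) == 4
    durations = sorted(so[2] for s in with_stop for so in s.stages[2].stopovers)
    assert durations == [3, 4, 6, 7]
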