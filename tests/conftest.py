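"""Shared fixtures: synthetic worlds, reference birds, and the full cohort.

Everything is generated at test time from the synthetic-data module; the
expensive objects (full-year birds, the 19-bird cohort) are session-scoped
so each is simulated once per run.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from ducktrack import pipeline
from ducktrack import synthetic_data as sd
from ducktrack import twilights as tw
from ducktrack.sensor_io import PipelineConfig

THRESHOLD = PipelineConfig().light_threshold
NOISE_FREE = sd.LightModel(shade_prob=0.0)
QUIET_BLOCKS = sd.BlockModel(cond_sd=0.0, temp_sd=0.0)


@pytest.fixture(scope="session")
def world():
    return sd.default_world()


@pytest.fixture()
def config():
    return PipelineConfig()


def _stationary_scenario(bird_id, lon, lat, start, end, water, step_sd=0.0,
                         wet_prob=0.9):
    plan = sd.StagePlan("wintering", pd.Timestamp(start, tz="UTC"),
                        pd.Timestamp(end, tz="UTC"), (lon, lat),
                        allowed_water=water, step_sd_km_day=step_sd,
                        wet_prob=wet_prob)
    return sd.TrackScenario(bird_id, lon, lat, [plan])


@pytest.fixture(scope="session")
def rooftop(world):
    """Noise-free stationary logger at a known mid-latitude site."""
    scen = _stationary_scenario("roof", 9.0, 50.5, "2017-04-01", "2017-04-20",
                                None, wet_prob=0.0)
    truth = sd.simulate_track(scen, world, seed=2)
    light = sd.simulate_light(truth, NOISE_FREE, seed=2)
    events = tw.detect_twilights(light, THRESHOLD, deploy_lon=9.0)
    return {"scenario": scen, "truth": truth, "light": light, "events": events}


@pytest.fixture(scope="session")
def winter_stationary(world):
    """Noise-free stationary wintering bird (Nov-Feb) in the brackish basin."""
    scen = _stationary_scenario("hk", 21.0, 58.0, "2017-11-20", "2018-02-20",
                                sd.BRACKISH_SEA)
    truth = sd.simulate_track(scen, world, seed=3)
    light = sd.simulate_light(truth, NOISE_FREE, seed=3)
    events = tw.detect_twilights(light, THRESHOLD, deploy_lon=21.0)
    return {"scenario": scen, "truth": truth, "light": light, "events": events}


@pytest.fixture(scope="session")
def year_stationary(world):
    """Noise-free bird sitting a full year in the brackish basin: exercises
    every season (both equinoxes, solstices) without movement confounds."""
    scen = _stationary_scenario("yr", 21.0, 58.0, "2017-07-01", "2018-06-25",
                                sd.BRACKISH_SEA)
    truth = sd.simulate_track(scen, world, seed=5)
    light = sd.simulate_light(truth, NOISE_FREE, seed=5)
    events = tw.detect_twilights(light, THRESHOLD, deploy_lon=21.0)
    return {"scenario": scen, "truth": truth, "light": light, "events": events}


@pytest.fixture(scope="session")
def default_bird(world):
    """One full default bird-year (default noise) through the whole pipeline."""
    scen = sd.default_scenario(jitter=False, world=world)
    ds, truth = sd.make_logger_dataset(scen, world, seed=7)
    result = pipeline.run_bird(ds, world, seed=11)
    return {"scenario": scen, "dataset": ds, "truth": truth, "result": result}


@pytest.fixture(scope="session")
def cohort(world):
    """The 19-bird study-design cohort, simulated and fully processed."""
    scens = sd.default_cohort(n=19, seed=42, world=world)
    datasets = []
    truths = {}
    for i, scen in enumerate(scens):
        ds, truth = sd.make_logger_dataset(scen, world, seed=1000 + i)
        datasets.append(ds)
        truths[scen.bird_id] = truth
    results = pipeline.run_cohort(datasets, world, seed=7)
    return {"scenarios": scens, "datasets": datasets, "truths": truths,
            "results": results}


@pytest.fixture(scope="session")
def two_basin_runs():
    """Stationary equinox bird in the two-basin world, modelled with the
    conductivity extension on and off."""
    import dataclasses

    from ducktrack import prob_track as ptm

    world2 = sd.two_basin_world()
    plan = sd.StagePlan("wintering", pd.Timestamp("2017-09-05", tz="UTC"),
                        pd.Timestamp("2017-10-10", tz="UTC"), (20.0, 57.0),
                        allowed_water=sd.BRACKISH_SEA)
    scen = sd.TrackScenario("basin01", 20.0, 57.0, [plan])
    ds, truth = sd.make_logger_dataset(scen, world2, seed=5)
    cfg = PipelineConfig()
    events = tw.validate_twilights(tw.detect_twilights(
        ds.light, cfg.light_threshold, deploy_lon=20.0))
    out = {"world": world2, "truth": truth}
    for mode in ("hard", "off"):
        c = dataclasses.replace(
            cfg, particle=dataclasses.replace(cfg.particle,
                                              conductivity_mode=mode))
        clouds, track = ptm.run_prob_track(events, ds.blocks, world2, c,
                                           20.0, 57.0, ds.deploy_start, seed=9)
        out[mode] = {"clouds": clouds, "track": track}
    return out


def boundary_errors_days(scenario, segmentation) -> dict:
    """|detected - scripted| start errors (days) for every stage boundary."""
    truth = scenario.stage_table()
    det = segmentation.intervals
    errs = {}
    for lbl in ["post_moult", "autumn_migration", "wintering",
                "spring_migration", "pre_breeding"]:
        t_true = truth[truth.label == lbl].start.iloc[0]
        row = det[det.label == lbl]
        errs[lbl] = (abs((row.start.iloc[0] - t_true).total_seconds()) / 86400
                     if len(row) else np.inf)
    b2 = det[det.label == "breeding"]
    t_true = truth[truth.label == "breeding"].start.iloc[1]
    errs["breeding_return"] = (
        abs((b2.start.iloc[1] - t_true).total_seconds()) / 86400
        if len(b2) > 1 else np.inf)
    return errs
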