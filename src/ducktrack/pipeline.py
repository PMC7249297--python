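"""End-to-end orchestration: logger record -> twilights -> positions ->
particle track -> stage segmentation -> phenology.

The library modules stay independent; this module only wires them together
in the order a bird-year is normally processed and bundles the results.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import prob_track, stages, threshold_geo, twilights
from .sensor_io import LoggerDataset, PipelineConfig
from .synthetic_data import BRACKISH_SEA, WHITE_SEA_LON, WorldModel


@dataclass
class BirdResult:
    bird_id: str
    twilights: pd.DataFrame
    positions: pd.DataFrame               # threshold-method positions
    track: pd.DataFrame                   # particle-model median track
    clouds: list
    segmentation: stages.StageSegmentation
    daily_lon: pd.DataFrame
    calibration: threshold_geo.SunAngleCalibration | None = None
    extras: dict = field(default_factory=dict)

    def wintering_centroid(self):
        """Geographic median of the particle-track medians in wintering."""
        iv = self.segmentation.interval("wintering")
        if iv is None:
            return None
        sel = (self.track["time"] >= iv[0]) & (self.track["time"] < iv[1])
        sub = self.track[sel].dropna(subset=["lon", "lat"])
        if sub.empty:
            return None
        return prob_track.geographic_median(sub["lon"].to_numpy(),
                                            sub["lat"].to_numpy())


def wintering_basin(lon: float) -> str:
    """Baltic-like vs White-Sea-like wintering, by centroid longitude."""
    if WHITE_SEA_LON[0] <= lon <= WHITE_SEA_LON[1]:
        return "white_sea"
    return "baltic" if lon < WHITE_SEA_LON[0] else "other"


def run_bird(dataset: LoggerDataset, world: WorldModel,
             config: PipelineConfig | None = None,
             twilight_overrides=None, seed: int | None = None) -> BirdResult:
    """Process one bird-year end to end."""
    config = config or PipelineConfig()
    seed = config.seed if seed is None else seed

    events = twilights.detect_twilights(
        dataset.light, config.light_threshold,
        deploy_lon=0.0 if np.isnan(dataset.deploy_lon) else dataset.deploy_lon)
    valid = twilights.validate_twilights(events, twilight_overrides)

    angle = config.fixed_angle
    calibration = None
    positions = threshold_geo.positions_from_twilights(valid, angle,
                                                       method="threshold")

    clouds, track = prob_track.run_prob_track(
        valid, dataset.blocks, world, config,
        deploy_lon=dataset.deploy_lon, deploy_lat=dataset.deploy_lat,
        deploy_start=dataset.deploy_start, seed=seed)

    classes = prob_track.classify_water_type(dataset.blocks, config)
    daily = stages.daily_longitude(positions)
    daily_cls = stages.daily_water_class(dataset.blocks, classes)
    polar_dates = pd.DatetimeIndex(
        valid.loc[valid["polar_day"].astype(bool), "time"]).floor("D").unique()
    seg = stages.segment_annual_cycle(daily, daily_cls, config,
                                      bird_id=dataset.bird_id,
                                      polar_day_dates=polar_dates)

    if config.sun_angle_mode == "hill_ekstrom":
        iv = seg.interval("wintering")
        if iv is not None:
            calibration = threshold_geo.calibrate_hill_ekstrom(valid, iv)
            angle = calibration.angle
            positions = threshold_geo.positions_from_twilights(
                valid, angle, method="hill_ekstrom")

    return BirdResult(dataset.bird_id, valid, positions, track, clouds, seg,
                      daily, calibration=calibration)


def run_cohort(datasets: list, world: WorldModel,
               config: PipelineConfig | None = None,
               seed: int = 0) -> dict:
    """Process a cohort; returns per-bird results plus the phenology table."""
    config = config or PipelineConfig()
    results = {}
    for i, ds in enumerate(datasets):
        results[ds.bird_id] = run_bird(ds, world, config, seed=seed + i)
    segs = [r.segmentation for r in results.values()]
    tracks = {b: r.track for b, r in results.items()}
    dailies = {b: r.daily_lon for b, r in results.items()}
    phen = stages.phenology_summary(segs, tracks=tracks, daily_lons=dailies)
    basins = {}
    for b, r in results.items():
        c = r.wintering_centroid()
        basins[b] = wintering_basin(c[0]) if c is not None else "unknown"
    return {"birds": results, "phenology": phen, "wintering_basin": basins}
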