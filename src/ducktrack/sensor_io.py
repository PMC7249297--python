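"""Logger data model, pipeline configuration, and file readers/writers.

The archival tags modelled here record relative light (maximum per 5 min on a
0-255 scale), and 4-hour sensor blocks holding the conductivity maximum
(relative 0-127 scale), the wet/dry sum (0-480, one sample every 30 s) and
min/mean/max temperature in deg C.

The native file dialect is plain CSV with a two-line header: line 1 a JSON
metadata object, line 2 the column names. A Movebank-style dialect maps the
conventional ``timestamp`` / ``location-long`` / ``location-lat`` columns for
position files and ``gls:light-level`` for light files.

All timestamps are handled in UTC. Logger clock drift is assumed to be
pre-corrected in the export (as drift-adjusted manufacturer exports are); the
``clock_drift_corrected`` metadata flag records that assumption.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

LIGHT_MAX = 255
COND_MAX = 127
WET_SUM_MAX = 480
LIGHT_STEP_S = 300
BLOCK_HOURS = 4

LIGHT_COLUMNS = ["timestamp", "light"]
BLOCK_COLUMNS = ["block_start", "cond_max", "wet_sum",
                 "temp_min", "temp_mean", "temp_max"]


class FormatError(ValueError):
    """Malformed file: missing columns or unparseable header."""


class DataError(ValueError):
    """Well-formed file with physically invalid content."""


def _utc(ts):
    return pd.to_datetime(ts, utc=True)


@dataclass
class LoggerDataset:
    """One bird's raw sensor record plus deployment metadata."""

    bird_id: str
    deploy_start: pd.Timestamp
    deploy_end: pd.Timestamp
    light: pd.DataFrame                   # columns: timestamp, light
    blocks: pd.DataFrame                  # columns: BLOCK_COLUMNS
    deploy_lon: float = np.nan            # tagging/retrieval site
    deploy_lat: float = np.nan
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        self.deploy_start = _utc(self.deploy_start)
        self.deploy_end = _utc(self.deploy_end)
        self.light = self.light.reset_index(drop=True)
        self.blocks = self.blocks.reset_index(drop=True)
        self.metadata.setdefault("clock_drift_corrected", True)
        self.validate()

    def validate(self):
        if self.deploy_end <= self.deploy_start:
            raise DataError("deploy_end must be after deploy_start")
        lt = self.light
        if list(lt.columns) != LIGHT_COLUMNS:
            raise FormatError(f"light columns must be {LIGHT_COLUMNS}")
        ts = pd.DatetimeIndex(_utc(lt["timestamp"]))
        diffs = np.diff(ts.view("int64")) / 1e9
        if (diffs <= 0).any():
            bad = int(np.argmax(diffs <= 0)) + 1
            raise DataError(f"light timestamps not strictly increasing at row {bad}")
        # gaps are allowed but spacing must be a multiple of the 5-min cadence
        off = np.remainder(diffs, LIGHT_STEP_S)
        if not np.all((off < 1.0) | (off > LIGHT_STEP_S - 1.0)):
            bad = int(np.argmax((off >= 1.0) & (off <= LIGHT_STEP_S - 1.0))) + 1
            raise DataError(f"light spacing not on the 300 s grid at row {bad}")
        if (lt["light"] < 0).any():
            raise DataError("negative light values")

        bl = self.blocks
        if list(bl.columns) != BLOCK_COLUMNS:
            raise FormatError(f"block columns must be {BLOCK_COLUMNS}")
        if len(bl):
            if ((bl["cond_max"] < 0) | (bl["cond_max"] > COND_MAX)).any():
                bad = int(((bl["cond_max"] < 0) | (bl["cond_max"] > COND_MAX)).idxmax())
                raise DataError(
                    f"cond_max outside 0-{COND_MAX} range at block row {bad}")
            if ((bl["wet_sum"] < 0) | (bl["wet_sum"] > WET_SUM_MAX)).any():
                raise DataError(f"wet_sum outside 0-{WET_SUM_MAX} range")
            if not ((bl["temp_min"] <= bl["temp_mean"] + 1e-9)
                    & (bl["temp_mean"] <= bl["temp_max"] + 1e-9)).all():
                raise DataError("temperature ordering min <= mean <= max violated")
            bts = pd.DatetimeIndex(_utc(bl["block_start"]))
            bdiff = np.diff(bts.view("int64")) / 3600e9
            if (bdiff <= 0).any():
                bad = int(np.argmax(bdiff <= 0)) + 1
                raise DataError(f"block timestamps not increasing at row {bad}")
            boff = np.remainder(bdiff, BLOCK_HOURS)
            if not np.all((boff < 1e-6) | (boff > BLOCK_HOURS - 1e-6)):
                raise DataError("block spacing not on the 4 h grid")
        return self

    def equals(self, other: "LoggerDataset") -> bool:
        return (self.bird_id == other.bird_id
                and self.deploy_start == other.deploy_start
                and self.deploy_end == other.deploy_end
                and np.isclose(self.deploy_lon, other.deploy_lon, equal_nan=True)
                and np.isclose(self.deploy_lat, other.deploy_lat, equal_nan=True)
                and _frames_equal(self.light, other.light)
                and _frames_equal(self.blocks, other.blocks))


def _frames_equal(a: pd.DataFrame, b: pd.DataFrame) -> bool:
    if list(a.columns) != list(b.columns) or len(a) != len(b):
        return False
    for col in a.columns:
        if np.issubdtype(np.asarray(a[col]).dtype, np.number):
            if not np.allclose(a[col].astype(float), b[col].astype(float),
                               atol=1e-9, equal_nan=True):
                return False
        else:
            if not (_utc(a[col]).values == _utc(b[col]).values).all():
                return False
    return True


# ---------------------------------------------------------------------------
# configuration


@dataclass
class SpeedModel:
    """Truncated-lognormal speed likelihood (m/s)."""

    mode: float
    max: float
    sigma: float = 0.6


@dataclass
class ParticleParams:
    n_particles: int = 400
    angle_band: tuple = (-10.0, -1.0)     # per-pair sun-elevation sampling band
    twilight_sd_min: float = 6.0          # twilight timing error SD (minutes)
    sst_tolerance: float = 1.0            # deg C (logger accuracy is 0.5 deg C)
    dry_speed: SpeedModel = field(default_factory=lambda: SpeedModel(15.0, 25.0))
    wet_speed: SpeedModel = field(default_factory=lambda: SpeedModel(0.5, 2.0))
    conductivity_mode: str = "hard"       # hard mask | soft | off
    soft_mismatch_weight: float = 0.05
    lat_info_cap_deg: float = 8.0         # equinox guard: see prob_track
    equinox_dec_deg: float = 6.0          # |solar dec| below which latitude
    #                                       is not inverted (equinox window)
    max_retries: int = 3


@dataclass
class StageParams:
    lon_stable_deg: float = 3.0           # "no longitudinal change" band
    migration_rate_deg_per_day: float = 3.0
    migration_min_run_days: int = 1
    winter_lon_range_deg: float = 10.0
    prebreeding_lon_range_deg: float = 15.0   # widened: polar-day inaccuracy
    window_days: int = 7
    # a stationary spell only ends a migration if it outlasts any stopover
    # (stopovers observed up to ~a week); otherwise it is a stopover
    settle_confirm_days: int = 10
    stopover_min_days: int = 2
    breeding_min_run_days: int = 2


@dataclass
class KDEParams:
    grid_cells: int = 100                 # per axis
    bandwidth: str | float = "adhoc"
    levels: tuple = (25, 50, 75)
    projection: str = "aeqd"              # aeqd | platecarree


@dataclass
class PipelineConfig:
    """Everything tunable in the pipeline, YAML round-trippable."""

    light_threshold: float = 6.375        # 2.5% of the 0-255 light scale
    sun_angle_mode: str = "prob_model"    # known_site | fixed | hill_ekstrom | prob_model
    fixed_angle: float = -3.5
    c_fresh_brackish: int = 10            # conductivity class bounds (0-127 scale)
    c_brackish_sea: int = 60
    wet_fraction_dry_threshold: float = 0.05
    particle: ParticleParams = field(default_factory=ParticleParams)
    stages: StageParams = field(default_factory=StageParams)
    kde: KDEParams = field(default_factory=KDEParams)
    seed: int = 0
    clock_drift_corrected: bool = True

    def __post_init__(self):
        if not (0 <= self.c_fresh_brackish < self.c_brackish_sea <= COND_MAX):
            raise ValueError("need 0 <= c_fresh_brackish < c_brackish_sea <= 127")
        if self.particle.n_particles < 1:
            raise ValueError("n_particles must be >= 1")
        if not all(0 < lv < 100 for lv in self.kde.levels):
            raise ValueError("KDE levels must lie in (0, 100)")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        if "particle" in d and isinstance(d["particle"], dict):
            p = dict(d["particle"])
            for k in ("dry_speed", "wet_speed"):
                if isinstance(p.get(k), dict):
                    p[k] = SpeedModel(**p[k])
            for k in ("angle_band",):
                if isinstance(p.get(k), list):
                    p[k] = tuple(p[k])
            d["particle"] = ParticleParams(**p)
        if "stages" in d and isinstance(d["stages"], dict):
            d["stages"] = StageParams(**d["stages"])
        if "kde" in d and isinstance(d["kde"], dict):
            k = dict(d["kde"])
            if isinstance(k.get("levels"), list):
                k["levels"] = tuple(k["levels"])
            d["kde"] = KDEParams(**k)
        return cls(**d)

    def to_yaml(self, path):
        Path(path).write_text(yaml.safe_dump(_listify(self.to_dict()), sort_keys=True))

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))

    def hash(self) -> str:
        blob = json.dumps(_listify(self.to_dict()), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def _listify(obj):
    if isinstance(obj, dict):
        return {k: _listify(v) for k, v in obj.items()}
    if isinstance(obj, tuple):
        return [_listify(v) for v in obj]
    if isinstance(obj, list):
        return [_listify(v) for v in obj]
    return obj


# ---------------------------------------------------------------------------
# native dialect: <base>.light.csv + <base>.blocks.csv, two-line headers


def write_logger_export(dataset: LoggerDataset, base_path) -> list:
    """Write a dataset in the native dialect; returns the file paths."""
    base = Path(base_path)
    base.parent.mkdir(parents=True, exist_ok=True)
    meta = {
        "bird_id": dataset.bird_id,
        "deploy_start": dataset.deploy_start.isoformat(),
        "deploy_end": dataset.deploy_end.isoformat(),
        "deploy_lon": None if np.isnan(dataset.deploy_lon) else dataset.deploy_lon,
        "deploy_lat": None if np.isnan(dataset.deploy_lat) else dataset.deploy_lat,
        **dataset.metadata,
    }
    paths = []
    for suffix, df in (("light", dataset.light), ("blocks", dataset.blocks)):
        path = Path(str(base) + f".{suffix}.csv")
        out = df.copy()
        tcol = out.columns[0]
        out[tcol] = pd.DatetimeIndex(_utc(out[tcol])).strftime("%Y-%m-%dT%H:%M:%SZ")
        with open(path, "w") as fh:
            fh.write(json.dumps({**meta, "table": suffix}, sort_keys=True) + "\n")
            out.to_csv(fh, index=False)
        paths.append(path)
    return paths


def read_logger_export(base_path, dialect: str = "native_csv") -> LoggerDataset:
    """Read a logger export.

    ``native_csv``: ``base_path`` is the base name used by
    :func:`write_logger_export`. ``movebank_csv``: ``base_path`` is a single
    CSV with Movebank-style columns (light only; blocks come back empty).
    """
    if dialect == "native_csv":
        return _read_native(Path(base_path))
    if dialect == "movebank_csv":
        return _read_movebank_light(Path(base_path))
    raise ValueError(f"unknown dialect {dialect!r}")


def _read_two_line_csv(path: Path):
    if not path.exists():
        raise FileNotFoundError(path)
    with open(path) as fh:
        header = fh.readline()
        try:
            meta = json.loads(header)
        except json.JSONDecodeError as exc:
            raise FormatError(f"{path}: first line is not JSON metadata") from exc
        df = pd.read_csv(fh)
    return meta, df


def _read_native(base: Path) -> LoggerDataset:
    meta_l, light = _read_two_line_csv(Path(str(base) + ".light.csv"))
    meta_b, blocks = _read_two_line_csv(Path(str(base) + ".blocks.csv"))
    for cols, df, which in ((LIGHT_COLUMNS, light, "light"),
                            (BLOCK_COLUMNS, blocks, "blocks")):
        missing = [c for c in cols if c not in df.columns]
        if missing:
            raise FormatError(f"{which} file missing columns {missing}")
    meta = {**meta_b, **meta_l}
    light["timestamp"] = _utc(light["timestamp"])
    blocks["block_start"] = _utc(blocks["block_start"])
    extra = {k: v for k, v in meta.items()
             if k not in {"bird_id", "deploy_start", "deploy_end",
                          "deploy_lon", "deploy_lat", "table"}}
    return LoggerDataset(
        bird_id=str(meta["bird_id"]),
        deploy_start=meta["deploy_start"], deploy_end=meta["deploy_end"],
        deploy_lon=np.nan if meta.get("deploy_lon") is None else float(meta["deploy_lon"]),
        deploy_lat=np.nan if meta.get("deploy_lat") is None else float(meta["deploy_lat"]),
        light=light[LIGHT_COLUMNS], blocks=blocks[BLOCK_COLUMNS],
        metadata=extra)


def _read_movebank_light(path: Path) -> LoggerDataset:
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path)
    need = ["timestamp", "gls:light-level"]
    missing = [c for c in need if c not in df.columns]
    if missing:
        raise FormatError(f"movebank light file missing columns {missing}")
    light = pd.DataFrame({
        "timestamp": _utc(df["timestamp"]),
        "light": df["gls:light-level"].astype(float),
    })
    bird = (str(df["individual-local-identifier"].iloc[0])
            if "individual-local-identifier" in df.columns else "unknown")
    blocks = pd.DataFrame(columns=BLOCK_COLUMNS)
    return LoggerDataset(
        bird_id=bird,
        deploy_start=light["timestamp"].iloc[0],
        deploy_end=light["timestamp"].iloc[-1] + pd.Timedelta(seconds=LIGHT_STEP_S),
        light=light, blocks=blocks)


def read_movebank_positions(path) -> pd.DataFrame:
    """Movebank-style position CSV -> DataFrame(bird_id, time, lon, lat)."""
    df = pd.read_csv(path)
    need = ["timestamp", "location-long", "location-lat"]
    missing = [c for c in need if c not in df.columns]
    if missing:
        raise FormatError(f"movebank position file missing columns {missing}")
    out = pd.DataFrame({
        "bird_id": df.get("individual-local-identifier", "unknown"),
        "time": _utc(df["timestamp"]),
        "lon": df["location-long"].astype(float),
        "lat": df["location-lat"].astype(float),
    })
    return out


# ---------------------------------------------------------------------------
# result export


def write_outputs(results: dict, out_dir, config: PipelineConfig | None = None) -> dict:
    """Write pipeline results and return (and save) a JSON manifest.

    ``results`` may contain: positions (DataFrame), track (DataFrame),
    stages (StageSegmentation or DataFrame), phenology (DataFrame),
    uds ({name: UtilizationDistribution}). At least one must be present.
    """
    keys = {"positions", "track", "stages", "phenology", "uds"}
    present = {k for k in keys if results.get(k) is not None}
    if not present:
        raise ValueError("results must contain at least one of "
                         "{positions, track, stages, phenology, UDs}")
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    files = {}

    for key in ("positions", "track", "phenology"):
        if key in present:
            path = out / f"{key}.csv"
            pd.DataFrame(results[key]).to_csv(path, index=False)
            files[key] = path.name
    if "stages" in present:
        seg = results["stages"]
        df = seg.to_frame() if hasattr(seg, "to_frame") else pd.DataFrame(seg)
        path = out / "stages.csv"
        df.to_csv(path, index=False)
        files["stages"] = path.name
    if "uds" in present:
        for name, ud in results["uds"].items():
            path = out / f"ud_{name}.geojson"
            path.write_text(json.dumps(ud.contours_geojson(), indent=1))
            files[f"ud_{name}"] = path.name

    manifest = {
        "files": files,
        "config_hash": config.hash() if config is not None else None,
        "n_outputs": len(files),
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
    return manifest
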