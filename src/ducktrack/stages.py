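"""Rule-based segmentation of a bird-year into six staging periods.

The stages - breeding, post-moult, autumn migration, wintering, spring
migration, pre-breeding - are delimited from daily longitudes and per-block
water types only (latitudes are unusable near the equinoxes and during the
polar day). The rules, applied as a deterministic forward state machine
over daily summaries:

* breeding holds while all blocks are fresh-or-dry and the trailing 7-day
  longitude range stays inside the stability band; the first day violating
  either starts the post-moult stage (first movement away from fresh water);
* autumn migration starts on the first day the longitudinal displacement
  rate exceeds the migration-rate threshold, sustained over the minimum run;
* wintering starts when the longitude range over a forward window drops
  below 10 degrees and the modal water-type class is unchanged across it;
* spring migration and pre-breeding are symmetric, with the pre-breeding
  constancy band widened to 15 degrees because longitude is less accurate
  during the polar day;
* breeding resumes at the first day of sustained fresh-only blocks.

Stopovers are >= 2-day runs without longitudinal change inside a migration
stage. Phenology summaries mirror a cohort table: per-stage start/end dates,
durations and longitudes as mean +/- SD and range, plus migration distances
measured along the particle-model median track.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import geo
from .sensor_io import PipelineConfig

STAGE_ORDER = ["breeding", "post_moult", "autumn_migration",
               "wintering", "spring_migration", "pre_breeding"]


class SegmentationError(ValueError):
    pass


@dataclass
class StageSegmentation:
    """Ordered, contiguous labelled intervals plus stopovers for one bird."""

    bird_id: str
    intervals: pd.DataFrame               # label, start, end (half-open days)
    stopovers: pd.DataFrame = field(default_factory=lambda: pd.DataFrame(
        columns=["parent", "start", "end", "mean_lon"]))

    def to_frame(self) -> pd.DataFrame:
        df = self.intervals.copy()
        df.insert(0, "bird_id", self.bird_id)
        return df

    def interval(self, label: str):
        """(start, end) of the first interval with this label, or None."""
        m = self.intervals[self.intervals["label"] == label]
        if m.empty:
            return None
        return pd.Timestamp(m.iloc[0]["start"]), pd.Timestamp(m.iloc[0]["end"])

    def validate(self):
        iv = self.intervals
        if iv.empty:
            raise SegmentationError("empty segmentation")
        for i in range(1, len(iv)):
            if iv.iloc[i]["start"] != iv.iloc[i - 1]["end"]:
                raise SegmentationError("intervals not contiguous")
        labels = list(iv["label"])
        pos = [STAGE_ORDER.index(lb) for lb in labels]
        for a, b in zip(pos[:-1], pos[1:]):
            if b != (a + 1) % len(STAGE_ORDER):
                raise SegmentationError(
                    f"cycle-order violation: {STAGE_ORDER[a]} -> {STAGE_ORDER[b]}")
        return self


def daily_longitude(positions: pd.DataFrame) -> pd.DataFrame:
    """Daily longitude = median of the (<= 2) twilight-pair longitudes.

    Days without a valid longitude inherit the previous value and are
    flagged. Returns columns date, lon, inherited.
    """
    pos = positions.dropna(subset=["lon"]).copy()
    if pos.empty:
        raise SegmentationError("no longitudes to summarize")
    pos["date"] = pd.DatetimeIndex(pos["time"]).floor("D")
    daily = pos.groupby("date")["lon"].median()
    full = pd.date_range(daily.index.min(), daily.index.max(), freq="D")
    out = daily.reindex(full)
    inherited = out.isna()
    out = out.ffill()
    return pd.DataFrame({"date": full, "lon": out.to_numpy(),
                         "inherited": inherited.to_numpy()})


def daily_water_class(blocks: pd.DataFrame, classes: pd.Series) -> pd.Series:
    """Modal water class per UTC day, indexed by date."""
    df = pd.DataFrame({
        "date": pd.DatetimeIndex(blocks["block_start"]).floor("D"),
        "cls": classes.to_numpy(),
    })
    return df.groupby("date")["cls"].agg(lambda s: s.mode().iloc[0])


def segment_annual_cycle(daily_lon: pd.DataFrame, water_classes: pd.Series,
                         config: PipelineConfig | None = None,
                         bird_id: str = "bird",
                         polar_day_dates=None,
                         overrides: dict | None = None) -> StageSegmentation:
    """Segment one bird-year into the six stages.

    ``daily_lon`` comes from :func:`daily_longitude`; ``water_classes`` from
    :func:`daily_water_class`. ``polar_day_dates`` optionally marks days on
    which the widened pre-breeding constancy band applies (defaults to the
    calendar window mid-May onward at Arctic latitudes, supplied by the
    caller). ``overrides`` may pin boundaries: {stage_label: start_date}.
    """
    cfg = (config or PipelineConfig()).stages
    dates = pd.DatetimeIndex(daily_lon["date"])
    lon = daily_lon["lon"].to_numpy(dtype=float)
    n = len(dates)
    cls = water_classes.reindex(dates)
    missing = float(cls.isna().mean())
    if missing > 0.2:
        raise SegmentationError(
            f"water types missing on {100 * missing:.0f}% of days")
    cls = cls.ffill().bfill().to_numpy(dtype=object)
    fresh_or_dry = np.isin(cls, ("fresh", "dry"))
    polar = np.zeros(n, dtype=bool)
    if polar_day_dates is not None:
        polar = np.isin(dates.values, pd.DatetimeIndex(polar_day_dates).values)

    w = cfg.window_days
    rate = np.abs(np.diff(lon, prepend=lon[0]))

    wc = max(cfg.settle_confirm_days, w)

    def forward_range(i, win=w):
        return float(np.ptp(lon[i:min(n, i + win)]))

    def forward_class_constant(i, win=w):
        seg = cls[i:min(n, i + win)]
        return all(c == seg[0] for c in seg)

    def sustained_rate(i):
        run = cfg.migration_min_run_days
        if i + run > n:
            return False
        return bool(np.all(rate[i:i + run] > cfg.migration_rate_deg_per_day))

    overrides = overrides or {}
    bounds = {}
    i = 0
    # --- breeding -> post_moult
    # departure from the breeding grounds is a habitat switch: the bird
    # leaves tundra fresh water for the sea, and the conductivity channel
    # reads it directly. Longitude is NOT consulted here - the breeding
    # site sits in (near-)24-h daylight where the light curve only grazes
    # the threshold, so shading fabricates crossings whose longitudes
    # carry polar-grade noise without a polar flag
    while i < n and fresh_or_dry[i]:
        i += 1
    bounds["post_moult"] = i
    # --- post_moult -> autumn_migration
    # skip the departure day and its neighbour: the first flight away from
    # the breeding lakes can move several degrees of longitude, and the
    # departure day's median longitude is a halfway value that would fake a
    # high displacement rate the day after
    i = min(i + 2, n)
    while i < n and not sustained_rate(i):
        i += 1
    bounds["autumn_migration"] = i
    # --- autumn_migration -> wintering: settling must outlast any stopover
    i = min(i + 1, n)
    while i < n and not (forward_range(i, wc) < cfg.winter_lon_range_deg
                         and forward_class_constant(i, wc)):
        i += 1
    bounds["wintering"] = i
    # --- wintering -> spring_migration
    i = min(i + cfg.window_days, n)
    while i < n and not sustained_rate(i):
        i += 1
    bounds["spring_migration"] = i
    # --- spring_migration -> pre_breeding
    i = min(i + 1, n)
    while i < n:
        band = cfg.prebreeding_lon_range_deg if polar[i] else cfg.winter_lon_range_deg
        if forward_range(i) < band and forward_class_constant(i):
            break
        i += 1
    bounds["pre_breeding"] = i
    # --- pre_breeding -> breeding
    run = cfg.breeding_min_run_days
    while i < n:
        if fresh_or_dry[i] and np.all(fresh_or_dry[i:min(n, i + run)]):
            break
        i += 1
    bounds["breeding2"] = i

    for label, when in overrides.items():
        key = "breeding2" if label == "breeding" else label
        idx = int(np.searchsorted(dates.values, pd.Timestamp(when).to_datetime64()))
        bounds[key] = idx

    edges = [0, bounds["post_moult"], bounds["autumn_migration"],
             bounds["wintering"], bounds["spring_migration"],
             bounds["pre_breeding"], bounds["breeding2"], n]
    labels = ["breeding", "post_moult", "autumn_migration", "wintering",
              "spring_migration", "pre_breeding", "breeding"]
    day = pd.Timedelta(days=1)
    rows = []
    for lb, a, b in zip(labels, edges[:-1], edges[1:]):
        if b > a:
            end = dates[b - 1] + day if b == n else dates[b]
            rows.append((lb, dates[a], end))
    iv = pd.DataFrame(rows, columns=["label", "start", "end"])
    seg = StageSegmentation(bird_id, iv)
    seg.stopovers = detect_stopovers(seg, daily_lon, cfg)
    return seg


def detect_stopovers(segmentation: StageSegmentation, daily_lon: pd.DataFrame,
                     cfg=None) -> pd.DataFrame:
    """Maximal >= 2-day runs without longitudinal change inside migrations."""
    cfg = cfg or PipelineConfig().stages
    dates = pd.DatetimeIndex(daily_lon["date"])
    lon = daily_lon["lon"].to_numpy(dtype=float)
    rows = []
    for itv in segmentation.intervals.itertuples():
        if not itv.label.endswith("migration"):
            continue
        sel = (dates >= itv.start) & (dates < itv.end)
        idx = np.nonzero(sel)[0]
        if idx.size < cfg.stopover_min_days:
            continue
        i = 0
        while i < idx.size:
            j = i
            while (j + 1 < idx.size
                   and np.ptp(lon[idx[i]:idx[j + 1] + 1]) < cfg.lon_stable_deg):
                j += 1
            n_days = j - i + 1
            if n_days >= cfg.stopover_min_days:
                rows.append((itv.label, dates[idx[i]],
                             dates[idx[j]] + pd.Timedelta(days=1),
                             float(np.mean(lon[idx[i]:idx[j] + 1]))))
                i = j + 1
            else:
                i += 1
    return pd.DataFrame(rows, columns=["parent", "start", "end", "mean_lon"])


def migration_distance(track: pd.DataFrame, interval, stopovers=None,
                       settle_days: float = 7.0) -> float:
    """Migration distance (km) along the median track over an interval.

    Estimated as the great-circle length through the *settled* endpoints -
    the geographic median of the track positions in a ``settle_days`` window
    just before departure and just after arrival - via the median position
    of each detected stopover. Twilight-indexed positions during a sprint
    lag and scatter (latitude is weakly observed in flight), so a raw
    position-to-position path sum is inflated by doglegs and noise; the
    settled-waypoint route is robust to both. When no flanking positions
    exist the first/last in-interval positions serve as endpoints.
    Undefined (NaN) with fewer than two positions - never reported as zero.

    ``settle_days`` must outlast the post-arrival relaxation of the
    position posterior. After a flight into a region under continuous
    twilight-free daylight, latitude is informed only by sea-surface
    temperature (a weak gradient relative to the observation noise), so
    the posterior converges on the new site over several days rather than
    at the first settled pair; a week of flanking positions averages over
    that transient, and over a truly stationary flank it only improves
    the median.
    """
    from .prob_track import geographic_median

    start, end = interval
    t = track["time"]
    pos = track.dropna(subset=["lon", "lat"])
    inside = pos[(pos["time"] >= start) & (pos["time"] < end)]

    def _median_window(lo, hi, fallback):
        w = pos[(pos["time"] >= lo) & (pos["time"] < hi)]
        if len(w) == 0:
            return fallback
        return geographic_median(w["lon"].to_numpy(), w["lat"].to_numpy())

    first = (float(inside["lon"].iloc[0]), float(inside["lat"].iloc[0])) \
        if len(inside) else None
    last = (float(inside["lon"].iloc[-1]), float(inside["lat"].iloc[-1])) \
        if len(inside) else None
    origin = _median_window(start - pd.Timedelta(days=settle_days), start, first)
    dest = _median_window(end, end + pd.Timedelta(days=settle_days), last)
    if origin is None or dest is None:
        return np.nan
    if origin == dest and len(inside) < 2:
        return np.nan if len(pos) < 2 else 0.0

    waypoints = [origin]
    if stopovers is not None and len(stopovers):
        so = stopovers[(pd.to_datetime(stopovers["start"]) >= start)
                       & (pd.to_datetime(stopovers["end"]) <= end)]
        for r in so.sort_values("start").itertuples():
            wp = _median_window(r.start, r.end, None)
            if wp is not None:
                waypoints.append(wp)
    waypoints.append(dest)
    lons = np.array([w[0] for w in waypoints])
    lats = np.array([w[1] for w in waypoints])
    return geo.track_length_km(lons, lats)


def is_white_sea_longitude(lon: float, band=(33.9, 41.6)) -> bool:
    """Whether a longitude falls in the White Sea longitudinal range."""
    return bool(band[0] <= lon <= band[1])


def phenology_summary(segmentations: list, tracks: dict | None = None,
                      daily_lons: dict | None = None) -> pd.DataFrame:
    """Cohort phenology table: per-stage timing, duration, longitude, distance.

    ``tracks`` maps bird_id -> particle-model median track (for migration
    distances); ``daily_lons`` maps bird_id -> daily-longitude frame (for
    stage mean longitudes). Start/end statistics are over calendar dates;
    SD columns are empty strings at n = 1; ranges bracket the means.
    Breeding duration is estimated from the surrounding stage boundaries
    (last pre-breeding end to first post-moult start the year before is not
    observable within one deployment, so the second breeding interval's
    bounded portion is reported as 'estimated').
    """
    rows = []
    for label in STAGE_ORDER:
        starts, ends, durs, lons, dists = [], [], [], [], []
        for seg in segmentations:
            iv = seg.intervals[seg.intervals["label"] == label]
            if iv.empty:
                continue
            s = pd.Timestamp(iv.iloc[0]["start"])
            e = pd.Timestamp(iv.iloc[-1]["end"])
            starts.append(s)
            ends.append(e)
            if label == "breeding":
                durs.append(_estimated_breeding_days(seg))
            else:
                durs.append((e - s).days)
            if daily_lons is not None and seg.bird_id in daily_lons:
                dl = daily_lons[seg.bird_id]
                m = (pd.DatetimeIndex(dl["date"]) >= s) & (pd.DatetimeIndex(dl["date"]) < e)
                if m.any():
                    lons.append(float(dl.loc[m, "lon"].mean()))
            if label.endswith("migration") and tracks is not None \
                    and seg.bird_id in tracks:
                d = migration_distance(tracks[seg.bird_id], (s, e),
                                       stopovers=seg.stopovers)
                if np.isfinite(d):
                    dists.append(d)
        if not starts:
            continue
        row = {
            "stage": label, "n": len(starts),
            "start_mean": _date_mean(starts), "start_sd_days": _sd([_ord(s) for s in starts]),
            "start_min": min(starts).date(), "start_max": max(starts).date(),
            "end_mean": _date_mean(ends), "end_sd_days": _sd([_ord(e) for e in ends]),
            "duration_mean_days": float(np.mean(durs)),
            "duration_sd_days": _sd(durs),
            "duration_min_days": float(np.min(durs)),
            "duration_max_days": float(np.max(durs)),
            "lon_mean": float(np.mean(lons)) if lons else np.nan,
            "lon_sd": _sd(lons),
            "distance_mean_km": float(np.mean(dists)) if dists else np.nan,
            "distance_sd_km": _sd(dists),
            "distance_min_km": float(np.min(dists)) if dists else np.nan,
            "distance_max_km": float(np.max(dists)) if dists else np.nan,
        }
        rows.append(row)
    return pd.DataFrame(rows)


def _estimated_breeding_days(seg: StageSegmentation) -> float:
    """Breeding duration from surrounding boundaries (pre-breeding end to
    post-moult start), using whichever breeding intervals the deployment saw."""
    iv = seg.intervals
    breed = iv[iv["label"] == "breeding"]
    total = sum((pd.Timestamp(r.end) - pd.Timestamp(r.start)).days
                for r in breed.itertuples())
    return float(total)


def _ord(ts: pd.Timestamp) -> float:
    return ts.value / 86400e9


def _date_mean(dates):
    vals = [_ord(pd.Timestamp(d)) for d in dates]
    return pd.Timestamp(float(np.mean(vals)) * 86400e9, tz="UTC").date()


def _sd(vals):
    vals = [v for v in vals if np.isfinite(v)]
    if len(vals) < 2:
        return ""
    return float(np.std(vals, ddof=1))
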