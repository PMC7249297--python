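"""Twilight assignment from stored light series.

Sunrise/sunset events are placed at linearly interpolated threshold
crossings of the 5-min light series. Quality control marks events as
``ambiguous`` when more than one crossing of the same sign occurs within a
4-h window (shading artefacts); validation keeps only unequivocal events,
with a user-supplied override list applied last.

During the polar day (24-h light) no crossing exists; a sunrise+sunset pair
is emitted at the estimated local midnight, located from the daily minimum
of the light curve (centroid of the dip) inside a window centred on the
midnight implied by the most recent 7-day median longitude, falling back to
the deployment-site longitude when no recent longitude exists.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .threshold_geo import longitude_from_transit, solar_ephemeris

log = logging.getLogger(__name__)

TW_COLUMNS = ["time", "kind", "quality", "polar_day"]
QC_WINDOW_H = 4.0


class ThresholdError(ValueError):
    """Light threshold incompatible with the recorded light range."""


def detect_twilights(light: pd.DataFrame, threshold: float,
                     deploy_lon: float = 0.0,
                     qc_window_h: float = QC_WINDOW_H,
                     max_recording_halfwidth_min: float = 2.0) -> pd.DataFrame:
    """Detect sunrise/sunset events (and polar-day midnight pairs).

    ``light`` has columns timestamp (UTC) and light; ``threshold`` is on the
    stored light scale. Returns a DataFrame with columns time, kind
    ('sunrise'/'sunset'), quality ('ok'/'ambiguous'), polar_day (bool).

    ``max_recording_halfwidth_min`` corrects for max-over-window recording:
    a stored maximum samples the end of its window on a rising edge and the
    start on a falling edge, so sunrise crossings are shifted late and
    sunset crossings early by the stamp-to-edge half-width (2 min for
    5-min maxima of per-minute readings stamped at the window centre).
    """
    if light.empty:
        raise ValueError("light series is empty")
    t = pd.DatetimeIndex(pd.to_datetime(light["timestamp"], utc=True))
    v = light["light"].to_numpy(dtype=float)
    tns = t.view("int64")

    above = v >= threshold
    flip = above[:-1] != above[1:]
    contiguous = np.diff(tns) <= 301e9          # don't interpolate across gaps
    idx = np.nonzero(flip & contiguous)[0]
    times = []
    kinds = []
    shift_ns = max_recording_halfwidth_min * 60e9
    for i in idx:
        dv = v[i + 1] - v[i]
        fr = 0.5 if dv == 0 else (threshold - v[i]) / dv
        tc = tns[i] + fr * (tns[i + 1] - tns[i])
        if above[i + 1]:
            times.append(tc + shift_ns)
            kinds.append("sunrise")
        else:
            times.append(tc - shift_ns)
            kinds.append("sunset")
    events = pd.DataFrame({
        "time": pd.to_datetime(np.asarray(times, dtype="int64"), utc=True),
        "kind": kinds,
    })
    events["quality"] = "ok"
    events["polar_day"] = False

    # --- threshold sanity: outside the observed light range on most days
    local_day = _local_day(t, deploy_lon)
    daily = pd.DataFrame({"day": local_day, "v": v}).groupby("day")["v"]
    dmin, dmax = daily.min(), daily.max()
    # a day entirely ABOVE the threshold is legitimate polar day; a threshold
    # the light never reaches is a mis-set calibration
    frac_dark = float((dmax < threshold).mean()) if len(dmax) else 0.0
    if frac_dark > 0.5:
        raise ThresholdError(
            f"threshold {threshold} above the observed light range on "
            f"{100 * frac_dark:.0f}% of days")

    # --- QC: repeated same-sign crossings within the window
    ev_ns = pd.DatetimeIndex(events["time"]).view("int64")
    amb = np.zeros(len(events), dtype=bool)
    for kind in ("sunrise", "sunset"):
        ki = np.nonzero((events["kind"] == kind).to_numpy())[0]
        kt = ev_ns[ki]
        close = np.diff(kt) < qc_window_h * 3600e9
        for j, c in enumerate(close):
            if c:
                amb[ki[j]] = amb[ki[j + 1]] = True
    events.loc[amb, "quality"] = "ambiguous"

    # --- polar-day pairs
    polar = _polar_day_events(t, v, tns, threshold, events, deploy_lon)
    if len(polar):
        events = pd.concat([events, polar], ignore_index=True)
    events = events.sort_values("time", kind="stable").reset_index(drop=True)
    return events[TW_COLUMNS]


def _local_day(t: pd.DatetimeIndex, ref_lon: float) -> np.ndarray:
    """Noon-to-noon local-day label so each window holds one local midnight."""
    shifted = t + pd.Timedelta(hours=ref_lon / 15.0 - 12.0)
    return shifted.floor("D").values


def _polar_day_events(t, v, tns, threshold, events, deploy_lon):
    local_day = _local_day(t, deploy_lon)
    df = pd.DataFrame({"day": local_day, "v": v, "tns": tns})
    day_min = df.groupby("day")["v"].min()
    crossing_days = set(_local_day(pd.DatetimeIndex(events["time"]), deploy_lon))
    polar_days = [d for d in day_min.index
                  if day_min.loc[d] >= threshold and d not in crossing_days]
    if not polar_days:
        return pd.DataFrame(columns=TW_COLUMNS)

    # provisional longitudes from ordinary day pairs, for the search window
    lons = _pair_longitudes(events)
    rows = []
    for d in polar_days:
        # centre of the noon-to-noon window labelled d (see _local_day)
        centre = pd.Timestamp(d, tz="UTC") + pd.Timedelta(hours=36.0 - deploy_lon / 15.0) \
            - pd.Timedelta(hours=12.0)
        ref_lon = _recent_lon(lons, centre, deploy_lon)
        approx_mid = _approx_midnight_utc(centre, ref_lon)
        sel = (tns >= (approx_mid - pd.Timedelta(hours=5)).value) \
            & (tns < (approx_mid + pd.Timedelta(hours=5)).value)
        if not sel.any():
            continue
        vv = v[sel]
        tt = tns[sel]
        # median-smooth so a single shading-attenuated sample cannot fake a
        # midnight dip; shallow dips bottom out in a wide plateau of equal
        # integer values, so centre on the plateau rather than its first cell
        sm = pd.Series(vv).rolling(7, center=True, min_periods=1).median().to_numpy()
        plateau = np.nonzero(sm <= sm.min() + 0.5)[0]
        t_min = float(np.median(tt[plateau]))
        near = np.abs(tt - t_min) <= 90 * 60e9
        w = (sm.max() - sm) * near
        if w.sum() > 0:
            mid_ns = float(np.sum(w * tt) / np.sum(w))
        else:
            mid_ns = float(approx_mid.value)   # saturated flat curve
        mid = pd.to_datetime(np.int64(mid_ns), utc=True)
        for kind in ("sunrise", "sunset"):
            rows.append((mid, kind, "ok", True))
    return pd.DataFrame(rows, columns=TW_COLUMNS)


def _pair_longitudes(events: pd.DataFrame) -> pd.DataFrame:
    """(time, lon) from consecutive sunrise->sunset day pairs."""
    ev = events.sort_values("time").reset_index(drop=True)
    out = []
    for i in range(len(ev) - 1):
        a, b = ev.iloc[i], ev.iloc[i + 1]
        if a.kind == "sunrise" and b.kind == "sunset":
            dt_h = (b.time - a.time).total_seconds() / 3600.0
            if 0 < dt_h < 24:
                mid = a.time + (b.time - a.time) / 2
                out.append((mid, longitude_from_transit(mid, "noon")))
    return pd.DataFrame(out, columns=["time", "lon"])


def _recent_lon(lons: pd.DataFrame, when: pd.Timestamp, deploy_lon: float) -> float:
    if len(lons):
        recent = lons[(lons["time"] >= when - pd.Timedelta(days=7))
                      & (lons["time"] <= when + pd.Timedelta(days=1))]
        if len(recent) == 0:
            recent = lons[lons["time"] < when].tail(14)
        if len(recent):
            return float(np.median(recent["lon"]))
    return deploy_lon


def _approx_midnight_utc(near: pd.Timestamp, lon: float) -> pd.Timestamp:
    """UTC time of local solar midnight closest to ``near`` at longitude lon."""
    _, eot = solar_ephemeris(near)
    h_utc = near.hour + near.minute / 60.0 + near.second / 3600.0
    h_local = (h_utc + lon / 15.0 + eot[0] / 60.0) % 24.0
    delta = ((-h_local + 12.0) % 24.0) - 12.0
    return near + pd.Timedelta(hours=float(delta))


def validate_twilights(events: pd.DataFrame, overrides=None) -> pd.DataFrame:
    """Keep only unequivocal events; apply keep/drop overrides last.

    ``overrides`` is an iterable of dicts {'time': ts, 'action': 'keep'|'drop'};
    'keep' restores a flagged event at that time (within 5 min), 'drop'
    removes an event. The number of removals is logged.
    """
    ev = events.copy()
    keep_mask = ev["quality"] != "ambiguous"
    n_removed = int((~keep_mask).sum())
    out = ev[keep_mask].copy()
    if n_removed:
        log.info("validate_twilights: removed %d ambiguous events", n_removed)
        if out.empty:
            log.warning("validate_twilights: all events were ambiguous")

    for ov in overrides or []:
        when = pd.to_datetime(ov["time"], utc=True)
        tol = pd.Timedelta(minutes=5)
        if ov["action"] == "keep":
            cand = ev[(ev["time"] - when).abs() <= tol]
            out = pd.concat([out, cand], ignore_index=True).drop_duplicates(
                subset=["time", "kind"])
        elif ov["action"] == "drop":
            out = out[(out["time"] - when).abs() > tol]
        else:
            raise ValueError(f"unknown override action {ov['action']!r}")
    return out.sort_values("time", kind="stable").reset_index(drop=True)
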