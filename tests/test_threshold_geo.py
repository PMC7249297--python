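import numpy as np
import pandas as pd
import pytest

from ducktrack import threshold_geo as tg
from ducktrack import synthetic_data as sd
from tests.conftest import THRESHOLD


# ---------------------------------------------------------------------------
# independent solar oracle: Astronomical Almanac low-precision algorithm
# (Michalsky-style), a different formulation from the implementation's
# NOAA-style declination + equation of time


def almanac_elevation(when, lon, lat):
    t = pd.Timestamp(when)
    jd = t.to_julian_date()
    n = jd - 2451545.0
    L = (280.460 + 0.9856474 * n) % 360.0
    g = np.radians((357.528 + 0.9856003 * n) % 360.0)
    lam = np.radians(L + 1.915 * np.sin(g) + 0.020 * np.sin(2 * g))
    eps = np.radians(23.439 - 0.0000004 * n)
    ra = np.degrees(np.arctan2(np.cos(eps) * np.sin(lam), np.cos(lam))) % 360.0
    dec = np.arcsin(np.sin(eps) * np.sin(lam))
    ut_hours = t.hour + t.minute / 60.0 + t.second / 3600.0
    gmst = (6.697375 + 0.0657098242 * (jd - 2451545.0 - ut_hours / 24.0)
            + 1.0027379093 * ut_hours) % 24.0
    lmst = (gmst + lon / 15.0) % 24.0
    ha = np.radians(((lmst * 15.0 - ra) + 180.0) % 360.0 - 180.0)
    phi = np.radians(lat)
    sin_el = np.sin(phi) * np.sin(dec) + np.cos(phi) * np.cos(dec) * np.cos(ha)
    return float(np.degrees(np.arcsin(np.clip(sin_el, -1, 1))))


def test_solar_elevation_matches_independent_almanac_oracle():
    rng = np.random.default_rng(0)
    worst = 0.0
    for _ in range(60):
        day = rng.integers(0, 700)
        when = pd.Timestamp("2017-01-01", tz="UTC") + pd.Timedelta(
            days=int(day), hours=float(rng.uniform(0, 24)))
        lon = float(rng.uniform(-180, 180))
        lat = float(rng.uniform(-80, 80))
        mine, _ = tg.solar_position(when, lon, lat)
        worst = max(worst, abs(mine - almanac_elevation(when, lon, lat)))
    assert worst < 0.2


def test_equator_equinox_noon_near_zenith():
    elev, _ = tg.solar_position("2018-03-20 12:07:00+00:00", 0.0, 0.0)
    assert elev > 89.5


def test_midnight_sun_at_capture_site():
    # 69.138 N: the sun stays up at local midnight around the June solstice
    elev, _ = tg.solar_position("2018-06-21 20:45:00+00:00", 48.848, 69.138)
    assert elev > 0.0


def test_elevation_slowly_varying_day_to_day():
    t0 = pd.Timestamp("2018-01-20 10:00:00+00:00")
    e1, _ = tg.solar_position(t0, 21.0, 58.0)
    e2, _ = tg.solar_position(t0 + pd.Timedelta(hours=24), 21.0, 58.0)
    assert abs(e1 - e2) < 1.0


# ---------------------------------------------------------------------------
# latitude inversion


def test_latitude_inversion_agrees_with_brute_force_scan():
    rng = np.random.default_rng(1)
    lat_grid = np.arange(-85.0, 85.0 + 1e-9, 0.1)
    n_checked = 0
    for _ in range(100):
        when = pd.Timestamp("2017-07-01", tz="UTC") + pd.Timedelta(
            days=float(rng.uniform(0, 365)))
        dec, _ = tg.solar_ephemeris(when)
        dec = float(dec[0])
        lat_true = float(rng.uniform(-65, 70))
        angle = float(rng.uniform(-9.5, -1.0))
        obs = float(tg.day_length_hours(lat_true, dec, angle))
        if obs <= 0.5 or obs >= 23.5:
            continue
        lat_hat, resid = tg.latitude_from_day_length(obs, dec, angle)
        prof = tg.day_length_hours(lat_grid, dec, angle)
        # the implementation's documented convention: northern branch of a
        # U-shaped equinox profile; restrict the brute scan identically
        i0 = int(np.argmin(prof))
        u_shaped = (0 < i0 < len(lat_grid) - 1
                    and prof[i0] < prof[0] - 1e-9 and prof[i0] < prof[-1] - 1e-9)
        branch = slice(i0, None) if u_shaped else slice(None)
        mism = np.abs(prof[branch] - obs)
        lat_brute = lat_grid[branch][int(np.argmin(mism))]
        if not np.isfinite(lat_hat):
            # degenerate: either no branch latitude fits, or day length is
            # locally insensitive to latitude (the 0.5 min/deg cutoff)
            jb = int(np.argmin(mism))
            lat_b = lat_grid[branch][jb]
            l1, l2 = max(lat_b - 1, -85.0), min(lat_b + 1, 85.0)
            sens = abs(float(tg.day_length_hours(l2, dec, angle))
                       - float(tg.day_length_hours(l1, dec, angle))) \
                / (l2 - l1) * 60.0
            assert np.min(mism) * 60.0 > 5.0 or sens < 0.5
            continue
        n_checked += 1
        assert abs(lat_hat - lat_brute) < 0.15
        # and the found latitude fits the observation as well as the scan
        assert abs(tg.day_length_hours(lat_hat, dec, angle) - obs) * 60.0 \
            <= np.min(mism) * 60.0 + 0.5
    assert n_checked > 60


def test_position_from_pair_recovers_forward_simulated_site():
    # brute-force minute scan of the solar oracle at the solstice
    lon_t, lat_t, angle = 0.0, 0.0, -6.0
    mins = pd.date_range("2017-12-21", "2017-12-22", freq="1min", tz="UTC")
    elev, _ = tg.solar_position(mins, lon_t, lat_t)
    up = elev > angle
    rises = np.nonzero(~up[:-1] & up[1:])[0]
    sets = np.nonzero(up[:-1] & ~up[1:])[0]
    sr, ss = mins[rises[0] + 1], mins[sets[0] + 1]
    if ss < sr:
        ss = mins[sets[1] + 1]
    est = tg.position_from_pair(sr, ss, angle)
    assert est["lat_flag"] == tg.LAT_FLAG_OK
    assert abs(est["lon"] - lon_t) < 0.5
    assert abs(est["lat"] - lat_t) < 1.0
    # time/longitude equivalence: +1 h on both twilights -> -15 deg, same lat
    est2 = tg.position_from_pair(sr + pd.Timedelta(hours=1),
                                 ss + pd.Timedelta(hours=1), angle)
    assert est2["lon"] - est["lon"] == pytest.approx(-15.0, abs=0.05)
    assert est2["lat"] == pytest.approx(est["lat"], abs=0.05)


def test_equinox_day_length_flags_latitude_undefined():
    sr = pd.Timestamp("2018-03-20 06:00:00+00:00")
    est = tg.position_from_pair(sr, sr + pd.Timedelta(hours=12), angle=-0.3)
    assert est["lat_flag"] == tg.LAT_FLAG_EQUINOX
    assert np.isnan(est["lat"])


def test_pair_longer_than_day_rejected():
    sr = pd.Timestamp("2018-01-01 08:00:00+00:00")
    with pytest.raises(ValueError, match="24"):
        tg.position_from_pair(sr, sr + pd.Timedelta(hours=30), angle=-3.5)


def test_polar_pair_gives_longitude_only():
    mid = pd.Timestamp("2017-06-21 20:45:00+00:00")
    est = tg.position_from_pair(mid, mid, angle=-3.5, polar_day=True)
    assert est["lat_flag"] == tg.LAT_FLAG_POLAR
    assert np.isnan(est["lat"])
    assert abs(est["lon"] - 48.5) < 5.0   # local midnight ~48 E


# ---------------------------------------------------------------------------
# calibrations


def test_known_site_calibration_recovers_truth(rooftop):
    cal = tg.calibrate_known_site(rooftop["events"], 9.0, 50.5)
    truth = sd.sun_angle_for_threshold(THRESHOLD)
    assert cal.method == "known_site"
    assert cal.angle == pytest.approx(truth, abs=0.2)
    # plausibility band for this logger class on real birds
    assert -12.0 < cal.angle < 3.0


def test_known_site_calibration_stable_under_more_days(rooftop):
    ev = rooftop["events"]
    half = ev[ev["time"] < ev["time"].min() + pd.Timedelta(days=9)]
    a_half = tg.calibrate_known_site(half, 9.0, 50.5).angle
    a_full = tg.calibrate_known_site(ev, 9.0, 50.5).angle
    assert abs(a_half - a_full) < 0.1


def test_known_site_needs_seven_days(rooftop):
    ev = rooftop["events"]
    short = ev[ev["time"] < ev["time"].min() + pd.Timedelta(days=4)]
    with pytest.raises(tg.CalibrationError):
        tg.calibrate_known_site(short, 9.0, 50.5)


def test_hill_ekstrom_recovers_truth_with_unimodal_profile(winter_stationary):
    tr = winter_stationary["truth"]
    cal = tg.calibrate_hill_ekstrom(
        winter_stationary["events"],
        (tr["timestamp"].iloc[0], tr["timestamp"].iloc[-1]))
    truth = sd.sun_angle_for_threshold(THRESHOLD)
    assert cal.angle == pytest.approx(truth, abs=0.25)
    prof = cal.diagnostics["variance_profile"]
    best = int(np.nanargmin(prof))
    left = prof[max(0, best - 8):best + 1]
    right = prof[best:best + 9]
    assert np.all(np.diff(left[np.isfinite(left)]) < 0)
    assert np.all(np.diff(right[np.isfinite(right)]) > 0)


def test_hill_ekstrom_requires_long_window(winter_stationary):
    tr = winter_stationary["truth"]
    t0 = tr["timestamp"].iloc[0]
    with pytest.raises(tg.CalibrationError):
        tg.calibrate_hill_ekstrom(winter_stationary["events"],
                                  (t0, t0 + pd.Timedelta(days=20)))


def test_year_round_longitude_unbiased(year_stationary):
    pos = tg.positions_from_twilights(year_stationary["events"],
                                      sd.sun_angle_for_threshold(THRESHOLD))
    err = pos["lon"].to_numpy() - 21.0
    assert abs(np.mean(err)) < 0.5
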