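# Methods note

`ducktrack` reconstructs the annual cycle of a sea duck from an archival
light-level geolocator that also records wet/dry state, conductivity and
water temperature. This note describes the model, its assumptions, the
parameters and their defaults, what the bundled synthetic-data generator
does and does not emulate, and the numerical choices that matter.

## 1. Sensor model

The logger measures light on an arbitrary 0–255 scale once per minute and
stores the **maximum over each 5-minute window**. Conductivity,
temperature and wet/dry state are summarized over 4-hour blocks: maximum
conductivity, minimum/mean/maximum temperature, and the number of wet
seconds (`wet_sum`, out of a 480-count sampling schedule).

The max-recording scheme biases threshold crossings: on a rising light
curve the stored value is dominated by the **end** of its window, on a
falling curve by the **start**. The twilight detector therefore shifts
interpolated sunrise crossings later and sunset crossings earlier by half
the recording interval (2 min by default, `max_recording_halfwidth_min`).
Without this correction longitudes carry a constant bias of about half a
degree and apparent day length is systematically long.

## 2. Threshold geolocation

Twilights are the times the light trace crosses `light_threshold`
(default 6.375, i.e. 2.5 % of the full scale). Each consecutive
sunrise/sunset pair yields one position:

- **Longitude** from the mid-time of the pair, which estimates local solar
  noon (or midnight): `lon = -15°/h · (t_transit − t_utc_noon)`, with the
  equation of time from a NOAA/Meeus-style solar ephemeris (declination
  accurate to ~0.01°, equation of time to seconds).
- **Latitude** by inverting observed day length at a calibrated
  sun-elevation angle using the standard hour-angle relation
  `cos H = (sin a − sin φ sin δ) / (cos φ cos δ)`.

### Northern-branch convention

For the negative sun angles of archival tags the day-length-vs-latitude
profile is **U-shaped** near the equinoxes: day length exceeds 12 h at
both poles, so a given day length can have two roots. The inverter takes
the **northern branch** (poleward of the profile minimum), which is
correct for the Arctic/Baltic domain this package targets; the convention
is explicit and tested. A strict-U test (interior minimum strictly below
both ends) prevents polar-night/polar-day plateaus from being mistaken
for a branch point.

### Identifiability limits

Latitude is reported as undefined (NaN, flag `equinox_undefined`) when
the sensitivity of day length to latitude falls below 0.5 min/deg — near
the equinoxes a timing error of minutes would otherwise map to tens of
degrees. Pairs under continuous daylight get flag `polar`; their
longitude comes from the night-time dip of the smoothed light curve
(rolling median over 7 samples, plateau-centred minimum), their latitude
from the movement prior downstream.

## 3. Calibration of the sun-elevation angle

Three alternatives, all returning a `SunAngleCalibration`:

- **Known-site** (`calibrate_known_site`): the median solar elevation at
  the observed threshold crossings while the tag sits at a known
  longitude/latitude (≥ 7 days required).
- **Fixed**: a conventional −3.5°.
- **Hill–Ekström** (`calibrate_hill_ekstrom`): over a stationary window
  (≥ 30 days), choose the angle (grid −10°…0°, step 0.25°) minimizing the
  variance of derived latitudes; days with |solar declination| < 6° are
  trimmed because equinox day lengths carry no latitude information. The
  variance profile is exposed for unimodality checks.

## 4. Probabilistic track model (particle filter)

`run_prob_track` fits a sequential Monte Carlo model in the spirit of
iterative prior-informed geolocation. Per twilight pair, for each of
`n_particles` (default 400):

- **Proposal**: twilight times perturbed with `twilight_sd_min` = 6 min;
  longitude from the perturbed transit; latitude by inverting the
  perturbed day length at the particle's own sun-elevation angle. Each
  particle carries a **persistent angle** (initialized uniformly on
  `angle_band` = [−10°, −1°], jittered by 0.1° per step): the effective
  angle is a quasi-static property of tag and habit (shading), so it is
  learned during well-constrained periods and retained through gaps.
- **Equinox guard**: latitude follows the movement prior instead of the
  day-length inversion when |solar declination| < 6°
  (`equinox_dec_deg`) or when the ±1σ timing perturbation maps to more
  than `lat_info_cap_deg` = 8° of latitude. Near the equinoxes the
  inversion's sensitivity collapses and asymmetric shading error becomes
  a systematic latitude excursion; this mirrors the Hill–Ekström trim.
- **Flight rule**: an interval mostly dry (`wet_frac` < 0.3) violates the
  at-rest assumption behind day-length latitude, so latitude follows the
  movement prior there too.
- **Weights**: (i) a speed mixture — truncated log-normal components for
  dry flight (mode 15, max 25 m/s) and wet drift (mode 0.5, max 2 m/s)
  mixed by the interval's wet fraction; (ii) a Gaussian sea-surface
  temperature term (σ = `sst_tolerance` = 1 °C) comparing logged wet
  temperature with the world's SST field; (iii) habitat: wet particles
  cannot sit on land or ice; (iv) the **conductivity extension** —
  logged conductivity classifies the interval as fresh (< 10), brackish
  (10–60) or marine (≥ 60), and in `hard` mode particles in the wrong
  water-type cell get zero weight (`soft` down-weights by
  `soft_mismatch_weight`; `off` disables).
- **Resampling**: systematic, every step. If all weights vanish the
  proposal is retried up to `max_retries` times with inflated noise;
  a still-degenerate step carries the previous cloud forward with flag
  `degenerate` rather than aborting mid-track.

Point estimates per pair are the geographic (great-circle Weiszfeld)
median of the cloud.

## 5. Annual-cycle segmentation

`segment_annual_cycle` runs a forward state machine over daily median
longitudes and daily modal water classes:

- **breeding** holds while the daily modal water class stays
  fresh-water-or-dry: departure is a habitat switch to the sea that the
  conductivity channel reads directly. Longitude is deliberately not
  consulted — at the breeding latitude the light curve only grazes the
  threshold, so shading fabricates crossings whose longitudes carry
  polar-grade noise without a polar flag;
- **autumn/spring migration** start when the day-over-day longitude rate
  exceeds `migration_rate_deg_per_day` = 3°/day for
  `migration_min_run_days`; the autumn search begins 2 days after the
  post-moult stage starts, so departure-day half-way positions cannot
  trigger it;
- **wintering** begins when a forward window of `settle_confirm_days`
  = 10 days keeps a longitude range under `winter_lon_range_deg` = 10°
  with a constant modal water class — long enough to outlast week-scale
  stopovers;
- **stopovers** are ≥ `stopover_min_days` = 2-day runs with < 3°
  longitude range inside a migration interval;
- **breeding** resumes after `breeding_min_run_days` = 2 consecutive
  fresh-water days.

**Migration distance** is the great-circle length through *settled*
endpoints — the geographic median over a `settle_days` = 7-day window
before departure and after arrival — via the median position of each
detected stopover. A raw sum over consecutive twilight positions is
structurally biased: latitude scatter during dry sprints inflates it with
doglegs, and day-resolution boundaries truncate overnight arrivals. The
7-day window also outlasts the post-arrival relaxation of the position
posterior at sites under continuous daylight, where latitude is informed
only by the weak SST gradient.

## 6. Space use

`kernel_ud` builds a Gaussian-kernel utilization distribution on a
100×100 grid in a local azimuthal-equidistant projection with the ad-hoc
bandwidth `h = sqrt((var x + var y)/2) · n^(−1/6)`. Contours (default 25,
50, 75 %) are the smallest-area regions holding the stated probability
mass, extracted with marching squares and returned as polygons/GeoJSON.
A degenerate (zero-variance) point set raises rather than returning an
empty distribution.

## 7. Synthetic generator: what it emulates, and what it does not

`synthetic_data` scripts a 19-bird female cohort over one deployment year
(late June to early July of the following year) in a rectangular world
(5–75° E, 50–78° N, 0.25° raster) with a freshwater breeding island at
(48.85° E, 69.14° N), a brackish south-western basin, a marine
north-eastern embayment (33.9–41.6° E), and a zonal land barrier between
them. The annual plan is breeding → flight to a marine post-moult site →
autumn migration (40 km/h great-circle flight, optional scripted
stopovers) → brackish wintering (one bird winters in the marine
embayment) → spring migration → pre-breeding staging → breeding. Stage
dates are jittered per bird around fixed means; within-stage movement is
a stationary Ornstein–Uhlenbeck jitter around the stage anchor with
habitat rejection. Light follows a logistic function of solar elevation
with Bernoulli/log-normal shading, max-recorded in 5-minute windows;
blocks carry conductivity levels (fresh 3, brackish 35, marine 95, σ = 3)
and water/air temperatures around a closed-form SST field
(`14 − 0.45·(lat − 50) + 6·cos(2π(doy − 225)/365.25)` °C, ice where
SST < 0).

It does **not** emulate: real coastlines or bathymetry, weather and cloud
systems (shading is i.i.d., not synoptic), behaviour-dependent shading
(diving, plumage), tag failure or battery decay, clock drift, leap-second
or longitude-wrap corner cases beyond the world's bounds, or density
dependence among birds. Scripted migration legs are great circles, so
the generator cannot test detour reconstruction.

## 8. Numerical choices

- Spherical Earth, radius 6371.0088 km; haversine distances; aeqd
  projection implemented directly from the spherical formulas.
- Latitude inversion: 341-point profile scan for bracketing plus Brent
  root refinement; vectorized grid interpolation inside the particle
  filter (angle grid step 0.75°, latitude via `np.interp` with linear
  blending between angle grid lines).
- Geographic medians via Weiszfeld iteration on the unit sphere's
  tangent plane; two-point clouds fall back to the weighted midpoint.
- All stochastic components draw from `numpy.random.default_rng` with
  explicit seeds; cohort runs derive per-bird seeds deterministically.

## 9. Limitations

- The latitude branch choice is hemisphere-specific; tracks that cross
  the profile minimum's latitude would need the opposite branch.
- During equinox windows and continuous daylight, latitude rests on the
  movement prior and the SST gradient (≈ 0.45 °C per degree against a
  1 °C tolerance), so systematic SST biases map directly into latitude.
- The conductivity classes are hard-coded salinity proxies; estuarine
  gradients between the class boundaries are not modelled.
- Problem sizes (400 particles, 100×100 KDE grid, 0.25° world raster)
  are chosen so a full 19-bird year processes in minutes on one core;
  they are configuration, not limits of the method.
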