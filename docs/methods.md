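# Methods

This note records the scientific and numerical choices behind `phenotrack`:
what the pipeline computes, what the synthetic cohort emulates (and does
not), and where the design was genuinely open.

## Data model

Raw input is one CSV per subject and stream kind (accelerometer at ~10 Hz in
g; GPS fixes; screen on/off power events; collection-log records), with UTC
millisecond timestamps. All analysis windows — calendar days and the
02:00–05:00 night window for home inference — use local clock time
(`timezone`, default Europe/Vilnius, the study region); daylight-saving days
keep their true 23/25-hour length and every per-day ratio uses the actual
day duration. Accelerometer and GPS samples are first averaged within each
epoch second ("per-second aggregation"), which regularizes device-specific
sampling rates.

**Coverage.** The collection app logs a "Create new data files" record for
every file it opens (hourly by default, `expected_files_per_day: 24`). The
clamped ratio of observed to expected records is the day's coverage; it
scales the denominator of the screen-time feature and gates day validity
(`coverage_floor: 0.5`). GPS- and accelerometer-based ratios are normalized
by their own observed time instead, which is the same idea applied at the
sensor level. A subject enters cohort analyses only with >= 14 valid days
(`min_valid_days`), and group summaries average each subject's first 14
valid days.

## Feature extraction

* **Activity.** Axes are normalized by their per-subject maximum absolute
  value (`x_norm = x / max|x|`), removing device amplitude differences. For
  every clock minute with at least two second-aggregated samples, the summed
  population variance `v_m = var(x)+var(y)+var(z)` is compared with
  `accel_variance_threshold_g2 = 1e-4`; minutes at or above it count as
  active, minutes below as "phone state unchanged". The ratio is active /
  observed minutes. The threshold applies to normalized values (the pipeline
  normalizes before analysis); `threshold_on_raw` restores raw-scale
  thresholding.
* **Movement.** Consecutive-fix speeds are computed after decimating the
  per-second fixes to one per `speed_baseline_s` (default 10 s). At 1 Hz any
  realistic GPS error makes fix-to-fix speeds noise-dominated (independent
  5 m errors imply ~25 km/h apparent speed for a stationary phone), so a
  baseline is required for the 10 km/h rule to mean anything; setting the
  baseline to 1 s restores literal consecutive-fix speeds. Movement is
  interval time with speed in `(movement_speed_min_kmh, movement_speed_max_kmh]`
  = (0.5, 10] km/h — the ceiling excludes vehicle travel, the floor residual
  jitter — divided by all observed interval time. Intervals longer than
  `gps_gap_s = 300 s` are treated as unobserved.
* **Home.** Night fixes (02:00–05:00, all days pooled) are snapped to a
  4-decimal-degree grid (~11 m, matching the 10 m same-place radius); home is
  the centroid of the modal cell. Without any night fix the mode over all
  fixes is used and flagged low-confidence. Home membership for the
  time-at-home ratio widens the 10 m radius by `home_noise_allowance_m = 20`:
  with 5–10 m GPS error a strict 10 m radius would systematically undercount
  home time.
* **Distance.** Great-circle distance on the WGS84 mean-radius sphere
  (haversine, R = 6371.0088 km); the daily feature is the mean over fixes, in
  km.
* **POI.** Sequential dwell extraction: a cluster opens at the first fix,
  extends while fixes stay within `poi_radius_m = 100` of its running
  centroid, and closes on exit or on a time gap > `gps_gap_s`. Clusters
  dwelling >= `poi_min_dwell_min = 30` are visits; visits within 100 m of an
  earlier visit's centroid merge into one place. The count is distinct
  places per day, not visits, and home is included (typical per-day counts
  of 2–4 are consistent with counting the home place;
  `exclude_home_from_poi` is available).
* **Screen time.** Repeated power states are collapsed to the first
  occurrence (duplicated OS events would double-count), on→off sessions are
  intersected with the day window (sessions open at a boundary are
  truncated; a day starting mid-session counts from midnight), and the sum
  is divided by day length × coverage, clipped to [0, 1].

Missing streams or empty days yield `NaN` features rather than zeros.

## Statistics

Pearson chi-squared uses no continuity correction and no minimum
expected-count rule — the convention that reproduces the published
statistics from their printed contingency tables. Printed statistics in
that table are truncated, not rounded, to three decimals (2.5185 prints as
2.518), and comparisons respect that convention. Mann–Whitney U is computed
by the rank formulation with ties counted half; the reported statistic is
`min(U_a, U_b)` and the two-sided p-value uses the tie-corrected normal
approximation without continuity correction (cohort sizes here are >= 26);
an exact permutation enumeration is available for samples up to ~10.
Kruskal–Wallis applies the standard tie-correction divisor and a chi-squared
reference with k−1 degrees of freedom. Empirical type-I error of all three
is 0.047–0.051 at n = 30/group under null resampling (see the acceptance
script). No multiple-testing correction is applied, matching the analysis
being reproduced.

## Trends

`loess_fit` is local polynomial regression: at each grid point, weighted
least squares over the `span` fraction of nearest neighbors with tricube
weights, degree 1 or 2 (defaults `span 0.75`, `degree 2` — common LOESS
defaults; the source analysis states neither). The fit is a linear smoother
`f(x0) = l(x0)·y`, so `se(x0) = sigma·‖l(x0)‖` with `sigma²` estimated
globally as RSS/(n − tr L); for n > 3000 the residual scale is estimated on
an even-spaced subsample of 1500 points. Degree-p fits reproduce degree-p
polynomials to machine precision — the defining property, tested at 1e-8.
Windows with fewer distinct x values than degree+1 are widened and flagged.

Group trends are evaluated on a common weekly-midpoint grid over 14 weeks
(study time = days since each subject's first valid day). Because daily
observations are clustered within subjects, iid pointwise bands would
shrink with subject-days rather than subjects; the band variance is
therefore inflated by the classic design effect `1 + (m−1)·ICC` (m = mean
observations per subject; ICC estimated from residual moments). With
identical generators the resulting 95% bands overlap over essentially the
whole grid, while the planted partial-vaccination POI ramp separates after
week 1 at study-scale group sizes. The CI multiplier is 1.96 (pointwise
normal); no simultaneous-band inference is attempted — the analysis is
interpreted visually, as in the source study.

## Synthetic cohort generator

The generator plants behavior at the parameter level and emits raw streams;
nothing is injected into extracted features, so the full stack is exercised.

**Profiles.** Group behavioral targets default to the published two-week
group summaries (fear / no-fear and fully / partially / unvaccinated):
activity, movement, home-time and screen fractions, POI rate and mean
distance to home. Per-subject parameters are drawn from normals truncated
symmetrically about the group mean (mean-preserving) with SD set to half the
published cohort SD — the printed SDs mix between- and within-subject
variance, while the profile SD is between-subject only. Home time is capped
at 0.88 (an ambulatory, mostly ECOG-0 cohort) and walking cannot exceed 85%
of non-home time.

**Days.** Each day is a physical itinerary: overnight (to 08:00) and evening
(from 22:00) home blocks; up to k visits to catalog places — an "anchor"
(clinic/workplace) whose distance is solved from the subject's
distance-to-home target, plus nearby minor places at 0.4–2.5 km — each as a
60 km/h drive out, a dwell of >= 40 min, and a drive back; and out-and-back
walking bouts at 5 km/h sized to the movement fraction. k is drawn around
the POI rate minus one (home is itself a place). Scheduling priorities when
the away-time budget binds: visits (dropping the travel-costliest place
first), then walking, then extra dwell. Three analytic compensations keep
expectations on target: the away-time of visit days is inflated to offset
stay-home days; the visit draw is inflated by ~1.4 × hourly-dropout
probability to offset visits clipped below the observable 30-min threshold;
and a nearby visit is dropped rather than squeezing walking below 80% of its
target.

**Emission.** GPS: 1 Hz fixes in a 60 s on / 120 s off duty cycle, with
correlated position error — a stationary AR(1)/Ornstein–Uhlenbeck process,
sigma 5 m, correlation time 1800 s per axis, reflecting the slowly varying
multipath/atmospheric character of real GNSS error (independent 5 m errors
per fix are not how receivers behave and would defeat any displacement-based
speed estimate). Accelerometer: 10 Hz, 1 min on / 10 min off; active
minutes draw axis noise at 0.15 g, stationary minutes 0.002 g, plus 1 g
gravity on z — far above and below the variance threshold after
normalization. Screen sessions are generated within hour boundaries so that
the hourly dropout model (each hour of all streams dropped with
`p_drop_hour = 0.05`) never truncates a session mid-way. Log records are
hourly for kept hours.

**Ground truth** is computed from the noise-free trajectory restricted to
the kept (post-dropout) observation pattern — the behavior an error-free
extractor could observe. For the POI count, a place counts when some kept
contiguous chunk of a visit spans >= 30 min between its first and last GPS
fix, exactly the observable criterion. Recovery tests therefore measure
extraction error (noise, duty cycling, thresholds), not sampling error. On
20 subjects × 14 days, extraction recovers the POI count exactly on 100% of
subject-days, ratio features within ±0.02 and distance within ±5% on >= 99%.

**Realized group means.** The five directly planted quantities converge to
their group targets within 3 SE at n = 200. Distance-to-home does not: its
published group means (8.3–43.5 km) are outlier-driven and jointly
infeasible with the published home-time and movement fractions inside a
physical 24-hour day (a 43 km mean with 69% home time would require more
driving than the away budget holds), so the anchor distance is capped and
realized distances are smaller while preserving group ordering. The per-day
recovery property — what the extraction pipeline is actually tested on — is
unaffected.

**What the generator does not emulate:** road networks (travel is
straight-line), within-day behavioral autocorrelation beyond the itinerary,
device heterogeneity, iOS/Android event quirks, GPS urban-canyon dropouts
correlated with location, or seasonal behavior change. Passing tests
demonstrate that the extraction stack inverts the generative model at
realistic noise levels and that the statistics are calibrated; they cannot
certify performance on real streams with pathologies outside this model.

**A behavior-level fast path** (`simulate_daily_features`) samples daily
feature realizations directly around profile parameters, including
week-indexed POI schedules for the trend analysis (partial group ramping
from ~3.3 to ~4 POI/day, fully vaccinated <= 3 with a week-11 dip,
unvaccinated declining from 2.5 to 2.0 by week 11 — the reported weekly
pattern). It is used where raw-stream emission adds runtime but no
information: statistical power checks and trend analyses.

## Problem sizes and reproducibility

Default verification sizes: recovery on 20 subjects × 14 days; null
calibration with 5,000 replicates (2,000 in the acceptance script) at
n = 30/group; trend separation over 20 (10) seeds at study-scale groups
143/26/33. Every stochastic step takes an explicit seed; a fixed seed gives
byte-identical simulated datasets and identical pipeline outputs.

## Known limitations

* Home inference assumes the subject sleeps at one place; shift workers or
  split residences would need a different night window.
* The movement ratio is displacement-based; slow indoor activity and
  treadmill walking are invisible to it.
* Screen-session pairing trusts the event stream after collapsing repeats; a
  lost `screen_off` extends a session until the next event.
* The printed distance-to-home group means cannot be realized jointly with
  the other published fractions (see above); synthetic cohorts preserve
  ordering, not level, for that one feature.
* LOESS bands are pointwise; "separation" of groups is a visual/heuristic
  criterion, not a formal curve-difference test.
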