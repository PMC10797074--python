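# phenotrack

Digital phenotyping of an oncology cohort from passive smartphone sensors.

Cancer patients' everyday behavior — how much they move, how long they stay
home, how many places they visit — can be quantified continuously and
unobtrusively from the sensors of their own phones. `phenotrack` implements a
complete analysis pipeline for such a study: it extracts six behavioral
features from raw accelerometer, GPS, screen-power and collection-log
streams, scores a COVID-19 fear questionnaire and vaccination status,
compares patient groups with rank-based tests, and fits local-polynomial
trends of behavior over a 14-week follow-up. Because raw cohorts of this
kind are not publicly shareable, the package ships a synthetic-data generator
that emits realistic multi-week sensor streams with exact per-day ground
truth, so every stage of the pipeline is testable end to end.

It is written for biostatisticians and digital-health researchers who want a
tested, reproducible reference implementation of this class of analysis.

## The six behavioral features

For each subject-day (local calendar day, Europe/Vilnius by default):

| feature | sensor | definition |
|---|---|---|
| activity duration ratio | accelerometer | share of observed minutes with per-minute variance `v_m = var(x) + var(y) + var(z) >= 1e-4 g²` on axes normalized by `x / max\|x\|`; below the threshold the phone's state is taken as unchanged |
| movement duration ratio | GPS | share of observed time at walking/jogging speed, i.e. computed speed in (0.5, 10] km/h |
| time at home ratio | GPS | share of observed time within 10 m (plus a GPS-noise allowance) of home — the modal 02:00–05:00 location |
| distance to home | GPS | mean great-circle distance (WGS84 mean radius, haversine) of the day's fixes to home, km |
| places of interest (POI) | GPS | distinct places with dwell >= 30 min, a 100 m radius defining "same place"; home included |
| screen time ratio | power events | summed screen-on session time over the coverage-scaled day |

Duration features are normalized by daily data **coverage**, inferred from
hourly "Create new data files" log records, so collection outages do not
masquerade as behavioral change. Subjects enter cohort analyses with at
least 14 valid days; group summaries use each subject's mean over the first
two weeks of valid days.

Group comparisons use Pearson chi-squared (contingency tables), Mann–Whitney
U (two groups; reported statistic is `min(U_a, U_b)`) and Kruskal–Wallis H
(three groups), all implemented from their defining formulas with tie
corrections. Trends are LOESS fits (tricube weights, local quadratic,
span 0.75) on a weekly grid with pointwise 95% bands inflated for
within-subject clustering.

## Worked example

Chi-squared on a published cohort characteristic (history of COVID-19 by
vaccination status, counts fully/partially/unvaccinated):

```python
>>> from phenotrack import chi_squared
>>> chi_squared([[53, 12, 20], [90, 14, 13]])
TestResult(statistic=6.3009400185870765, p_value=0.04283199070162793,
           method='pearson-chi2', df=2)
```

The statistic 6.30 (p = 0.043) says prior COVID-19 infection is unevenly
distributed across vaccination groups. Scoring a fear questionnaire:

```python
>>> from phenotrack import score_fear
>>> r = score_fear([3, 4, 2, 3, 3, 5, 3, 3, 2, 4])
>>> r.raw_sum, r.score_0_100, r.fear_flag
(32, 55.0, True)
```

The raw item sum 32 maps to 55 on the 0–100 scale; at or above 50 the
subject belongs to the fear group. Simulating a subject and recovering their
behavior from the raw streams:

```python
>>> from phenotrack import PipelineConfig, extract_daily_features
>>> from phenotrack.synthetic_data import make_cohort_profiles, simulate_subject
>>> cfg = PipelineConfig()
>>> profile = make_cohort_profiles({"fear": 1}, seed=7, config=cfg)[0]
>>> streams, truth = simulate_subject(profile, 3)
>>> daily = extract_daily_features(streams, cfg, profile.subject_id)
>>> print(daily[["date", "coverage_ratio", "time_home_ratio", "n_poi"]].round(3).to_string(index=False))
      date  coverage_ratio  time_home_ratio  n_poi
2022-09-05           0.958            0.700    3.0
2022-09-06           0.958            0.891    1.0
2022-09-07           0.917            0.672    3.0
```

The planted ground truth for those days is 0.699 / 0.891 / 0.668 for home
time and 3 / 1 / 3 places of interest: extraction recovers the behavior to
within a few thousandths despite 5 m correlated GPS noise, duty-cycled
sampling, and dropped collection hours.

The same workflow is available from the shell:

```bash
phenotrack all --out run/ --seed 3 --weeks 2 --groups fear=5,no_fear=5
phenotrack chisq --counts "53,12,20;90,14,13"
```

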