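# pbt — personalized basal tuner

`pbt` analyses continuous glucose monitoring (CGM) history to judge whether a
type 1 diabetes patient's programmed **basal insulin rate** is set correctly —
**without requiring meal annotations**. Meal announcements are the weak link of
retrospective CGM analysis: they are frequently missing, late or wrong. `pbt`
instead removes meal-related glucose excursions directly from the signal, then
asks, hour by clock hour, whether the remaining (fasting-like) glucose stays
flat.

It is aimed at diabetes-technology researchers and algorithm developers working
with pump + CGM event data.

## Method in brief

For each day of history (integer mg/dL CGM at ~5-minute cadence):

1. **Smooth** the trace with a 15-minute centered moving average.
2. **Detect peaks**: every strict local maximum; its *height* is the apex
   minus the **deeper** of the two neighboring minima (mg/dL) and its *width*
   is found by linear interpolation at half height (hours).
3. **Flag meal-likely peaks**: height or width at or above that day's 95th
   percentile (`P_j or W_j >= P95`).
4. **Excise** the window `[apex − 1 h, apex + 3 h)` around each flagged peak,
   carrying overflow past midnight into the next day.
5. **Composite profile**: overlay all cleaned days on a 24 h × 1-minute grid;
   for each (day, hour) with ≥ 2 samples compute the *relative change*
   Δ = last − first (mg/dL). A well-set basal rate gives Δ ≈ 0; Δ > 0 points
   to insufficient and Δ < 0 to excessive basal insulin in that hour.
6. **Grade reliability** of each hour's box-plot summary (low/medium/high)
   from its sample count against the 50th/70th percentiles of all 24 counts.

Three evaluation statistics accompany the pipeline:

* **Noninferiority**: one-sided t-test of mean |Δ| of the meal-agnostic arm
  against `(1 + margin) ×` mean |Δ| of a comparator that excludes 4 h after
  every *announced* meal (margin 20% by default).
* **Precision**: fraction of flagged peaks matched by a meal in
  `[apex − width/2 − 1 h, apex + 1 h]`, with a Wilson score 95% CI.
* **Interindividual classification**: each participant-hour is *excessive*
  (median Δ < 0), *insufficient* (> 0) or *optimal* (= 0), with cohort
  summaries (non-optimal %, optimal hours/day, daily cumulative |Δ|).

A seedable simulator (`pbt.simulate`) generates synthetic participants —
gamma-shaped meal excursions, per-hour basal-error drift, sensor noise,
dropout — with ground truth, so the whole pipeline is testable end to end.

## Worked example

Simulate 45 days of a participant with three daily meals, clean and evaluate:

```sh
pbt simulate --n-days 45 --seed 7 --out-dir sim
pbt clean   --cgm sim/cgm.csv --out cleaned.csv
pbt profile --cleaned cleaned.csv --out hourly_profile.csv
pbt evaluate --cgm sim/cgm.csv --meals sim/meals.csv --out evaluation.json
```

which prints (to stderr) along the way:

```
wrote 12719 samples over 45 days to sim
INFO pbt: flagged 113 meal-likely peaks
kept 7489, excluded 5230 samples -> cleaned.csv
wrote 24-hour profile -> hourly_profile.csv
noninferiority t=3.607 (df=1334) one-sided p=0.9998 -> evaluation.json
```

`hourly_profile.csv` starts:

```
hour,median,q1,q3,whisker_lo,whisker_hi,n,reliability,outliers
0,1,-6,4,-14,19,45,high,
1,-1,-5,4,-15,12,45,high,
```

Hour 0 contributed 45 day-deltas with median +1 mg/dL — a basal rate holding
glucose essentially flat overnight, graded `high` reliability. In
`evaluation.json`, all 113 flagged peaks matched an annotated meal
(precision 1.000, Wilson 95% CI 0.967–1.000), and the participant's daily
cumulative |Δ| was 195.5 mg/dL. The noninferiority test does *not* pass here
(t = 3.61, one-sided p ≈ 1): the per-day 95th-percentile rule flags at most a
couple of peaks per day, so with three announced meals per day the comparator
arm removes more meal influence than the meal-agnostic arm — visible exactly
because the simulator's annotations are complete and exact, which real meal
diaries are not.

Every command writes a `manifest.json` (parameters, input digests, version,
seed) next to its outputs. The same pipeline is available as library calls:
`pbt.clean_days`, `pbt.build_profile`, `pbt.evaluate_participant`,
`pbt.evaluate_cohort`.

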