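# Methods

This note documents the models, conventions and parameter choices behind
`pbt`, in the order the pipeline applies them, together with what the
synthetic-data generator does and does not emulate.

## Signal model and assumptions

CGM glucose is treated as a per-day sequence of (local timestamp, mg/dL)
samples at a nominal 5-minute cadence with gaps. The package assumes:

* glucose excursions caused by meals (and their bolus response) appear as
  *peaks* — local maxima that are markedly taller or wider than the day's
  background fluctuation;
* outside meal-influenced intervals, glucose trends over a clock hour are
  dominated by the basal-rate/endogenous-glucose balance, so the hourly
  relative change Δ = last − first sample is a (noisy) readout of basal
  adequacy: Δ ≈ 0 when the rate is right;
* time-of-day structure is stable enough across ~45 days that pooling days
  by clock hour is meaningful. Daylight-saving shifts are ignored: days are
  identified by wall-clock label and a 23/25-hour day still maps onto the
  00:00–23:59 grid.

## Cleaning pipeline

**Smoothing.** Centered moving average, 3 samples (≈ 15 min), per day;
edges average the shorter available window; days with < 3 samples pass
through with a warning. Chosen over heavier filters because it attenuates
single-sample sensor error while leaving meal-peak geometry (apex position,
flank slopes) essentially intact, and it has no tuning beyond the window.
The window is indexed by sample, not by time, so across a data gap it spans
more wall time; at 2% dropout this is immaterial.

**Peak detection.** Every strict local maximum of the smoothed day. A run
of equal values is one candidate apex whose timestamp is the run's center
sample (earlier of the two centers for even runs); runs touching the series
boundary are not peaks. The flanking ("neighboring") minima are found by
walking outward while values are non-increasing.

**Height.** `apex − min(left minimum, right minimum)` — the base is the
*deeper* valley. This is deliberately the opposite base choice from the
topographic-prominence convention (which uses the higher base) and makes
heights larger for peaks with asymmetric flanks; `height_base="higher"`
switches conventions. Candidates with height < 5 mg/dL are discarded:
integer quantization of CGM otherwise yields a large population of 1–2
mg/dL "peaks" that would dilute the outlier percentile.

**Width.** Horizontal distance between the two crossings of the level
`apex − rel_height · height`, each found by linear interpolation between
bracketing samples, scanning outward from the apex *no further than the
neighboring minima*. Because the height reaches to the deeper valley, the
level can lie below the shallower valley; such a flank is clipped at its
base. When that base is the first/last sample of the series the peak is
marked edge-truncated. Bounding the scan at the bases matters: scanning
onward until the level is re-crossed assigns multi-hour widths to small
wiggles riding the decaying tail of a meal excursion (the level is only
re-crossed back on the meal's rising flank), which corrupts the width
percentile and, in simulation, roughly halves flagging precision.
`rel_height` defaults to 0.5 (half height) and is exposed as a parameter.

**Meal-likely flag.** A peak is flagged when its height **or** width is ≥
the 95th percentile of that day's heights/widths (linear interpolation
between order statistics). The percentile is computed per day, matching the
per-day structure of the cleaning loop; `global_percentile=True` pools all
days instead. The ≥ comparison has a deliberate degenerate consequence: if
all peaks of a day share a value on one axis, all are flagged on that axis.

**Exclusion.** Each flagged apex removes the half-open window
`[apex − 1 h, apex + 3 h)` — asymmetric because glucose absorption and
insulin action mostly play out in the 3–4 h after intake begins, and the
rise precedes the apex by up to an hour. Windows crossing midnight are
split and the overflow carried to the next calendar date; a window that
would begin before the day's own 00:00 is clamped to it (only forward
carry-over; backward carry would mutate an already-processed day).
Same-day overlapping windows are merged. Exclusion removes samples from the
*raw* day, so retained values are original sensor readings and
|raw| = |kept| + |inside windows| holds exactly per day.

**Comparator arm.** With meal annotations, the window is
`[meal, meal + 4 h)` per announced meal, midnight-split and merged the same
way.

## Composite profile

Cleaned days are overlaid on a days × 1440 minute-of-day grid (timestamps
truncated to the minute; one cell per cleaned sample). For each (date,
hour) with ≥ 2 retained samples in the half-open hour `[h:00, h+1:00)`,
Δ = last − first. Deltas are computed per day and then pooled per hour —
not on row-averaged composite values — so day-to-day spread remains visible
in the hourly distributions.

Per-hour box-plot statistics use linear-interpolation quartiles, whiskers
at the most extreme points within 1.5·IQR of the quartiles, and explicit
outlier lists. Reliability per hour: with P50/P70 the 50th/70th percentiles
of the 24 hourly counts, `low` if n < P50, `medium` if P50 ≤ n < P70,
`high` if n ≥ P70 (boundary sides are a package choice; only the two
percentile anchors are inherent to the grading idea). A ±36 mg/dL display
band sometimes drawn around such profiles is provided as a constant only;
it has no computational role.

## Evaluation statistics

**Noninferiority.** Per-(date, hour) absolute deviations |Δ| from each arm
form two samples. The comparator sample is scaled by (1 + margin), margin
0.20 by default, and a two-sample pooled-variance t-test is run:
t = (mean₁ − (1+m)·mean₂)/SE, df = n₁ + n₂ − 2; negative t favors
noninferiority and the one-sided p is P(T_df ≤ t). The pooled form is the
default because integer df values are what partner analyses report; a
Welch option exists. Both one- and two-sided p-values are returned. With
zero pooled variance and equal means the statistic is undefined and a
degenerate-input error is raised. The test's operating characteristic is
verified by simulation: at the null boundary (both arms half-normal, means
in exact (1+m) ratio) the empirical one-sided rejection rate at α = 0.05
is 0.048 over 10,000 replicates of n = 500 per arm.

**Precision.** A flagged peak counts as correct when an annotated meal
falls in `[apex − width/2 − 1 h, apex + 1 h]` — the half-width estimates
the excursion's start, and the hour of slack on each side absorbs
annotation timing error. Peaks on dates with no meal annotations at all
have no reference and leave the denominator; they are reported as missing
meal days, and the participant is flagged low-quality when more than 25%
of their peak-bearing dates lack annotations. The Wilson score interval
(via `statsmodels.stats.proportion.proportion_confint`) accompanies every
proportion; an independent closed-form evaluation backs it in the tests.

**Interindividual classification.** Each participant-hour's median Δ is
classified: excessive insulin (< 0), insufficient (> 0), optimal (= 0).
Exact zero is attainable because CGM values are integer mg/dL, so medians
of deltas land on 0 with positive probability; `optimal_tol` widens the
band for other readings. Cohort summaries report the non-optimal
percentage with Wilson CI, optimal hours per day (optimal count /
participants), the range of medians, the per-participant daily cumulative
value Σₕ |median Δₕ| (mean, population SD, maximum), and sample variances
of the pooled excessive and insufficient median sets.

## Synthetic data generator

Per sample at minute m of hour h:
`g = baseline + d_h·(m mod 60)/60 + Σ meal responses + N(0, σ)`, rounded to
integer mg/dL and clipped to [40, 400] (inside the 20–600 sensor range so
generated files never trip boundary validation). Defaults: 45 days,
baseline 120 mg/dL, meals at 08:00/13:00/19:00 with 20-min Gaussian jitter,
amplitude 80 ± 15 mg/dL, noise SD 5 mg/dL, dropout 2%.

The meal response is a gamma density rescaled to peak at exactly the drawn
amplitude, shape 5 and scale 0.25 h: mode at 1.0 h post-meal, ≥ 99% of its
area inside 4 h and < 1% of the amplitude remaining beyond 4 h — matching
the 3–4 h absorption/insulin-action window the exclusion logic assumes. A
log-normal response is selectable. Overlapping responses add linearly — a
simplification with no pretense of insulin–glucose dynamics (no
Bergman-style ODE model); the generator only reproduces the *statistical*
structure the cleaning algorithm keys on.

The drift term models a mis-set basal rate as an hourly slope d_h that
accumulates within the hour and resets at the hour boundary, so the
generative hourly delta at full cadence is d_h·55/60. The reset produces a
small sawtooth discontinuity at hour boundaries (≤ 3.7 mg/dL at |d| = 4),
below the 5 mg/dL peak noise floor. Ground truth (meal times, amplitudes,
drift, per-sample meal-influence flags over [meal, meal + 4 h)) is emitted
alongside.

What passing synthetic tests does **not** show: robustness to compression
lows, sensor drift/recalibration steps, exercise- or stress-driven
excursions, circadian insulin-sensitivity changes, or sparse/incorrect meal
diaries. Real-data precision will be lower than the simulator's (annotations
there are noisy and incomplete), and noninferiority outcomes depend on the
annotation quality of the comparator arm: with the simulator's complete,
exact meal diary the comparator arm removes more meal influence than the
meal-agnostic arm and noninferiority is typically *not* concluded — the
meal-agnostic method's practical value lies precisely where annotations are
unreliable.

## Problem sizes and numerical choices

* Stochastic verification sizes: drift recovery pools 10 simulated
  45-day participants per drift profile and requires the pooled per-hour
  median within ±2 mg/dL of the injected slope; flagging precision is
  checked on three 45-day participants; calibration uses 10,000 replicates
  of n = 500 per arm. The pooled (rather than per-seed) drift check is the
  package's choice: a single 45-day median of last−first deltas carries a
  standard error of ≈ 1.3 mg/dL at the default noise, so per-seed ±2
  checks would fail by chance at a non-trivial rate under the very
  conditions being verified.
* Percentiles and quartiles everywhere use numpy's linear interpolation
  between order statistics.
* Peak-geometry equality with the brute-force oracle is exact in floating
  point; the oracle shares the interpolation *expression* (not the code
  paths) so the comparison can be `==` rather than toleranced.
* Timestamps are ISO 8601 without timezone; duplicate timestamps are an
  error, not deduplicated. Glucose is stored as float but integer inputs
  round-trip exactly through the CSV writers (`repr`-based formatting).
* Degenerate inputs: empty peak lists flag nothing; hours with < 2 samples
  contribute no delta; an hour with no deltas has null statistics and low
  reliability; an all-excluded day is an empty cleaned day with a warning.

## Known limitations

* The deeper-valley height convention and the half-height width level are
  exposed as parameters because the field has no single convention; results
  are moderately sensitive to both through the 95th-percentile flag.
* The per-day percentile rule flags roughly the top one or two peaks per
  axis per day; on days with three or more comparable meal excursions some
  go unflagged. Pooling with `global_percentile=True` trades per-day
  adaptivity for a cohort-wide threshold.
* Exclusion windows are fixed (−1 h/+3 h) regardless of measured width.
* The hourly delta uses exactly two samples (first/last); it is unbiased
  for the hourly trend but not variance-optimal; reliability grading
  partially compensates by flagging thin hours.
* The package evaluates basal adequacy; it does not generate basal-rate
  recommendations.
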