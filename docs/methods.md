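# Methods

This note records the models, conventions and design decisions behind
`stepmetrics`, in the spirit of a methods appendix: what is computed, what
was genuinely open and how it was resolved, and what the synthetic tests
do and do not demonstrate.

## Data model

Input is epoch-level: vertical-axis activity counts per 15-s epoch, steps
per 60-s epoch, and per-axis acceleration mean and SD (g) per 15-s epoch.
Timestamps are naive local time on a strict 15-s grid aligned to clock
quarter-minutes; the calendar day boundary is local midnight. Grid gaps
are an error by design — silent gap-filling hides device problems that the
validity screen should see. Steps above 300/min are rejected as
physiologically impossible (the fastest behavioral band starts at 120).

Counts epochs (15 s) and step epochs (60 s) are deliberately kept at
their native resolutions. A minute contributes to step-based metrics only
when all four of its 15-s epochs are awake wear; this prevents partial
minutes from diluting cadence estimates. The two families of metrics
therefore have slightly different denominators, which is inherent to the
mixed epoch lengths.

## Nonwear detection

Each consecutive 15-min block (anchored at the recording start) is
classified using the 60-min window *centered* on the block and truncated
at the recording edges. Per-axis window statistics are pooled from the
epoch-level channels: window mean = mean of epoch means; window variance
= mean within-epoch variance + between-epoch variance of the means. The
block is nonwear if ≥2 of 3 axes have window SD < 13 mg, or ≥2 of 3 have
|window mean| < 50 mg. Blocks in which every epoch has some axis |mean|
above 5.5 g are malfunction and likewise flagged.

Open choices resolved here:

* **Centered vs trailing window** — centered, matching the published
  description of the surrounding moving window. Detection is invariant to
  shifting the recording by whole blocks (tested).
* **"Sustained" high acceleration** — read as a full 15-min block of
  epochs above 5.5 g. Malfunction spikes shorter than a block are
  physically implausible for the failure mode this targets (stuck
  sensor), and a weaker rule would misfire on vigorous impacts.
* **Pooled statistics** — exact raw-sample window statistics are not
  recoverable from epoch summaries; the pooled form is the correct
  variance decomposition given the available channels.

## Imputation

Nonwear (including malfunction) epochs are imputed with the mean value at
the same clock time over the subject's other days where that epoch is
worn: counts per 15-s slot, steps per minute (donor minutes must be fully
worn). Epochs with no donor day stay missing and drop out of metric
denominators. Because counts cannot be recomputed from imputed
acceleration summaries, the derived channels are imputed directly; this
preserves the intent — recover the typical value at that time of day — at
the resolution the data supports. Imputation runs before sleep
exclusion; imputed epochs count as wear in all metric denominators.

A consequence worth knowing: donor-mean cadences are fractional and
shrink toward the middle of the cadence distribution, so heavy nonwear
slightly inflates the incidental band and deflates TZC and the extreme
bands. At the default nonwear rates this bias is well under the
between-subject sampling error. The first cadence band is defined as
(0, 20) steps/min (zero exclusive) so fractional imputed cadences still
partition cleanly with TZC.

## Sleep exclusion and validity

Diary bed→wake windows are masked as sleep (a bed time later than the
wake time spans midnight; otherwise the window lies within its date).
Nights without an entry use the subject's mean bed/wake clock times over
reported nights, averaged on a noon-anchored scale so windows crossing
midnight average correctly. A subject with no diary at all is a
configuration error. Sleep minutes are attributed to the calendar day
they occur in; awake time per day is 1440 min minus that day's sleep
minutes. Replacing a raw-acceleration sleep-detection algorithm with
diary windows is a documented fidelity limitation of the epoch-level
contract.

A day is valid with ≥16 h of wear **over the full 24-h day** (the
protocol is 24-h wear, so wear during sleep counts toward the threshold;
mean awake time is only ~15.3 h/day, which is why the threshold cannot
refer to waking wear). A subject is included with ≥4 valid days of which
≥1 falls on Saturday or Sunday.

## Metrics

* Intensity minutes: counts/15 s against sedentary ≤25, light 26–573,
  moderate 574–1002, vigorous ≥1003; each epoch is 0.25 min. LMVPA >25,
  MVPA >573. All cut points are config keys.
* Minutes are kept as exact multiples of 0.25; rounding to one decimal
  happens only at serialization (12 significant digits in CSV output).
* Cadence bands: TZC (exactly zero), then (0,20), [20,40) … [120, ∞)
  steps/min over whole awake-wear minutes.
* Peak N-min cadence: mean of the N highest (not necessarily
  consecutive) minutes of the day; days offering fewer than N minutes
  use all available and carry a `peak_short` flag (such days do not
  arise after screening, but the code must behave).
* Weekly value = (mean over valid weekdays × 5 + mean over valid weekend
  days × 2) / 7, applied per metric; peak cadences are computed per day
  and then weekly-weighted (not pooled across days). The ≥60 min/day
  MVPA guideline is evaluated on the weekly-weighted MVPA, boundary
  inclusive.

## Statistical layer

* Simple regressions: OLS with intercept; r² = 1 − SSE/SST.
* Stepwise selection: forward; the candidate with the largest r² gain is
  added if its partial F-test (equivalently squared-t) has p < .05;
  after each addition, included predictors with VIF > 7 are dropped
  permanently, highest VIF first, and become ineligible. "Significantly
  increased the variance explained" is operationalized as the partial
  F-test; VIF screening per step rather than only on the final model.
  Exact ties in r² gain break by the canonical pool order (steps/day,
  bands ascending, peaks by descending window). TZC never enters a pool
  because it measures inactivity.
* Group contrasts: Student's pooled-variance two-sample t test by
  default (a Welch option exists); α = .05 per test with no
  multiple-testing correction, matching the analysis style the package
  reproduces.
* Guideline thresholds: the fitted line MVPA = a + b·x is inverted at
  the 60 min/day target, θ = (60 − a)/b, with a delta-method CI from the
  coefficient covariance (gradient [−1/b, −θ/b]). Inversion refuses
  slopes that are nonpositive or not significant; the point estimate,
  not a CI bound, is reported.

## Synthetic cohort generator

The generator emulates the study conditions: default 105 subjects ×
7 days (starting on a Monday), 24-h wear, bed ~22:20 and wake ~07:00
(±15 min between subjects, ±12 min between nights; expected awake time
~920 min/day), diary equal to truth by default (a reporting-jitter knob
exists), ~0.15 nonwear episodes/day of 60–120 min aligned to
quarter-hours, and ~0.2 malfunction blocks/week at 5.8–6.5 g.

Awake time is tiled with alternating rest and activity bouts
(exponential bout lengths, mean 3 min). Expected daily minutes per
cadence band default to the reference cohort descriptives
(`stepmetrics.reference`), drawn per subject from censored normals with
a numerically corrected location so cohort means stay on target, scaled
by a mean-one lognormal general-activity factor (σ = 0.12) shared across
bands, and jittered day-to-day (lognormal σ = 0.12; a weekend multiplier
defaults to 1). Nominal bout cadences stay two steps/min clear of band
edges so the ±0.5 steps/min per-minute jitter cannot leak minutes across
bands; the incidental band draws from a geometric-shaped distribution on
2–17 steps/min whose mean (5.103) makes the expected steps/day equal
the reference 8676.8.

Counts follow a linear cadence→counts map (5 counts/15 s per step/min)
with mean-one lognormal noise (σ = 0.45), calibrated so 115 steps/min
sits at the moderate threshold (575 ≥ 574 counts/15 s). Because much of
children's count-defined MVPA is non-ambulatory play, a configurable
fraction of awake zero-cadence minutes (default 7%) receives high-count
stepless bursts; each subject's burst propensity scales with relative
ambulatory volume (power 2.5, residual lognormal σ = 0.30), which is
what couples count-based MVPA to step volume across children. Wear
orientation puts ~90/95 mg on the two minor axes; off-body episodes lie
flat (≈8/12/1000 mg, SD ≈ 2 mg); epoch SDs during wear stay above
14 mg. Ground truth records sleep windows, planted intervals, and the
per-day band/intensity/step totals realized in the activity stream
before nonwear overwriting (with no nonwear planted this coincides with
the emitted stream, which is how the conservation test is phrased).

One root seed; per-subject generators are spawned from a
`SeedSequence`, so identical (config, seed) give byte-identical files.

**What the generator does not emulate**, and hence what passing tests do
not show about real data: within-day circadian structure (activity is
placed uniformly in the awake window), weekday/weekend contrasts,
posture-specific acceleration signatures, seasonal effects, diary
misreport beyond Gaussian jitter, and the joint cadence–counts
distribution of real devices (the linear-with-noise map is a modeling
choice). Peak cadences run somewhat higher than the reference cohort
(uniform in-band cadence draws put more mass near band tops); peak
metrics are therefore validated structurally (rank-order, oracle
equivalence), not against reference means.

## Problem sizes and numerical choices

The test suite uses a study-scale cohort (105 subjects × 7 days) for
calibration and invariant checks, small cohorts (3–8 subjects) for
recovery and pipeline tests, 100 random 3-h series for the nonwear
oracle, 50 random days for the day-metrics oracle, 10 seeds × (n = 40,
4 predictors) for the stepwise oracle, 50–500 replicates at n = 105 for
r²/threshold/selection recovery, and 10⁴ null replicates for the type-I
error of the group comparison. Degenerate inputs (all-sleep days, days
with no awake wear, empty diaries, zero-variance predictors,
single-member groups, nonpositive slopes) raise typed errors or produce
missing values as documented rather than silently succeeding.

## Known limitations

* Diary-based sleep exclusion is cruder than raw-acceleration sleep
  detection; misreported diaries propagate directly into awake time.
* Imputation at the derived-channel level cannot reproduce what
  reprocessing imputed raw accelerations through a count algorithm
  would give.
* The epoch-level contract cannot distinguish a genuinely still wearer
  from a removed device within a single window; the mean rule carries
  that burden and depends on wear orientation keeping two axes above
  50 mg.
* Stepwise inference reports no post-selection-corrected p-values; the
  selected-model r² values are descriptive, as in the analysis style
  this package reproduces.
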