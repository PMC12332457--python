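# Methods

This note documents the models, rules and numerical choices implemented in
`rhythmkit`, and what the synthetic generator does and does not emulate.

## Data model and validity rules

The canonical unit is a per-participant, minute-indexed, gap-free frame of
step counts and heart rate in naive local time.  Minutes missing heart rate
have their step count forced to missing, because optical heart rate is the
wear signal: steps logged while the device is off the wrist are not
trustworthy.  A heart rate ≤ 0 is treated as a sensor gap, never as a
measurement.  The per-minute validity mask is true exactly where both
streams are present.

A calendar day (local midnight boundary) is valid when it carries at least
20 hours (1200 minutes, inclusive) of concurrent data; a participant is
included with at least 5 valid days.  Partial first/last days face the same
rule with no special trimming.  Hourly cells need ≥ 30 valid minutes;
hourly step sums are rescaled by 60/(valid minutes) so partially worn hours
are not biased low (a raw-sum mode exists behind
`PreprocessConfig.rescale_partial_hours=False`, since either reading of
"hourly aggregation" is defensible).  All SDs are sample SDs (n − 1).

For duplicate samples, the long-CSV reader treats duplicate minutes as an
error (a canonical store should never contain them), while the
intraday-API-shaped JSON reader resolves them first-observation-wins, which
is the natural rule for repeated API pages.

## Nonparametric rhythm indexes

All metrics consume valid days only and return missing — never zero — when
undefined, with the reason logged.

* **IS** uses the missing-data generalization
  (N·Σ_h (x̄_h − x̄)²)/(24·Σ_i (x_i − x̄)²) over the N non-missing hourly
  cells.  1 means each day repeats the mean profile exactly; 0 means clock
  hour carries no information.
* **IV** is the mean squared successive hourly difference divided by the
  population variance of the hourly values.  Successive pairs never bridge
  a missing cell or an excluded day; calendar-adjacent valid days chain
  through midnight.  On gap-free data this equals the textbook
  N·Σdiff²/((N−1)·Σdev²), giving exactly 4 for strict alternation and
  ≈ 2(1 − cos(π/12)) ≈ 0.068 for an hourly-sampled 24-h cosine.
* **M10/L5/RA** are computed on the across-valid-day mean 24-h profile
  with circular 10-h/5-h windows at hourly resolution (the profile
  convention of the origin literature; the alternative per-day computation
  averages window positions and was not used).  Window midpoints are
  reported as the window-center clock hour.
* **ICV**: for each clock hour with ≥ 2 non-missing days and positive mean,
  the across-day CV (sample SD / mean); ICV is the mean over eligible
  hours.  Two published descriptions of this index conflict (across-day CV
  per clock hour vs within-hour CV of minute data); the explicit formulaic
  one is the default and the within-hour reading is available as
  `intradaily_cv_within_hour`.  ICV is scale-invariant by construction.
* **Day-lag autocorrelation**: Pearson correlation of the 15/30/60-minute
  binned series with itself shifted exactly one day, pairwise-complete,
  requiring ≥ 3 overlapping pairs.
* **Peaks**: smoothed z-score detector with a rolling window of `lag`
  filtered samples.  A sample is signal when it exceeds the rolling mean by
  `threshold` rolling (population) SDs; flagged samples enter the filter
  with weight `influence`.  Missing samples are skipped without resetting
  state, so wear gaps cannot abort or fragment detection.  A peak is a
  maximal run of consecutive signal samples, attributed to the day of its
  first sample; days with no data contribute nothing to the mean.  Defaults
  lag = 60 samples, threshold = 3, influence = 0.1 (the algorithm's
  customary operating point; no published parameterization exists for this
  pipeline), all configurable.

## Extended cosinor

The model is r(t) = min + amp·l(c(t)), c(t) = cos((t − φ)π/12),
l(c) = e^{β(c−α)}/(1 + e^{β(c−α)}) evaluated through a numerically stable
logistic.  α ∈ (−1, 1) sets where on the cosine the curve crosses its
midline (negative α: wide peaks, narrow troughs), β > 0 the steepness
(large β approaches a square wave).  MESOR = min + amp/2 is attained where
c = α, so the midline crossings are UpMesor/DownMesor =
φ ∓ (12/π)·arccos(α) mod 24.

Fitting pools all valid days with clock time as the sole predictor (no
day-level random effects) and minimizes squared error with
`scipy.optimize.least_squares` (trf, tolerances 1e-10) under bounds
amp ≥ 0, |α| ≤ 1 − 1e-6, 1e-3 ≤ β ≤ 100, φ within ±12 h of each start.
The β ceiling of 100 prevents square-wave runaway on noisy data without
constraining realistic fits (cohort-level β values run an order of
magnitude lower).  Starts come from the closed-form linear cosinor
(cos/sin regression) at four phase offsets (0/6/12/18 h); the best residual
sum of squares wins.  Fits with amplitude < 1e-3 are flagged degenerate and
their phase quantities withheld.  The rhythm-robustness index is
F_pseudo = ((RSS₀ − RSS)/4)/(RSS/(n − 5)) against the intercept-only null
(4 numerator degrees of freedom, the convention of the transformed-cosinor
origin literature); it indexes fit improvement and is not treated as a
calibrated F test.

Heart rate is fitted at minute resolution; steps default to hourly
aggregates to tame minute-level zero-inflation (switchable via
`cosinor_steps_resolution="minute"`), since the fitting resolution per
stream is otherwise a free choice.

## Heart-rate metrics

RHR averages heart rate inside 15-minute blocks aligned to
:00/:15/:30/:45 whose minutes are all valid with zero steps; fixed
alignment is deterministic where a sliding window would be ambiguous, and a
relaxation (`RestConfig.require_complete=False`) accepts gappy blocks whose
present minutes are all zero-step.  The overall mean is taken over all
valid minutes of valid days (not a mean of daily means); dRHR = mean − RHR
exactly.  Daytime HR covers 14:00–16:00; nighttime HR is the unweighted
mean of the 0–2, 2–4 and 4–6 h window means and is missing if any window is
empty.  RMSSD uses successive present pairs only (gaps break pairs), on raw
minutes and on hourly means restricted to adjacent clock hours of the same
day.

## Synthetic cohort generator

The generator emulates week-long wrist recordings of older adults in three
planted groups (robust / prefrail / frail).  Per participant:

* a two-state rest/active minute Markov chain whose stationary active
  probability follows a sigmoid-squashed 24-h cosine peaking near 13:00,
  shifted by the group phase offset; the burst exit rate is the group
  `fragmentation` parameter (geometric burst lengths);
* day-to-day irregularity: a log-normal daily level multiplier and a
  Gaussian daily phase jitter, plus a log-normal hour-block multiplier,
  all with spreads scaling with `fragmentation`.  This coupling is a
  deliberate design choice: burst switching alone *lowers* the across-day
  hourly CV (shorter bursts average out within the hour), so day- and
  hour-scale level irregularity is what actually drives ICV up and IS down
  in the frail group, matching the direction seen in real cohorts;
* steps are negative-binomial counts (dispersion 0.5) in active minutes;
* heart rate is the group's extended-cosinor curve plus a coupling term
  (bpm per step/min of the trailing 5-minute step rate) plus AR(1) noise
  (lag-1 coefficient 0.7, innovation SD `noise_sd`), clipped to 30–190 and
  rounded to integer bpm (rounding can be disabled for exact-recovery
  tests);
* non-wear: Poisson-placed blocks of geometric mean length 45 minutes at
  `nonwear_rate` expected hours/day, capped at 210 minutes per day so that
  compliant wearers' day validity is governed by recording length rather
  than by chance — participants meant to fail inclusion are given short
  recordings instead.

Group defaults are centred on published cohort-level magnitudes for this
population (daily steps ≈ 9080/7809/6005; heart-rate cosinor minima/
amplitudes near 58.8/21.9 for robust and 61.7/17.5 for frail; dRHR higher
in robust than frail) and were calibrated once, at design time, so that
extracted IS/IV/ICV/autocorrelation land in the realistic 0.45–0.6 /
0.9–1.1 / 1.0–1.2 / 0.3–0.5 ranges.  The questionnaire layer draws the
social-frailty score from group-specific distributions concentrated on the
defining score (so the score classifier reproduces planted labels for
≳ 90% of participants), and the word-list-memory score is generated as
WLM = a₀ − a₁·age − a₂·(step ICV × 100) + Gaussian noise with defaults
(28.3, 0.15, 0.04), using the participant's own realized ICV computed
through the package's preprocessing path — which is what makes regression
recovery of a₂ well-posed.  One RNG stream per participant is derived from
(master seed, participant index), so cohorts are bitwise reproducible.

What the generator does **not** emulate: sleep architecture, accelerometer
counts, weekday/weekend structure, weather- or illness-driven behaviour
changes, device-specific step-detection bias, and beat-to-beat heart-rate
dynamics (RMSSD here reflects the AR(1) minute process, not RR intervals).
Passing tests therefore demonstrate correctness of the metrics and the
statistical machinery under controlled ground truth, not device validity on
real recordings.

## Statistical layer

Normality gating uses Shapiro–Wilk at α = .05; a pair gets Pearson only
when both variables pass, Spearman otherwise (both-must-pass is assumed
where one variable is normal and the other not).  Group tests are
Kruskal–Wallis with tie correction — degenerate all-identical input is
reported as H = 0, p = 1 — followed by Dunn z contrasts on joint midranks
with tie-corrected variance; the Bonferroni factor is 3 (the three pairwise
contrasts per variable), not the variable count.  The multinomial logit
uses the robust group as reference, Wald 95% CIs on the OR scale (the CI
method is otherwise unspecified in this literature; Wald is the common
default), a likelihood-ratio test against intercept-only for whole-model
fit, Nagelkerke R² = (1 − (L0/L1)^{2/n})/(1 − L0^{2/n}), and AIC.
Separation is flagged when any |β| exceeds 15 or the optimizer fails, and
estimates are then withheld.  All models are complete-case with dropped-row
counts logged.  The Dunn test is implemented in-package (no suitable
post hoc dependency is declared) and is verified against an independent
rank-based computation in the test suite.

## Problem sizes in the test suite

The acceptance-style suites run at the sizes the analyses are designed for:
50 replicates for parameter- and effect-recovery harnesses, 1000 replicates
for type-I calibration of the group test, 1000 random matrices for
brute-force oracle equality, and cohorts of 86 (28/39/19) or 90 (30×3)
participants × 7 days for the direction suite.

## Known limitations

* The peak detector's counts depend on its (configurable) operating point;
  no attempt is made to calibrate it against an annotated gold standard.
* β of the extended cosinor is weakly identified on noisy, nearly
  sinusoidal data; its estimates have heavy right tails (hence the bound).
* ICV is sensitive to near-zero hourly means; hours with non-positive mean
  are excluded rather than regularized.
* The multinomial model offers no penalization, so quasi-separated designs
  are flagged rather than estimated.
* Timestamps are naive local time; daylight-saving transitions are not
  modelled (single-region studies).
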