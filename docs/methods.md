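# Methods

`lockstep` analyses continuously recorded, minute-level consumer-tracker
activity data around a calendar interruption (the motivating case is a
citywide COVID-19 lockdown starting 2020-03-23). This note documents the
models, the synthetic-data generator, the numerical choices, and what the
test suite does and does not establish.

## Data model and cleaning

Each participant contributes an ordered stream of minute records: timestamp,
step count, MET value (metabolic equivalent task, the device's per-minute
energy-expenditure estimate), heart rate (beats/min; 0 encodes
device-not-worn), and a device-detected sleep flag. Timestamps are local
wall-clock, strictly increasing and minute-aligned; gaps are permitted and
never imputed — nonwear is handled by filtering, not by filling in.

The **waking filter** removes a minute when any of three criteria hold:
device-detected sleep, clock time in [00:00, 05:00), or heart rate 0. The
05:00 boundary is half-open (a minute stamped 05:00 is retained) — "between
midnight and 5 AM" is read as the right-open interval. Days with zero
retained minutes drop out of all analyses. A configurable minimum daily wear
threshold (`min_wear_minutes`, default 600 = 10 waking hours, the common
actigraphy convention) marks short days invalid; setting it to 0 applies no
day-validity rule, which is the pipeline default since the motivating
analysis states none.

## Intensity, bouts and w50

MET cutpoints: sedentary < 1.5, lightly active [1.5, 3), fairly active
[3, 6), very active ≥ 6. Intervals are left-closed so the four categories
partition [0, ∞) exhaustively and exclusively; a value of exactly 6.0 METs is
very active. The vendor's supplementary "≥145 steps/min in ≥10-min bouts"
rule for very-active minutes is internal to the device's own labelling and is
not re-implemented: classification consumes the MET value the device already
assigned.

A **bout** is a maximal run of consecutive retained minutes (consecutive in
wall-clock time) sharing a category; any removed or missing minute terminates
the run, as does the calendar-day boundary. Bridging gaps would fabricate
behaviour out of minutes that carry no category.

The **usual bout duration** (w50, also written x50) is the duration-weighted
median bout length: sort a category's bouts ascending by duration, accumulate
duration as a fraction of the category's total minutes, and return the
duration of the first bout at which the cumulative fraction reaches ≥ 0.5.
The attained value is returned with no interpolation, so a cumulative
fraction landing exactly on 0.5 selects that bout (durations [1, 2, 3] give
w50 = 2). This tie rule is a documented package choice; the verbal
definition ("half of all activity time accrues in bouts longer than w50")
does not fix the boundary case. w50 is order-invariant, invariant to how the
bout list was split across days, and scale-equivariant; with no bouts it is
undefined and raises, never 0.

## Interruption models

All outcomes are modelled per participant on the log scale, so the
coefficient β of the binary interruption indicator L (0 before the cutoff
date, 1 on/after) back-transforms to a relative rate exp(β).

**Minute-level METs** — log minute METs on
{1, L, sin(2πt/24), cos(2πt/24), L·sin, L·cos}, where t is the 24-hour
continuous clock time, with AR(1) errors. The harmonic terms and their
interactions absorb shifts in *when* the device is worn, so L captures the
level change, not a wear-timing change. The minute sequence is treated as
equally spaced for the autocorrelation structure (gaps are ignored); the
reported β is the contrast at the harmonic reference.

**Daily steps** — negative-binomial regression (NB2, log link) of the daily
total on {1, L, centred log wear minutes}. The dispersion is reported as
theta = 1/alpha (variance μ + μ²/θ).

**Daily intensity minutes** — log(minutes + 1) on {1, L, centred wear
minutes} with AR(1) errors over the day sequence. The +1-minute offset keeps
zero-minute days finite and is negligible against daily totals; a fit is
refused when the category is absent on more than half the days (the offset,
not behaviour, would then drive the estimate).

Daily models cannot carry minute-resolution harmonics; the wear-habit
adjustment enters instead as the daily wear covariate. Both that form and a
no-adjustment form are available (`wear_adjust="wear" | "none"`).

Numerical choices: AR coefficients are estimated by iterated
Prais–Winsten/Yule–Walker updates (statsmodels GLSAR) with convergence
tolerance 1e-8 and a 50-iteration cap — deterministic, no random
initialisation; with the AR order set to 0 the fit is exactly OLS. NB fits
use Newton with a BFGS fallback. Minimum fit sizes default to 30 days (daily
models) and 5,000 minutes (METs model) per interruption state; fits with
less data, or non-finite standard errors, raise rather than return garbage.

## Pooling and significance

Per-participant coefficients for one outcome are combined by fixed-effect
(inverse-variance) meta-analysis: w_i = 1/se_i², β̂ = Σw_iβ_i/Σw_i,
se = (Σw_i)^(−1/2). No heterogeneity statistics are computed and no
random-effects model is offered — the two-stage fixed-effect pooling is the
analysis this package implements. The pooled coefficient is expressed as a
relative rate rr = exp(β̂) and Δ% = 100·(rr − 1) with a normal-theory 95% CI
(±1.96·se on the log scale, then transformed); the effect is significant
when the Δ% interval excludes zero. No multiplicity adjustment is applied
across outcomes.

## Power

For daily step counts following a negative binomial with dispersion θ
(variance μ + μ²/θ), the power of a two-sided two-group comparison at level
α uses a Wald statistic on the difference of log group means, whose
per-group variance by the delta method is (1/μ + 1/θ)/n. All observed days
are treated as exchangeable, so "100 days per period for 11 participants"
enters as n = 1,100 per group — the clustered per-participant reading is a
known alternative, not implemented. A Monte-Carlo mode simulates two-group
datasets, applies the same Wald test with plug-in moment estimates, and
returns the rejection rate; it verifies the analytic formula and returns
≈ α under the null ratio of 1.

## Synthetic cohort generator

No minute-level cohort data are deposited with the motivating study, so the
generator is a first-class module that produces data with the structure the
analysis assumes, plus a *known* interruption effect for parameter-recovery
testing.

Defaults mirror the study scale: 11 participants, ~123 days pre / ~100 days
post cutoff (staggered ±15 days per participant), pre-period mean 10,000
steps/day with lognormal participant-level spread (sd 0.25 on the log
scale), NB day-total dispersion θ = 5, day-level AR(1) log-noise
(ρ = 0.3, sd 0.15), nightly sleep 23:00–06:30, ~0.3 nonwear episodes/day of
mean 45 minutes. Pre-period occupancy {sedentary 0.785, light 0.18, fair
0.012, very 0.023} and mean bout lengths {12, 2.6, 1.6, 9} minutes give
daily summaries and w50 values of realistic magnitude. The default
interruption multiplies expected daily steps by 0.91 (Δ% −9), sedentary
occupancy by 1.03 (other categories renormalised), and sedentary /
very-active mean bout lengths by 1.2 / 1.25 — the directions and rough sizes
of the published shifts, so that both the daily-minutes models and w50 have
recoverable signals.

Mechanics worth knowing:

* **State chain.** Successive states are drawn i.i.d. from entry
  probabilities q with geometric dwells of mean m; identical consecutive
  draws merge, making realised bouts geometric with mean m_j/(1−q_j). A
  fixed point solves (q, m) so realised bout means equal the configured
  dwell means while long-run occupancy equals the configured occupancy
  exactly. Geometric (memoryless) dwells keep every bout-level oracle
  simple, including truncation at the day boundary.
* **MET emission.** Uniform within each category's classification band
  ([1, 1.45], [1.5, 2.95], [3, 5.9], [6, 9]), so classifying emitted METs
  reproduces the generating category exactly.
* **Steps.** Day totals are NB(μ_d, θ) with
  μ_d = base · ratio^L · exp(e_d − sd²/2) (AR(1) e_d, mean-corrected), then
  multinomially allocated to worn waking minutes with weights rising with
  intensity (1.5 : 25 : 70 : 130).
* **Circadian structure.** A fraction `circadian_amplitude` (default 0.4) of
  non-sedentary bouts is anchored toward midday when bouts are laid out
  within the day. Because this only reorders bouts, occupancy and
  bout-length distributions are untouched while steps and METs acquire a
  daytime profile. Modulating entry probabilities instead would have made
  the occupancy oracle approximate.
* **Nonwear / sleep.** Nonwear episodes zero the heart rate (and receive no
  steps); sleep minutes are flagged, carry METs 1.0 and heart rate 55.

What the generator does **not** emulate: physiological heart-rate dynamics
(worn/not-worn signalling only), weekday/weather structure, device sync
artefacts, autocorrelated occupancy (day-to-day intensity composition is
independent given the period), or intervention-induced trends. Passing
recovery tests therefore show the estimators are consistent and calibrated
under the assumed structure — not that the motivating study's point
estimates are reproduced, which is impossible without the original data.

## Problem sizes used in the checks

The recovery check uses 25 replicate cohorts of 11 participants at ~120/~100
days; measured against the known truths (Δ% −9 steps, +3 sedentary), pooled
CIs achieve ~95% coverage and the median pooled Δ% lands within a fraction
of a point of truth. The false-positive check uses 200 null cohorts at 40/40
days per participant; mild inflation above the nominal 5% is expected
because the NB day model ignores the generator's small AR(1) day-level
correlation, and the observed rate stays within 2–10%. The power
calculation's Monte-Carlo verification uses 5,000 replicates.

## Known limitations

* AR structure is first-order and treats observed sequences as equally
  spaced; long gaps are not down-weighted.
* The fixed-effect pooling assumes a common effect; with 11 heterogeneous
  participants the pooled Δ% is a precision-weighted average, not a
  population mean.
* The NB daily model absorbs lognormal day-level noise into its dispersion
  but not its autocorrelation; standard errors are slightly anti-conservative
  when day-to-day correlation is strong.
* w50's attained-value tie rule can differ from interpolated weighted-median
  definitions by up to one bout-duration step on tiny bout sets.
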