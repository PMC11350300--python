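# Methods

## The detection problem

Chronic heart failure decompensates episodically: fluid retention drives a
weight ramp over days, gas exchange worsens (SpO2 falls), and heart rate
drifts up. Daily home self-measurement of these three signals allows a
simple threshold algorithm to flag new-onset acute heart failure (AHF)
early enough for outpatient diuretic adjustment. The cost of such a rule
set is false alerts — from atrial tachyarrhythmias (isolated high heart
rate), mis-taken measurements (especially weight typos), and respiratory
infections (desaturation plus tachycardia without weight gain). `hfalert`
implements the rule set, the episode adjudication, the patient-level
diagnostic evaluation, and a synthetic cohort on which all of it can be
exercised and calibrated.

## Alert rule

Two firing paths per day (see README for the formulas): one severe
abnormality (HR > 110 bpm, SpO2 < 90 %, gain ≥ 4 kg over baseline, or
≥ 4 kg within the 4-day window) fires alone; otherwise two concurrent mild
abnormalities (HR > 90 bpm, SpO2 < 92 %, gain ≥ 2 kg within 4 days) fire
together. Notable interpretation choices, all configurable through
`AlertRuleConfig`:

- **Comparison strictness.** Heart rate and SpO2 use strict comparisons
  ("above 110", "< 90 %"); weight gains use ≥ ("at least 4 kg"). Clinical
  descriptions of such rules mix "more than" and "at least" phrasing for
  weight; ≥ is the default and `weight_comparison="gt"` switches to strict.
- **Minor weight window.** The 2-kg minor criterion is evaluated over the
  same 4-day window as the major one. A 2-day variant appears in some
  protocol descriptions and is available as `minor_weight_window_days=2`.
- **Windowed gain on sparse records.** `Δ₄(t)` is the maximum of today's
  weight over *any* available prior weight within the window
  (`max_pairwise`), so a missing day does not blind the rule to a ramp; an
  `endpoint` variant compares strictly against day t−4.
- **Minor heart-rate band.** The mild criterion is implemented as
  HR > 90 with no upper bound rather than 90 < HR < 110: whenever
  HR > 110 the major path fires first, so the band cap is redundant, and
  dropping it keeps the flag set monotone in the measurement.
- **Baseline weight** is the first non-missing weight at or after
  enrollment — the simplest auditable convention for "baseline"; a
  median-of-first-7-days alternative is exposed
  (`derive_baseline_weight(..., method="median7")`).
- **No engine-level debouncing.** The engine reports every firing day;
  episode grouping is a separate, explicit step.

## Compliance

A monitoring day is *complete* when all three values are present; the
compliance fraction divides complete days by **calendar** days in the
window (days with no record count against compliance), and a patient is
compliant at ≥ 75 %. The alternative reading — counting individual values
rather than complete days — is stricter bookkeeping of the same behaviour
and was not implemented; the calendar-day denominator is the conservative
choice.

## Adjudication

Fired days merge into one episode when successive fired days are at most
`gap_days = 3` calendar days apart, mirroring the ~72-hour alert-resolution
workflow of nurse-led telemonitoring; with `gap_days = 0` no distinct days
merge. Episodes are labelled against ground truth with ±3 days of overlap
slack (`match_window_days`). When an episode overlaps both an AHF event and
a non-AHF event, AHF wins: detecting a true decompensation dominates. An
episode overlapping nothing is `unconfirmed/other` — `inaccurate_measurement`
is only assigned on overlap with an injected measurement-error event, so
cause shares are meaningful. Ground-truth event types are {AHF, arrhythmia,
infection, measurement_error}; injected infections are reported with cause
`bacterial_pneumonia`, while the `covid19` cause is reachable through the
external label-table path. Patient-level label: confirmed if *any* episode
is confirmed; a patient with only unconfirmed episodes is a false-positive
patient.

## Performance evaluation

The unit is the patient (alerted × true-AHF), which is how telemonitoring
audits report their 2×2 table. Undefined ratios (empty denominator) are
`None`, never 0. Percentages are reported at full precision — e.g.
PPV 28/39 = 71.79 % — rather than truncated to match any printed rounding.
Per-criterion metrics use a documented patient-level convention (tp = confirmed
patients whose confirming episodes include the family; fp = non-AHF patients
with any episode including it); published per-criterion cells from the
original audit are not reconstructible under any single convention we could
derive, so they are informative output only, not a validation target. The
2×2 association test is chi-square with continuity correction, switching to
Fisher's exact test when any expected cell is below 5 (standard
contingency-table practice).

## Synthetic cohort

`SimulationConfig` defaults describe a 111-patient, 365-day cohort:

| parameter | default | rationale |
|---|---|---|
| baseline weight | log-normal, median 75 kg, σ=0.24 | matches a 64–89 kg IQR |
| baseline SpO2 | N(96, 1) truncated to [94.5, 98.5] % | stable outpatients |
| baseline HR | N(68, 7) truncated to [55, 80] bpm | uncontrolled tachycardia is an exclusion criterion |
| daily noise SD | 0.3 kg / 1 % / 5 bpm | self-measurement variability |
| missingness | 5 % per value per day | high-compliance population (≈86 % complete days) |
| p_ahf | 0.25 per patient-year | one in four patients decompensates |
| AHF ramp | 0.5–1.0 kg/day for 7–12 days, then 5–9 day decay | congestion then diuresis |
| in-event SpO2 | clipped to [90.0, 91.4] % (detectable regime) | corroborates the ramp without firing the major oxygen path alone |
| in-event HR | +5–15 bpm | mild sympathetic drive |
| p_measurement_error / p_arrhythmia / p_infection | 0.070 / 0.042 / 0.028 | see calibration |

Weights are quantised to 0.1 kg (home scale resolution), SpO2 and HR to
integers. In the default *detectable* regime ramp rates are drawn on a
0.1 kg/day grid from 0.5 kg/day up, so every injected decompensation
satisfies the 2 kg / 4-day minor threshold exactly even after quantisation
— decompensations are detectable by construction, reflecting audits in
which no AHF went unalerted. `detectable_only=False` lifts the clamps and
permits sub-threshold "silent" events for stress-testing. Measurement
errors are single-day artifacts (70 % weight typos of +5–9 kg, 30 % low
SpO2 probe misreads of 60–85 %), drawn in the first ~120 days where device
misuse concentrates; arrhythmias are 1–3 days of HR 115–150; infections are
3–6 days of SpO2 87.5–91 % with HR 93–108 bpm.

**Calibration.** The false-alert probabilities were set by closed form, not
by fitting: a non-AHF patient should false-alert with probability
11/83 ≈ 0.133 (the audited false-positive rate) with causes in a 5:3:2
ratio (measurement error : arrhythmia : infection). Solving
1 − (1−p₁)(1−p₂)(1−p₃) ≈ 0.133 under that ratio gives 0.070/0.042/0.028.
With p_ahf = 0.25 the expected structure of a 111-patient cohort is ≈28
true decompensations (all detected), ≈11 false-alert patients, ≈39 alerted
— i.e. sensitivity 1.0, specificity ≈ 0.867, PPV ≈ 0.72.

**Reproducibility.** One child RNG stream per patient is spawned from the
master seed (`numpy` `SeedSequence.spawn`), so patient *k*'s trajectory is
unchanged when the cohort grows, and identical configs give byte-identical
cohorts.

**What the simulator does not model.** Demographics and comorbidities
(irrelevant to the threshold rule); treatment response (confirmation is an
overlap-with-truth rule, not a diuretic simulation); within-event
trajectory shapes beyond the linear-ramp/plateau forms chosen here (real
decompensations vary); autocorrelated or seasonally drifting baselines;
informative missingness (a deteriorating patient may measure *less*).
Passing tests therefore demonstrate correctness of the rule engine and
evaluation machinery and internal consistency of the calibrated operating
point — not field performance on real patients.

## Problem sizes and numerical choices

The Monte-Carlo checks average 20 independently seeded default cohorts
(111 patients × 365 days each, ≈10 s total), which puts the standard error
of the specificity mean near 0.008 — an order of magnitude inside the
tolerance used. Order statistics (median, IQR) use the linear-interpolation
percentile convention of `numpy.percentile`. Episode merging ties are
impossible by construction (decisions are strictly date-ordered);
degenerate inputs (empty cohorts, all-missing days, undefined ratios,
empty summaries) return empty/missing values rather than raising, except
where a precondition is violated (no weight ever recorded, empty
compliance window, all-zero contingency table), which raise typed errors.
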