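# Methods

This note records the modeling assumptions, parameter choices, and
numerical conventions behind `mclir`. It is the place to look when a result
depends on a convention rather than on the science.

## Natural-history model

Each simulated individual carries a smoking history and, conditionally, one
lung tumor with a full latent trajectory:

1. **Onset.** Tumor onset age is drawn from a proportional-hazards model
   `h(a) = h0(a) · exp(β_py · PY(a) + β_cur · cur(a)) · m_sex`, where
   `h0` is a Weibull or constant baseline, `PY(a)` is pack-years
   accumulated by age `a` (cigarettes/day ÷ 20 × years smoked, frozen at
   the quit age), `cur(a)` indicates current smoking, and `m_sex` is a
   sex multiplier. `β_py ≥ 0` is enforced so risk is non-decreasing in
   cumulative dose. Pack-years enter the hazard as a time-varying
   covariate, so a quitter's hazard flattens rather than drops.
2. **Sojourn.** The preclinical, screen-detectable phase lasts a random
   sojourn time `S` drawn from the profile's distribution (exponential,
   Weibull, lognormal, fixed, or a two-component mixture — the mixture is
   how profiles encode an indolent subpopulation / long-sojourn tail).
   Clinical diagnosis occurs at `onset + S` in the absence of screening.
3. **Stage progression.** The preclinical phase passes through stages
   I → II → III → IV. Profile fractions `f_1..f_4` (summing to 1) set the
   relative dwell lengths; the dwell in stage `k` is `f_k × span`. By
   default `span = S` (stage milestones scale with the sojourn), but a
   profile may fix `progression_span` to a constant (the bundled profiles
   use 3.2 y), in which case tumors with short sojourns are clinically
   diagnosed at an early stage and long-sojourn tumors progress to stage
   IV before diagnosis. The fixed-span option exists because a pure
   proportional partition makes the clinical stage the same for every
   tumor regardless of sojourn length, which defeats the stage-shift
   mechanism the framework is built to measure; with a fixed span, stage
   at diagnosis varies with sojourn time as it should. Optionally the
   fractions themselves are redrawn per-individual from a Dirichlet
   centered on `f` with a concentration parameter.
4. **Survival.** A clinically diagnosed cancer at stage `k` is cured with
   probability `cure_k` (non-increasing in stage unless a profile
   explicitly overrides the ordering); otherwise a death delay is drawn
   from the stage-specific death-time distribution. Screen detection
   re-evaluates survival at the (earlier) screen stage — the *stage shift*
   — and a profile may additionally multiply the cure probability by a
   `cure_boost ≥ 1` (capped at 1) to represent within-stage benefit of
   early detection. Other-cause death is fixed at age 100 so that window
   tallies isolate the disease process; lung-cancer deaths at or beyond
   that age are censored.

Individuals whose tumor would be clinically diagnosed before the screening
age are flagged `excluded` and removed from every scenario's denominator
(they could never be screen-detected), keeping the four scenarios on an
identical eligible cohort.

## Scenarios and common random numbers

The four scenarios (no screen; realistic sensitivity + realistic
treatment; realistic sensitivity + perfect treatment; perfect sensitivity +
perfect treatment) are evaluated on the same life histories using
inverse-CDF coupling. Each individual has one reserved detection uniform
`u`; a screen at stage `k` detects iff `u < sens_k`. Because a single `u`
is compared against nested thresholds, the detection sets are exactly
nested: everyone detected under realistic sensitivity is detected under
perfect sensitivity. Screen-survival draws come from reserved substreams,
so toggling the treatment mode perturbs nothing else. These choices make
the orderings `MCLIR ≥ RCLIR` and `MMOR ≥ ISMOR ≥ RMOR` path-wise
identities, not asymptotic facts, and make scenario differences free of
Monte-Carlo noise from unrelated draws.

All randomness derives from a counter-based Philox generator keyed by
`(seed, purpose)`, with twelve fixed purposes (detection, onset, sojourn,
stage fractions, cure, death delay, screen cure, …). Individual `i` takes
element `i` of each purpose stream, so any individual's draws are
reproducible from `(seed, i)` alone and extending the cohort never changes
earlier individuals.

## Metrics and conventions

- **Window.** Ages `[65, 81)` partitioned into 16 one-year bins `[A, A+1)`
  (half-open: a diagnosis at exactly 81.0 is outside the window; at 80.9 it
  is in the final bin).
- **Reductions.** `(1 − Σ scenario / Σ reference) × 100` over window
  clinical incidence (RCLIR/MCLIR) or window lung-cancer deaths
  (RMOR/ISMOR/MMOR). A zero reference raises `UndefinedMetricError`
  rather than returning a silent 0 or infinity; an empty outcomes table
  aggregates to an explicit all-zero series.
- **Mortality basis.** By default a death counts if the *death* falls in
  the window (`death_in_window`); `diagnosis_in_window` instead attributes
  deaths to diagnoses made in the window, for sensitivity analyses of the
  attribution convention.
- **Areas.** Incidence: `A = RCLIR`, `B = MCLIR − RCLIR`,
  `C = 100 − MCLIR`. Mortality: `A = RMOR`, `B = ISMOR − RMOR`,
  `C = MMOR − ISMOR`, `D = 100 − MMOR`. Rescaled "detectable-denominator"
  versions divide by `A+B(+C)`; conditional screen-detected shares are
  `100·A/(A+B)` and its complement, undefined (error) when `A+B = 0`.
- **Curves.** Per-year reduction curves use the same ratio per bin, with
  `NaN` flagging years whose reference count is zero. Stage-IV curves
  report the percentage of each year's clinical diagnoses made at stage IV
  under no screening, realistic sensitivity, and perfect sensitivity.
- **Rounding.** Reported values are rounded half-away-from-zero to one
  decimal (so 48.85 → 48.9), matching the convention of printed
  percentage tables; internal computation is never rounded.
- **Cross-profile summaries.** Median (midpoint for even counts) and
  model range (min, max) across profiles, computed on the rounded
  per-profile values as they would appear in a table.

## Sojourn-time recovery

Under perfect sensitivity, every preclinical case at the screen is
detected, and for each the full sojourn is observable as
`elapsed + lead time`. Prevalent cases oversample long sojourns
(length bias): under a locally stationary onset rate the probability a
tumor of sojourn `s` is preclinical at the screen is proportional to `s`.
The bin-mass estimator therefore weights each detection by `1/s`, which is
the exact renewal correction in the stationary case. Binned masses
(`<2`, `[2,4)`, `[4,5)`, `≥5` years, summing to 100) are reported with the
Kish effective sample size `(Σw)² / Σw²` so Monte-Carlo standard errors
account for the weighting; an estimate from fewer than 200 detections is
flagged `low_precision`.

## Bundled profiles

The five bundled profiles are **illustrative**
(`calibration_status: illustrative`): their stage-specific CT sensitivities
are published model values, while the remaining natural-history parameters
were chosen once as field-plausible defaults and are not calibrated to any
registry or trial. Shared choices: Weibull onset baseline (shape 5, scale
160 y) with `β_py = 0.018` per pack-year, `β_cur = 0.20`, female baseline
multiplier 0.9; stage dwell fractions (0.35, 0.15, 0.15, 0.35) of a fixed
3.2-year progression span; cure probabilities (0.55, 0.40, 0.22, 0.04) by
stage with exponential death delays of mean (5, 4, 2.5, 1.2) years.
Profiles differ in sensitivity vectors, sojourn shape (profiles flagged
`long_sojourn_tail` mix a mean-1.2 y exponential with an indolent
lognormal component; the others use a Weibull), whether screen detection
confers a within-stage cure boost (1.2 where present), and female
modifiers (sojourn scale 1.2–1.35, all > 1, reflecting the slower
progression consistently reported for women; mild sensitivity and cure
scales). Light-smoker modifiers on two profiles illustrate
profile-dependent risk gradients. These values produce reductions and
area decompositions of realistic magnitude for one-time CT screening of
heavy smokers (single-digit incidence reductions, mortality ceilings in
the teens) without claiming calibration.

## What is simulated versus real data

Everything is synthetic: the package emulates cohorts, tumors, and screens
rather than ingesting registry or trial data. The simulator's outputs play
the role that calibrated microsimulation models play in comparative
modeling studies — the object of study is the *consequence of assumptions*,
which the metrics isolate by construction. No claim is made that any
bundled profile reproduces a particular population's incidence or
mortality.

## Problem sizes and numerics

- Default cohort size 200,000: per-year window counts in the thousands,
  so one-decimal percentages are stable to Monte-Carlo noise; a full run
  (life histories + four scenarios) takes ~2 s on one core.
- Onset ages invert the cumulative hazard numerically on a 0.05-year age
  grid (trapezoidal integration + linear interpolation); the inversion is
  exact for constant hazards and the grid error is far below one decimal
  at the reported scales.
- Sojourn mixtures draw the component from a dedicated uniform and the
  value by inverse CDF, keeping the coupling property intact.
- Stage membership uses half-open intervals `[entry_k, entry_{k+1})`; the
  clinical stage is the stage occupied in the left limit at diagnosis.

## Limitations

- One screen at a single age; no repeat screening, no screening-related
  harms, no false positives or work-up cascades.
- Other-cause mortality is a fixed horizon, not a life table; competing
  risks are deliberately absent so that metric differences are pure
  disease-process effects.
- The bundled profiles are not calibrated; absolute numbers from them are
  illustrative, while orderings and decomposition identities hold by
  construction for any valid profile.
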