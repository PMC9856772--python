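# Methods

## Model structure

The disease process is a discrete-time Markov chain on six states —
healed, uninfected DFU (uDFU), infected DFU (iDFU), gangrene,
postamputation, death — with a one-month cycle and a five-year
(60-cycle) horizon. The cohort starts in uDFU, matching the trial
population (debrided, uninfected ulcers of Wagner grade 1–2). Death is
absorbing; there are no tunnel states, no time-varying probabilities,
and no background mortality beyond the constant monthly death
transitions of the input table. Both strategy arms share every
transition except uDFU→healed, which carries the treatment effect.

## Input parameters

All inputs live in `src/dfucea/data/on101_taiwan.yaml` (checksum
guarded): monthly transition probabilities, yearly health utilities in
[0, 1], monthly state costs and one-time event costs in 2021 USD, the
monthly drug cost ($608), and the healing odds ratio (2.30). Costs and
outcomes are discounted at 3%/year, applied as (1.03)^(−t/12) per
monthly cycle (an annual-step switch exists). Sensitivity ranges are
±50% of base for probabilities, costs and the OR, and ±10% for
utilities, as shipped in the file.

## Calibration of ambiguous inputs

Read literally, several printed monthly values are implausible (21.1%
of healed patients becoming infected ulcers each month; 43% of
amputees developing gangrene each month) and jointly incompatible with
the published five-year occupancy profile (≈80–86% healed). Each such
row therefore carries an interpretation tag in the model file, and
`dfucea.calibration` enumerates the declared alternatives
(108 combinations), scoring each against (a) the published occupancy
profile and mean healed months of both arms and (b) the published
base-case increments, which discriminate among candidates that tie on
occupancy. The shipped tags are the winner:

- **healed→uDFU 0.038** is the monthly recurrence probability;
  **healed→iDFU 0.211** is the conditional probability that a
  recurrence presents infected (entry 0.038 × 0.211);
- **uDFU→iDFU 0.068** is conditional on the ulcer persisting (entry
  0.068 × (1 − 0.259)); the conditional uses the unadjusted healing
  probability in both arms so that all non-healing transitions remain
  identical across strategies;
- **iDFU→iDFU 0.084** is an explicitly printed self-transition; the
  row residual (0.863) is routed to healed — an infection episode is
  treated and resolves on the one-month time scale;
- **postamputation→gangrene 0.43** is excluded from the matrix (the
  literal reading implies an amputation↔gangrene cycle that inflates
  costs by ~40% and depresses healed occupancy far outside the
  published profile);
- the healing OR is applied as a **direct risk multiplier**
  (0.259 × 2.30 = 0.5957). The odds-scale transform (0.4457) is
  implemented and selectable, but under it the incremental QALY gain
  falls to 0.029 versus the published 0.038, while the multiplier
  reproduces the published increments almost exactly.

With these choices the model reproduces, deterministically: healed
occupancy 79.5%/85.2% (published 79.7/85.6), healed months 47.4/52.0
(47.4/52.6), ΔCost $572 (571), ΔQALY 0.0384 (0.0383), ICER $14,905
(14,922), and arm totals $9,257/$9,829 (9,210/9,781). The
literal-as-printed variant is also shipped
(`load_paper_parameters(variant="literal")`) and regression-tested.

## Accrual conventions

No half-cycle correction (a trapezoid correction is a switch); rewards
accrue on start-of-cycle occupancy; the death cycle earns no partial
life-year credit. The drug cost accrues while the intervention-arm
patient occupies uDFU, uncapped; a duration cap (e.g. the 16-week
trial course, 4 cycles) and a wider accrual set (uDFU + iDFU) are
configuration options. The initial work-up cost ($161) is charged once
at cycle 0. Event costs attach to transition flows: hospitalization
for infection on any →iDFU flow from a non-postamputation state,
hospitalization for amputation on any →postamputation flow, and the
postamputation infection/gangrene admissions on the corresponding
flows out of postamputation; the mapping is data, editable in the
model file.

## Microsimulation

Event counts come from 10,000 simulated patients per arm (a separate
categorical draw per patient-cycle from the arm's matrix row, one
shared seed-derived stream per arm, no common random numbers across
arms by default). An event is every entry transition into healed,
iDFU, gangrene or postamputation — counted per occurrence, not per
patient — so a patient can contribute several healing events across
recurrences. Expected totals agree with the cohort flows by
construction and are tested to within three Monte-Carlo standard
errors.

## Probabilistic sensitivity analysis

All ranged inputs are redrawn independently each iteration: beta for
probabilities (method of moments, mean = base, sd = range/3.92),
uniform for utilities (hard bounds), triangular for costs (mode =
base), lognormal for the OR (median = base, sd of log =
ln(high/low)/3.92). Draws producing an invalid matrix (the sampled
OR times the sampled healing probability can push the uDFU row above
1) are resampled whole and counted (~5% of iterations). 10,000
iterations; decisions are summarised by net monetary benefit and the
CEAC on a $0–150,000 grid that always contains the two thresholds
exactly. Signed ICERs are reported (median, and the mean with its
known cross-quadrant pathology flagged in the report metadata) but
never used for decisions.

## Threshold searches

Break-even multipliers and two-way OR thresholds are Brent roots
(tolerances 0.001 on the multiplier, 0.005 on the OR). Incremental
cost is strictly increasing in the drug-cost multiplier, so a
bracketed break-even root is unique; unbracketed criteria return
explicit "always"/"never" results. Roots are verified in tests by sign
change of the criterion at root ± tolerance.

## What the shipped model does and does not reproduce

Reproduced within tight tolerances: the base-case economics, occupancy
profile, healed months, healing events gained (≈2,770 ± 200 per
10,000 patients vs 2,787), CEAC probabilities (±3 percentage points)
and the break-even/two-way thresholds to within ~15%.

Not reproduced, under any interpretation combination examined:

- **the one-year-horizon ICER** ($9,459 published; ≈$25,000 here).
  In this model the drug cost is front-loaded (≈47% accrues in year
  one) while the savings from averted complications accrue roughly in
  proportion to the occupancy gap, so the short-horizon ICER is
  necessarily *above* the five-year one; no accrual variant that
  matches the five-year increments can invert that ordering. Capping
  the drug at the 16-week trial course yields ≈$10,700 at one year but
  flips the five-year incremental cost to −$1,029.
- **infected-DFU events averted** (2,766 published; ≈1,750 here).
  Counting every entry into iDFU, the intervention arm's larger healed
  population feeds back more infected recurrences, damping the
  aversion; counting only uDFU→iDFU entries would give ≈2,560 but is
  not the declared event definition.
- the tornado's second rank (drug cost published; here the
  healing-state utility edges it into third).

These three are asserted at their published values in the acceptance
tests and left failing deliberately rather than tuned away.

## Synthetic models and the limits of testing

`generate_random_model` produces random valid six-state models (random
sub-stochastic exit blocks with an absorbing death state, uniform
utilities, positive costs, log-uniform effect sizes) used by the
property tests: row-stochasticity, matrix-power oracle agreement,
finiteness and QALY ≤ life-year bounds. These models exercise the
engine's algebra, not DFU epidemiology; passing them shows the
machinery is correct, not that the shipped parameterisation is
clinically right. Real-data features deliberately absent: parameter
correlation in the PSA, patient-level covariate heterogeneity,
time-varying risks, and any recalibration of the input table against
primary sources.
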