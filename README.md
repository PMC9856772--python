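# dfucea

Cost-effectiveness modelling of wound-care strategies for diabetic foot
ulcers (DFUs), built around a six-state monthly Markov state-transition
model. The shipped model compares a macrophage-regulating topical
treatment (ON101 cream) added to general wound care (GWC) against GWC
alone, from the Taiwan health-care-sector perspective with costs in
2021 USD, and is aimed at health-economics researchers and modellers
who want a scriptable, testable version of this class of analysis.

## The model

A hypothetical cohort starts with an uninfected DFU (uDFU) and moves
monthly among six mutually exclusive states — healed, uDFU, infected
DFU (iDFU), gangrene, postamputation, death (absorbing) — according to
a transition matrix **P** built from published monthly probabilities.
The intervention arm differs only in the uDFU→healed entry, which is
scaled by the trial's healing odds ratio (OR = 2.30); how the OR maps
onto the probability (direct risk multiplication or the odds-scale
transform p′ = OR·p/(1−p) / (1 + OR·p/(1−p))) is a model-file switch.

Per cycle *t*, with discount factor d(t) = 1.03^(−t/12), each arm
accrues

- cost: state costs on occupancy, one-time event costs (hospitalization
  for infection, amputation, postamputation complications) on
  transition flows, the monthly drug cost while the intervention arm
  occupies the uDFU state, and a one-time initial work-up cost;
- QALYs: occupancy-weighted health utilities / 12;
- life-years: the surviving fraction / 12.

The incremental cost-effectiveness ratio is ICER = ΔCost/ΔQALY,
assessed against the Taiwan willingness-to-pay thresholds of
$32,787/QALY (highly cost-effective) and $98,361/QALY
(cost-effective). Uncertainty is handled by a probabilistic
sensitivity analysis (all inputs redrawn jointly from beta, uniform,
triangular and lognormal distributions; decisions summarised by net
monetary benefit and the cost-effectiveness acceptability curve), a
one-way tornado analysis, a two-way drug-cost × effect-size threshold
scan, and a break-even search on the drug cost. A separate
microsimulation engine draws individual patient paths from the same
matrices to count discrete clinical events (healings, infections,
gangrene, amputations).

Several printed transition values are ambiguous read literally; the
package resolves them with an explicit calibration step documented in
`docs/methods.md`, and every interpretation is a tagged, editable
field of the model file (`src/dfucea/data/on101_taiwan.yaml`).

## Worked example

```sh
$ dfucea basecase
 strategy  total_cost  incremental_cost  life_years  qalys  incremental_qalys    icer dominance
      GWC        9257               NaN      4.5169 3.6995                NaN     NaN      None
ON101+GWC        9829             572.0      4.5182 3.7379             0.0384 14905.0     ratio
```

Over five years the intervention arm costs $572 more per patient and
gains 0.0384 QALYs, an ICER of $14,905/QALY — well under the
$32,787/QALY threshold, i.e. highly cost-effective. The same numbers
are available programmatically:

```python
import dfucea

fixture = dfucea.load_paper_parameters()          # checksum-verified
result = dfucea.compare_strategies(fixture.model, fixture.definition.strategies())
print(result.delta_cost, result.delta_qalys, result.icer)
# 572.13 0.03839 14904.6
```

Threshold analyses from the command line:

```sh
$ dfucea breakeven
break-even multiplier: 0.782 (78.2%)      # drug below 78% of list price is cost-saving
$ dfucea twoway
drug $304/mo: minimum OR 1.293 (root)     # effect size needed at each price
drug $608/mo: minimum OR 1.586 (root)
drug $912/mo: minimum OR 1.878 (root)
```

Other subcommands: `psa` (acceptability curve, median ICER),
`dsa` (tornado), `microsim` (event counts per 10,000 patients),
`scenario` (horizon, subgroup OR or price overrides) and `report`
(tables + figures + reproducibility manifest). All accept
`--model FILE` to run a user-edited model file and `--seed` where
randomness is involved.

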