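# Six-state monthly Markov model of diabetic foot ulcer progression:
# ON101 cream + general wound care (GWC) vs GWC alone, Taiwan health
# care sector perspective, costs in 2021 USD.
#
# Values, ranges and distribution families are as printed in the source
# table.  Interpretation tags record how each printed number enters the
# transition matrix; the shipped tags are the calibrated defaults
# selected by dfucea.calibration (see docs/methods.md for the
# rationale and the alternatives).

name: on101-taiwan-2021

states: [healed, uDFU, iDFU, gangrene, postamputation, death]

settings:
  cycle_length_months: 1
  horizon_cycles: 60
  discount_rate_annual: 0.03
  wtp_thresholds: [32787, 98361]
  initial_state: uDFU
  # How the healing odds ratio is applied to the uDFU->healed
  # probability: "risk_ratio" (direct multiplication, calibrated
  # default) or "odds" (odds-scale transform).
  effect_mode: risk_ratio

transitions:
  - {label: uDFU to healing, from: uDFU, to: healed,
     value: 0.259, low: 0.1295, high: 0.3885, distribution: beta,
     interpretation: direct}
  # Infection risk of a persisting ulcer: conditional on not healing
  # in the cycle, so the matrix entry is 0.068 * (1 - 0.259).  The
  # conditional uses the unadjusted healing probability in both arms,
  # keeping all non-healing transitions equal across strategies.
  - {label: uDFU to iDFU, from: uDFU, to: iDFU,
     value: 0.068, low: 0.034, high: 0.102, distribution: beta,
     interpretation: conditional, parent: uDFU to healing, parent_complement: true}
  - {label: uDFU to death, from: uDFU, to: death,
     value: 0.001, low: 0.0005, high: 0.0015, distribution: beta,
     interpretation: direct}
  # Printed explicitly as a self-transition; the row residual (what is
  # left after the printed self, amputation, gangrene and death exits)
  # is routed to healed: an infection episode resolves quickly.
  - {label: iDFU to iDFU, from: iDFU, to: iDFU,
     value: 0.084, low: 0.042, high: 0.126, distribution: beta,
     interpretation: self}
  - {label: iDFU to postamputation, from: iDFU, to: postamputation,
     value: 0.016, low: 0.008, high: 0.024, distribution: beta,
     interpretation: direct}
  - {label: iDFU to gangrene, from: iDFU, to: gangrene,
     value: 0.036, low: 0.018, high: 0.054, distribution: beta,
     interpretation: direct}
  - {label: iDFU to death, from: iDFU, to: death,
     value: 0.001, low: 0.0005, high: 0.0015, distribution: beta,
     interpretation: direct}
  # Ulcer recurrence after healing; 0.211 is the conditional
  # probability that a recurrence presents infected, so the healed ->
  # iDFU entry is 0.038 * 0.211.
  - {label: Healing to progression, from: healed, to: uDFU,
     value: 0.038, low: 0.019, high: 0.057, distribution: beta,
     interpretation: direct}
  - {label: Healing to iDFU, from: healed, to: iDFU,
     value: 0.211, low: 0.1055, high: 0.3165, distribution: beta,
     interpretation: conditional, parent: Healing to progression}
  - {label: Healing to death, from: healed, to: death,
     value: 0.001, low: 0.0005, high: 0.0015, distribution: beta,
     interpretation: direct}
  - {label: Postamputation to iDFU, from: postamputation, to: iDFU,
     value: 0.007, low: 0.0035, high: 0.0105, distribution: beta,
     interpretation: direct}
  # Implausible as a literal monthly probability (it implies a heavy
  # amputation<->gangrene cycle incompatible with the published state
  # occupancies and costs); excluded from the matrix by calibration,
  # kept here for provenance.
  - {label: Postamputation to gangrene, from: postamputation, to: gangrene,
     value: 0.43, low: 0.215, high: 0.645, distribution: beta,
     interpretation: excluded}
  - {label: Postamputation to death, from: postamputation, to: death,
     value: 0.003, low: 0.0015, high: 0.0045, distribution: beta,
     interpretation: direct}
  - {label: Gangrene to postamputation, from: gangrene, to: postamputation,
     value: 0.313, low: 0.1565, high: 0.4695, distribution: beta,
     interpretation: direct}
  - {label: Gangrene to death, from: gangrene, to: death,
     value: 0.01, low: 0.005, high: 0.015, distribution: beta,
     interpretation: direct}

residual_to:
  iDFU: healed

utilities:  # per year, uniform sampling over the +-10% range
  - {state: healed, value: 0.84, low: 0.756, high: 0.924, distribution: uniform}
  - {state: uDFU, value: 0.75, low: 0.675, high: 0.825, distribution: uniform}
  - {state: iDFU, value: 0.7, low: 0.63, high: 0.77, distribution: uniform}
  - {state: gangrene, value: 0.69, low: 0.621, high: 0.759, distribution: uniform}
  - {state: postamputation, value: 0.59, low: 0.531, high: 0.649, distribution: uniform}

state_costs:  # 2021 USD per monthly cycle
  - {state: healed, value: 9, low: 4, high: 13, distribution: triangular}
  - {state: uDFU, value: 97, low: 49, high: 146, distribution: triangular}
  - {state: iDFU, value: 160, low: 80, high: 240, distribution: triangular}
  - {state: gangrene, value: 231, low: 116, high: 347, distribution: triangular}
  - {state: postamputation, value: 504, low: 252, high: 756, distribution: triangular}

event_costs:  # one-time 2021 USD, charged on the listed transition flows
  - label: Hospitalization for infection
    cost: 8847
    low: 4423
    high: 13270
    distribution: triangular
    transitions: [[uDFU, iDFU], [healed, iDFU], [gangrene, iDFU]]
  - label: Hospitalization for amputation
    cost: 7552
    low: 3776
    high: 11328
    distribution: triangular
    transitions: [[iDFU, postamputation], [gangrene, postamputation]]
  - label: Hospitalization for postamputation infection
    cost: 13583
    low: 6791
    high: 20374
    distribution: triangular
    transitions: [[postamputation, iDFU]]
  - label: Hospitalization for postamputation gangrene
    cost: 13583
    low: 6791
    high: 20374
    distribution: triangular
    transitions: [[postamputation, gangrene]]

initial_event:  # ulcer work-up charged once at cycle 0
  cost: 161
  low: 80
  high: 241
  distribution: triangular

drug:  # ON101 cream, intervention arm only
  monthly_cost: 608
  low: 304
  high: 912
  distribution: triangular
  states: [uDFU]          # accrues while an uninfected ulcer persists
  duration_cap_cycles: null

effect:  # complete-healing effect size, ON101+GWC vs GWC alone
  odds_ratio: 2.30
  low: 1.15
  high: 3.45
  distribution: lognormal
  transition: [uDFU, healed]
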