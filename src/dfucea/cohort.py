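"""Deterministic Markov cohort simulation and cost-effectiveness accounting.

The cohort engine propagates a state-occupancy vector through the
monthly transition matrix, records the per-cycle transition flows, and
accumulates discounted costs, life-years and quality-adjusted life-years
(QALYs) per strategy arm.  Costs have four components: monthly state
costs, one-time event costs on transition flows, the drug cost accrued
in the treated states of the intervention arm, and the initial work-up
cost at cycle 0.

Accrual conventions (all exposed as switches on the parameter set):

* rewards are credited on start-of-cycle occupancy with no half-cycle
  correction by default; a trapezoid half-cycle correction is optional;
* discounting is continuous monthly compounding, ``(1+r)^(-t/12)``,
  with annual-step discounting optional;
* the death state accrues nothing, so life-years count the fraction of
  the cohort alive at the start of each cycle.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass

import numpy as np

from .model import ParameterSet, StrategyConfig, validate_transition_matrix
from .states import N_STATES, STATE_INDEX, STATES, HealthState


def discount_factor(
    annual_rate: float, cycle_index: int, annual_step: bool = False
) -> float:
    """Discount factor for a monthly cycle index.

    ``(1 + rate)^(-t/12)`` by default; with ``annual_step`` the factor
    steps once per completed model year.  Equals 1 at cycle 0.
    """
    if cycle_index < 0:
        raise ValueError("cycle index must be non-negative")
    if annual_rate < 0:
        raise ValueError("discount rate must be non-negative")
    exponent = (cycle_index // 12) if annual_step else (cycle_index / 12)
    return float((1.0 + annual_rate) ** (-exponent))


@dataclass(frozen=True)
class CohortTrace:
    """Occupancy and flow history of a cohort run.

    ``occupancy[t]`` is the state distribution at the start of cycle
    ``t`` (``t = 0 .. horizon``); ``flows[t][i, j]`` is the fraction of
    the cohort moving i -> j during cycle ``t``.
    """

    occupancy: np.ndarray  # (horizon+1, 6)
    flows: np.ndarray  # (horizon, 6, 6)

    @property
    def horizon_cycles(self) -> int:
        return self.flows.shape[0]

    def state_occupancy(self, state: HealthState) -> np.ndarray:
        return self.occupancy[:, STATE_INDEX[state]]

    def months_in_state(self, state: HealthState) -> float:
        """Undiscounted expected months in ``state`` (one month credited
        per cycle of start-of-cycle occupancy over the horizon)."""
        return float(self.state_occupancy(state)[:-1].sum())

    def entries_into(self, state: HealthState) -> float:
        """Expected entry transitions into ``state`` per cohort member."""
        j = STATE_INDEX[state]
        inflow = self.flows[:, :, j].sum() - self.flows[:, j, j].sum()
        return float(inflow)


def run_cohort(
    matrix: np.ndarray,
    initial_state: HealthState,
    horizon_cycles: int,
) -> CohortTrace:
    """Propagate a unit cohort from ``initial_state`` for ``horizon_cycles``."""
    if horizon_cycles < 1:
        raise ValueError("horizon must be at least one cycle")
    validate_transition_matrix(matrix)
    occupancy = np.zeros((horizon_cycles + 1, N_STATES))
    flows = np.zeros((horizon_cycles, N_STATES, N_STATES))
    v = np.zeros(N_STATES)
    v[STATE_INDEX[initial_state]] = 1.0
    occupancy[0] = v
    for t in range(horizon_cycles):
        flows[t] = v[:, None] * matrix
        v = v @ matrix
        occupancy[t + 1] = v
    return CohortTrace(occupancy=occupancy, flows=flows)


@dataclass(frozen=True)
class ArmOutcome:
    """Discounted totals and occupancy summaries for one strategy arm."""

    strategy: str
    total_cost: float
    life_years: float
    qalys: float
    cost_components: dict[str, float]
    mean_months_in_state: dict[HealthState, float]
    cumulative_probability: dict[HealthState, float]

    def __post_init__(self) -> None:
        if self.qalys > self.life_years + 1e-9:
            raise ValueError("QALYs exceed life-years; utilities above 1?")


def accumulate_outcomes(
    trace: CohortTrace,
    params: ParameterSet,
    strategy: StrategyConfig,
    matrix: np.ndarray | None = None,
) -> ArmOutcome:
    """Accumulate discounted cost, life-years and QALYs over a trace."""
    horizon = trace.horizon_cycles
    util = np.array([params.utilities.get(s, np.nan) for s in STATES])
    scost = np.array([params.state_costs.get(s, np.nan) for s in STATES])
    live = [s for s in STATES if s != HealthState.DEATH]
    if np.isnan(util[[STATE_INDEX[s] for s in live]]).any():
        missing = [str(s) for s in live if s not in params.utilities]
        raise ValueError(f"missing utilities for states: {missing}")
    if np.isnan(scost[[STATE_INDEX[s] for s in live]]).any():
        missing = [str(s) for s in live if s not in params.state_costs]
        raise ValueError(f"missing state costs for states: {missing}")
    util = np.nan_to_num(util)
    scost = np.nan_to_num(scost)

    event = np.zeros((N_STATES, N_STATES))
    for (i, j), c in params.event_costs.items():
        event[STATE_INDEX[i], STATE_INDEX[j]] += c
    drug_ind = np.zeros(N_STATES)
    if strategy.apply_healing_or:
        for s in strategy.drug_cost_states:
            drug_ind[STATE_INDEX[s]] = 1.0
    alive = np.ones(N_STATES)
    alive[STATE_INDEX[HealthState.DEATH]] = 0.0

    state_cost = drug_cost = event_cost = 0.0
    qalys = life_years = 0.0
    cap = strategy.drug_duration_cap_cycles
    for t in range(horizon):
        d = discount_factor(
            params.discount_rate_annual, t, params.annual_step_discounting
        )
        v = trace.occupancy[t]
        if params.half_cycle_correction:
            v = 0.5 * (trace.occupancy[t] + trace.occupancy[t + 1])
        state_cost += d * float(v @ scost)
        if cap is None or t < cap:
            drug_cost += d * params.drug_cost_monthly * float(v @ drug_ind)
        event_cost += d * float((trace.flows[t] * event).sum())
        qalys += d * float(v @ util) / 12.0
        life_years += d * float(v @ alive) / 12.0

    initial_cost = params.initial_event_cost
    total = state_cost + drug_cost + event_cost + initial_cost
    months = {s: trace.months_in_state(s) for s in STATES}
    final = {s: float(trace.occupancy[-1, STATE_INDEX[s]]) for s in STATES}
    return ArmOutcome(
        strategy=strategy.label,
        total_cost=total,
        life_years=life_years,
        qalys=qalys,
        cost_components={
            "state": state_cost,
            "event": event_cost,
            "drug": drug_cost,
            "initial": initial_cost,
        },
        mean_months_in_state=months,
        cumulative_probability=final,
    )


class Dominance(enum.Enum):
    """Quadrant of the incremental cost-effectiveness plane."""

    RATIO = "ratio"  # more costly, more effective (or both negative)
    DOMINANT = "dominant"  # cheaper and more effective: cost-saving
    DOMINATED = "dominated"  # more costly and less effective
    UNDEFINED = "undefined"  # no QALY difference


@dataclass(frozen=True)
class CEResult:
    """Incremental comparison of intervention vs comparator."""

    intervention: ArmOutcome
    comparator: ArmOutcome
    delta_cost: float
    delta_qalys: float
    icer: float | None
    dominance: Dominance
    nmb: dict[float, dict[str, float]]  # wtp -> strategy label -> NMB

    def nmb_difference(self, wtp: float) -> float:
        """NMB(intervention) - NMB(comparator) at willingness-to-pay ``wtp``."""
        d = self.nmb.get(wtp)
        if d is None:
            d = {
                self.intervention.strategy: wtp * self.intervention.qalys
                - self.intervention.total_cost,
                self.comparator.strategy: wtp * self.comparator.qalys
                - self.comparator.total_cost,
            }
        return d[self.intervention.strategy] - d[self.comparator.strategy]


def compute_icer(
    intervention: ArmOutcome,
    comparator: ArmOutcome,
    wtp_list: tuple[float, ...] = (),
) -> CEResult:
    """Incremental cost, QALYs, ICER with dominance flags, and NMB."""
    dc = intervention.total_cost - comparator.total_cost
    dq = intervention.qalys - comparator.qalys
    if math.isclose(dq, 0.0, abs_tol=1e-12):
        icer, dom = None, Dominance.UNDEFINED
    elif dc <= 0 and dq > 0:
        icer, dom = None, Dominance.DOMINANT
    elif dc >= 0 and dq < 0:
        icer, dom = None, Dominance.DOMINATED
    else:
        icer, dom = dc / dq, Dominance.RATIO
    nmb = {
        wtp: {
            intervention.strategy: wtp * intervention.qalys - intervention.total_cost,
            comparator.strategy: wtp * comparator.qalys - comparator.total_cost,
        }
        for wtp in wtp_list
    }
    return CEResult(
        intervention=intervention,
        comparator=comparator,
        delta_cost=dc,
        delta_qalys=dq,
        icer=icer,
        dominance=dom,
        nmb=nmb,
    )


def compare_strategies(
    params: ParameterSet,
    strategies: tuple[StrategyConfig, StrategyConfig] | None = None,
    values: dict[str, float] | None = None,
    horizon_cycles: int | None = None,
) -> CEResult:
    """Run both arms of the comparison and return the incremental result.

    ``strategies`` is the (comparator, intervention) pair; the default
    pair applies the healing effect and uDFU drug accrual to the
    intervention arm only.  ``values`` overrides printed transition
    values by label (sensitivity analyses); ``horizon_cycles`` overrides
    the parameter set's horizon (scenario analyses).
    """
    from .model import GWC, ON101, build_transition_matrix

    comparator, intervention = strategies if strategies is not None else (GWC, ON101)
    horizon = horizon_cycles if horizon_cycles is not None else params.horizon_cycles
    outcomes = []
    for strat in (comparator, intervention):
        matrix = build_transition_matrix(params, strat, values)
        trace = run_cohort(matrix, params.initial_state, horizon)
        outcomes.append(accumulate_outcomes(trace, params, strat, matrix))
    return compute_icer(outcomes[1], outcomes[0], params.wtp_thresholds)
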