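"""Individual-level Monte-Carlo simulation for clinical event counting.

The cohort engine yields expected values; the microsimulation engine
draws individual patient trajectories from the same monthly transition
matrix to count discrete clinical events: every entry into the healed,
infected-ulcer, gangrene and postamputation states, counted each time it
occurs (a patient whose ulcer recurs and heals again contributes several
healing events).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .model import validate_transition_matrix
from .states import N_STATES, STATE_INDEX, STATES, HealthState

#: States whose entry transitions are counted as clinical events.
EVENT_STATES: tuple[HealthState, ...] = (
    HealthState.HEALED,
    HealthState.IDFU,
    HealthState.GANGRENE,
    HealthState.POSTAMPUTATION,
)


@dataclass(frozen=True)
class PatientPath:
    """One simulated trajectory: states per cycle plus event tallies."""

    states: tuple[HealthState, ...]
    events: dict[HealthState, int]


@dataclass(frozen=True)
class EventSummary:
    """Aggregate event counts over a simulated patient population."""

    n_patients: int
    horizon_cycles: int
    totals: dict[HealthState, int]
    per_patient: dict[HealthState, np.ndarray]
    mean_months_in_state: dict[HealthState, float]
    seed: int

    def standard_error(self, event: HealthState) -> float:
        """Monte-Carlo standard error of the event total."""
        counts = self.per_patient[event]
        return float(np.sqrt(self.n_patients * counts.var(ddof=1)))


def simulate_patient(
    matrix: np.ndarray,
    horizon_cycles: int,
    rng: np.random.Generator,
    initial_state: HealthState = HealthState.UDFU,
) -> PatientPath:
    """Draw one patient path; each cycle's next state is a categorical
    draw from the current state's matrix row."""
    validate_transition_matrix(matrix)
    if horizon_cycles < 1:
        raise ValueError("horizon must be at least one cycle")
    state = STATE_INDEX[initial_state]
    path = [STATES[state]]
    events = {s: 0 for s in EVENT_STATES}
    for _ in range(horizon_cycles):
        nxt = rng.choice(N_STATES, p=matrix[state])
        if nxt != state and STATES[nxt] in events:
            events[STATES[nxt]] += 1
        state = nxt
        path.append(STATES[state])
    return PatientPath(states=tuple(path), events=events)


def run_microsim(
    matrix: np.ndarray,
    n_patients: int,
    horizon_cycles: int,
    seed: int,
    initial_state: HealthState = HealthState.UDFU,
) -> EventSummary:
    """Simulate ``n_patients`` independent paths and tally events.

    Vectorised across patients: each cycle draws one uniform variate per
    patient and maps it through the cumulative distribution of the
    patient's current matrix row.  Identical ``(seed, inputs)`` give an
    identical summary.
    """
    if n_patients < 1:
        raise ValueError("n_patients must be at least 1")
    if horizon_cycles < 1:
        raise ValueError("horizon must be at least one cycle")
    validate_transition_matrix(matrix)
    rng = np.random.default_rng(seed)
    cum = matrix.cumsum(axis=1)

    states = np.full(n_patients, STATE_INDEX[initial_state], dtype=np.int64)
    counts = {s: np.zeros(n_patients, dtype=np.int64) for s in EVENT_STATES}
    months = np.zeros(N_STATES)
    for _ in range(horizon_cycles):
        np.add.at(months, states, 1)
        u = rng.random(n_patients)
        nxt = (u[:, None] > cum[states]).sum(axis=1)
        moved = nxt != states
        for s in EVENT_STATES:
            counts[s] += moved & (nxt == STATE_INDEX[s])
        states = nxt

    return EventSummary(
        n_patients=n_patients,
        horizon_cycles=horizon_cycles,
        totals={s: int(c.sum()) for s, c in counts.items()},
        per_patient=counts,
        mean_months_in_state={s: months[STATE_INDEX[s]] / n_patients for s in STATES},
        seed=seed,
    )


def compare_event_totals(
    arm_a: EventSummary, arm_b: EventSummary
) -> dict[HealthState, tuple[int, float]]:
    """Signed per-event difference ``a - b`` with its Monte-Carlo
    standard error; arms must be the same size and horizon."""
    if arm_a.n_patients != arm_b.n_patients:
        raise ValueError(
            f"mismatched n_patients: {arm_a.n_patients} != {arm_b.n_patients}"
        )
    if arm_a.horizon_cycles != arm_b.horizon_cycles:
        raise ValueError("mismatched horizons")
    out: dict[HealthState, tuple[int, float]] = {}
    for s in EVENT_STATES:
        diff = arm_a.totals[s] - arm_b.totals[s]
        se = float(np.hypot(arm_a.standard_error(s), arm_b.standard_error(s)))
        out[s] = (diff, se)
    return out
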