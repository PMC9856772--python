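"""Transition-matrix construction for the six-state monthly Markov model.

A :class:`ParameterSet` holds one complete numeric instantiation of the
model: per-cycle transition probabilities, yearly health utilities,
monthly state costs, one-time event costs, the monthly drug cost and the
healing odds ratio of the intervention.  :func:`build_transition_matrix`
turns it into a row-stochastic 6x6 monthly matrix for one strategy arm.

Ambiguous source rows carry an ``interpretation`` tag saying how the
printed number enters the matrix:

``direct``
    the printed value is the monthly transition probability;
``conditional``
    the printed value is conditional on a parent transition and is
    multiplied by the parent's (direct or complemented) probability;
``self``
    the printed value is an explicit self-transition probability, in
    which case the row residual is routed to the row's ``residual_to``
    state instead of back to the source state;
``excluded``
    the printed value is judged not to be a monthly exit probability and
    is dropped from the matrix (kept in the file for provenance).

The treatment effect is a healing odds ratio.  Two application modes are
supported: ``odds`` (convert to odds, multiply, convert back - the
textbook mapping, implemented by :func:`or_adjust_probability`) and
``risk_ratio`` (direct multiplication, clipped to [0, 1]).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from .states import ABSORBING, N_STATES, STATE_INDEX, STATES, HealthState

ROW_SUM_TOL = 1e-12

INTERPRETATION_TAGS = ("direct", "conditional", "self", "excluded")
EFFECT_MODES = ("odds", "risk_ratio")


class ModelValidationError(ValueError):
    """A parameter set or matrix violates a structural constraint."""


def or_adjust_probability(p: float, or_value: float) -> float:
    """Apply an odds ratio to a probability on the odds scale.

    Converts ``p`` to odds, multiplies by ``or_value`` and converts
    back: ``p' = OR*p/(1-p) / (1 + OR*p/(1-p))``.  Monotone increasing
    in both arguments; the identity for ``or_value == 1``.

    Raises
    ------
    ValueError
        if ``p`` is outside ``[0, 1)`` (odds undefined at 1) or
        ``or_value`` is not positive.
    """
    if not 0.0 <= p < 1.0:
        raise ValueError(f"probability must be in [0, 1), got {p}")
    if or_value <= 0.0:
        raise ValueError(f"odds ratio must be positive, got {or_value}")
    odds = or_value * p / (1.0 - p)
    return odds / (1.0 + odds)


def risk_multiply_probability(p: float, or_value: float) -> float:
    """Apply an effect size as a direct risk multiplier, clipped to [0, 1]."""
    if not 0.0 <= p <= 1.0:
        raise ValueError(f"probability must be in [0, 1], got {p}")
    if or_value <= 0.0:
        raise ValueError(f"effect size must be positive, got {or_value}")
    return min(p * or_value, 1.0)


def apply_effect(p: float, or_value: float, mode: str) -> float:
    """Apply the healing effect size to ``p`` under the given mode."""
    if mode == "odds":
        return or_adjust_probability(p, or_value)
    if mode == "risk_ratio":
        return risk_multiply_probability(p, or_value)
    raise ValueError(f"unknown effect mode {mode!r}; expected one of {EFFECT_MODES}")


@dataclass(frozen=True)
class TransitionSpec:
    """One printed transition of the model.

    ``value`` is the number as printed in the source table; ``low`` and
    ``high`` bound its sensitivity range; ``distribution`` names the
    sampling family for probabilistic analysis.  ``interpretation``
    says how the value enters the matrix (see module docstring); for
    ``conditional`` rows, ``parent`` names the parent transition label
    and ``parent_complement`` selects 1-parent instead of the parent
    probability itself.
    """

    from_state: HealthState
    to_state: HealthState
    value: float
    low: float | None = None
    high: float | None = None
    distribution: str = "beta"
    interpretation: str = "direct"
    parent: str | None = None
    parent_complement: bool = False
    label: str | None = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.value <= 1.0:
            raise ModelValidationError(
                f"transition {self.name}: probability {self.value} outside [0, 1]"
            )
        if self.from_state in ABSORBING:
            raise ModelValidationError(
                f"transition {self.name}: no transitions out of {self.from_state}"
            )
        if self.interpretation not in INTERPRETATION_TAGS:
            raise ModelValidationError(
                f"transition {self.name}: unknown interpretation "
                f"{self.interpretation!r}; expected one of {INTERPRETATION_TAGS}"
            )
        if self.interpretation == "conditional" and self.parent is None:
            raise ModelValidationError(
                f"transition {self.name}: conditional interpretation requires a parent"
            )
        if self.interpretation == "self" and self.from_state != self.to_state:
            raise ModelValidationError(
                f"transition {self.name}: 'self' interpretation on a non-self row"
            )

    @property
    def name(self) -> str:
        return self.label or f"{self.from_state} to {self.to_state}"


@dataclass(frozen=True)
class ParameterSet:
    """One complete numeric instantiation of the model.

    Utilities are per year in [0, 1]; state costs are per month; event
    costs are one-time charges on the named (from, to) transition flows;
    ``initial_event_cost`` is charged once at cycle 0.  All costs in the
    shipped model are 2021 USD.
    """

    transitions: tuple[TransitionSpec, ...]
    utilities: dict[HealthState, float]
    state_costs: dict[HealthState, float]
    event_costs: dict[tuple[HealthState, HealthState], float]
    drug_cost_monthly: float
    healing_or: float
    discount_rate_annual: float = 0.03
    horizon_cycles: int = 60
    wtp_thresholds: tuple[float, ...] = (32787.0, 98361.0)
    initial_event_cost: float = 0.0
    initial_state: HealthState = HealthState.UDFU
    effect_mode: str = "risk_ratio"
    effect_transition: tuple[HealthState, HealthState] = (
        HealthState.UDFU,
        HealthState.HEALED,
    )
    residual_to: dict[HealthState, HealthState] = field(default_factory=dict)
    half_cycle_correction: bool = False
    annual_step_discounting: bool = False
    name: str = "model"

    def __post_init__(self) -> None:
        for s, u in self.utilities.items():
            if not 0.0 <= u <= 1.0:
                raise ModelValidationError(f"utility of {s} outside [0, 1]: {u}")
        for s, c in self.state_costs.items():
            if c < 0:
                raise ModelValidationError(f"negative state cost for {s}: {c}")
        for (i, j), c in self.event_costs.items():
            if c < 0:
                raise ModelValidationError(f"negative event cost for {i}->{j}: {c}")
        if self.healing_or <= 0:
            raise ModelValidationError(f"healing OR must be positive: {self.healing_or}")
        if self.discount_rate_annual < 0:
            raise ModelValidationError("discount rate must be non-negative")
        if self.horizon_cycles < 1:
            raise ModelValidationError("horizon must be at least one cycle")
        if self.effect_mode not in EFFECT_MODES:
            raise ModelValidationError(f"unknown effect mode {self.effect_mode!r}")

    def with_overrides(self, **kwargs) -> "ParameterSet":
        """Return a copy with top-level fields replaced."""
        return replace(self, **kwargs)

    def transition(self, from_state: HealthState, to_state: HealthState) -> TransitionSpec:
        for t in self.transitions:
            if t.from_state == from_state and t.to_state == to_state:
                return t
        raise KeyError(f"no transition {from_state} -> {to_state}")

    def transition_by_label(self, label: str) -> TransitionSpec:
        for t in self.transitions:
            if t.name == label:
                return t
        raise KeyError(f"no transition labelled {label!r}")


@dataclass(frozen=True)
class StrategyConfig:
    """How one strategy arm modifies the shared model.

    The intervention arm applies the healing odds ratio to the
    uDFU->healed transition and accrues the monthly drug cost while the
    patient occupies one of ``drug_cost_states`` (optionally capped at
    ``drug_duration_cap_cycles`` cycles).
    """

    label: str
    apply_healing_or: bool = False
    drug_cost_states: frozenset[HealthState] = frozenset({HealthState.UDFU})
    drug_duration_cap_cycles: int | None = None


#: The two arms of the shipped comparison.
GWC = StrategyConfig(label="GWC", apply_healing_or=False)
ON101 = StrategyConfig(label="ON101+GWC", apply_healing_or=True)


def _effective_probability(
    spec: TransitionSpec, params: ParameterSet, values: dict[str, float]
) -> float:
    """Resolve a spec's printed value to its matrix entry probability."""
    v = values[spec.name]
    if spec.interpretation == "conditional":
        parent = params.transition_by_label(spec.parent)
        pv = values[parent.name]
        factor = 1.0 - pv if spec.parent_complement else pv
        return v * factor
    return v


def build_transition_matrix(
    params: ParameterSet,
    strategy: StrategyConfig,
    values: dict[str, float] | None = None,
) -> np.ndarray:
    """Build the monthly transition matrix for one strategy arm.

    ``values`` optionally overrides the printed value of any transition
    by its label (used by sensitivity analyses); conditional rows are
    expanded against the overridden parents.  The healing effect size is
    applied to the effect transition when ``strategy.apply_healing_or``.

    Returns a row-stochastic 6x6 array in the canonical state order;
    self-transitions are the residual 1 - sum(exits), except for rows
    with an explicit ``self`` entry whose residual goes to the row's
    ``residual_to`` state.

    Raises
    ------
    ModelValidationError
        if the listed exits of any row sum above 1 after interpretation
        expansion and effect adjustment.
    """
    if values is None:
        values = {t.name: t.value for t in params.transitions}
    else:
        base = {t.name: t.value for t in params.transitions}
        unknown = set(values) - set(base)
        if unknown:
            raise ModelValidationError(f"unknown transition labels: {sorted(unknown)}")
        base.update(values)
        values = base

    matrix = np.zeros((N_STATES, N_STATES))
    explicit_self: dict[int, float] = {}

    for spec in params.transitions:
        if spec.interpretation == "excluded":
            continue
        p = _effective_probability(spec, params, values)
        i, j = STATE_INDEX[spec.from_state], STATE_INDEX[spec.to_state]
        if (
            strategy.apply_healing_or
            and (spec.from_state, spec.to_state) == params.effect_transition
        ):
            p = apply_effect(p, params.healing_or, params.effect_mode)
        if spec.interpretation == "self":
            explicit_self[i] = p
        else:
            matrix[i, j] += p

    for i, state in enumerate(STATES):
        if state in ABSORBING:
            matrix[i, :] = 0.0
            matrix[i, i] = 1.0
            continue
        exits = matrix[i].sum() - matrix[i, i]
        self_p = explicit_self.get(i, 0.0)
        residual = 1.0 - exits - self_p
        if residual < -ROW_SUM_TOL:
            raise ModelValidationError(
                f"row {state}: listed exits sum to {exits + self_p:.6f} > 1"
            )
        residual = max(residual, 0.0)
        if i in explicit_self:
            matrix[i, i] += self_p
            dest = params.residual_to.get(state, state)
            matrix[i, STATE_INDEX[dest]] += residual
        else:
            matrix[i, i] += residual

    validate_transition_matrix(matrix)
    return matrix


def validate_transition_matrix(matrix: np.ndarray) -> None:
    """Check row-stochasticity, entry bounds and the absorbing death row."""
    if matrix.shape != (N_STATES, N_STATES):
        raise ModelValidationError(f"matrix must be {N_STATES}x{N_STATES}")
    if np.any(matrix < -ROW_SUM_TOL) or np.any(matrix > 1 + ROW_SUM_TOL):
        raise ModelValidationError("matrix entries outside [0, 1]")
    rowsums = matrix.sum(axis=1)
    if not np.allclose(rowsums, 1.0, atol=1e-10):
        bad = [str(STATES[i]) for i in np.where(~np.isclose(rowsums, 1.0, atol=1e-10))[0]]
        raise ModelValidationError(f"rows do not sum to 1: {bad}")
    d = STATE_INDEX[HealthState.DEATH]
    if not math.isclose(matrix[d, d], 1.0, abs_tol=ROW_SUM_TOL):
        raise ModelValidationError("death row is not absorbing")


def strategy_matrices(
    params: ParameterSet, values: dict[str, float] | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Build the (comparator, intervention) matrix pair."""
    return (
        build_transition_matrix(params, GWC, values),
        build_transition_matrix(params, ON101, values),
    )
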