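"""Shipped model fixture and random-model generation.

:func:`load_paper_parameters` returns the packaged Taiwan ON101 model
with per-parameter provenance.  Two interpretation variants are
available for the structurally ambiguous rows of the published input
table: the calibrated default, and the literal-as-printed reading (every
value used directly as a monthly probability, effect applied on the
odds scale).  :func:`generate_random_model` builds random valid
parameter sets for property testing.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .model import ParameterSet, TransitionSpec
from .modelfile import ModelDefinition, load_default_definition
from .states import STATES, HealthState


@dataclass(frozen=True)
class InterpretationOptions:
    """Resolution of the ambiguous input-table rows.

    healed_row
        ``recurrence_plus_conditional`` - healed->uDFU is the printed
        recurrence probability and healed->iDFU is the printed value
        times the recurrence probability (infected share of
        recurrences); ``conditional_split`` - the recurrence probability
        is split between uDFU and iDFU by the infected share;
        ``direct`` - both printed values are monthly probabilities.
    idfu_self
        what the explicit iDFU self-transition implies for the row
        residual: sent to ``healed`` or ``uDFU``, or ``redundant``
        (residual stays put, the printed self is absorbed into it).
    postamp_gangrene
        ``excluded``, ``direct``, or ``conditional_on_recurrence``
        (scaled by the postamputation ulcer-recurrence probability).
    udfu_infection
        ``conditional_not_healing`` (printed infection risk conditional
        on the ulcer persisting) or ``direct``.
    effect_mode
        ``risk_ratio`` or ``odds``.
    """

    healed_row: str = "recurrence_plus_conditional"
    idfu_self: str = "residual_healed"
    postamp_gangrene: str = "excluded"
    udfu_infection: str = "conditional_not_healing"
    effect_mode: str = "risk_ratio"


CALIBRATED = InterpretationOptions()
LITERAL = InterpretationOptions(
    healed_row="direct",
    idfu_self="redundant",
    postamp_gangrene="direct",
    udfu_infection="direct",
    effect_mode="odds",
)

_HEALED_ROW = {
    "direct": [("Healing to progression", "direct", None, False),
               ("Healing to iDFU", "direct", None, False)],
    "conditional_split": [
        ("Healing to progression", "conditional", "Healing to iDFU", True),
        ("Healing to iDFU", "conditional", "Healing to progression", False),
    ],
    "recurrence_plus_conditional": [
        ("Healing to progression", "direct", None, False),
        ("Healing to iDFU", "conditional", "Healing to progression", False),
    ],
}
_POSTAMP = {
    "direct": ("direct", None, False),
    "excluded": ("excluded", None, False),
    "conditional_on_recurrence": ("conditional", "Postamputation to iDFU", False),
}
_UDFU_INF = {
    "direct": ("direct", None, False),
    "conditional_not_healing": ("conditional", "uDFU to healing", True),
}


def apply_interpretation(
    defn: ModelDefinition, options: InterpretationOptions
) -> ModelDefinition:
    """Rewrite a definition's interpretation tags per ``options``."""
    rewrites: dict[str, tuple[str, str | None, bool]] = {}
    for label, tag, parent, compl in _HEALED_ROW[options.healed_row]:
        rewrites[label] = (tag, parent, compl)
    rewrites["Postamputation to gangrene"] = _POSTAMP[options.postamp_gangrene]
    rewrites["uDFU to iDFU"] = _UDFU_INF[options.udfu_infection]

    transitions = []
    for t in defn.transitions:
        if t.name in rewrites:
            tag, parent, compl = rewrites[t.name]
            t = replace(
                t, interpretation=tag, parent=parent, parent_complement=compl
            )
        elif t.name == "iDFU to iDFU":
            t = replace(t, interpretation="self", parent=None, parent_complement=False)
        transitions.append(t)

    residual_to = dict(defn.residual_to)
    residual_to.pop(HealthState.IDFU, None)
    if options.idfu_self == "residual_healed":
        residual_to[HealthState.IDFU] = HealthState.HEALED
    elif options.idfu_self == "residual_udfu":
        residual_to[HealthState.IDFU] = HealthState.UDFU
    elif options.idfu_self != "redundant":
        raise ValueError(f"unknown idfu_self option {options.idfu_self!r}")

    return replace(
        defn,
        transitions=tuple(transitions),
        residual_to=residual_to,
        effect_mode=options.effect_mode,
    )


@dataclass(frozen=True)
class PaperFixture:
    """The shipped model plus provenance of every parameter."""

    definition: ModelDefinition
    model: ParameterSet
    provenance: dict[str, str]
    variant: str


def load_paper_parameters(variant: str = "calibrated") -> PaperFixture:
    """Load the packaged model (checksum-verified).

    ``variant`` is ``"calibrated"`` (the shipped interpretation tags,
    which are the calibration winner) or ``"literal"`` (every printed
    value used directly, effect on the odds scale).
    """
    defn = load_default_definition()
    if variant == "literal":
        defn = apply_interpretation(defn, LITERAL)
    elif variant != "calibrated":
        raise ValueError(f"unknown variant {variant!r}")
    records = defn.value_records()
    provenance = {name: name for name in records}  # names are the table row labels
    return PaperFixture(
        definition=defn,
        model=defn.parameter_set(),
        provenance=provenance,
        variant=variant,
    )


def generate_random_model(
    seed: int,
    max_exits: float = 0.9,
) -> ParameterSet:
    """Random valid six-state parameter set for property tests.

    Exit probabilities of each live state are drawn so they sum below
    ``max_exits`` (the self-transition takes the residual); utilities
    are uniform on [0, 1]; costs positive; the healing effect size is
    log-uniform on [0.5, 4].  Deterministic per seed.
    """
    rng = np.random.default_rng(seed)
    live = [s for s in STATES if s != HealthState.DEATH]
    healing_or = float(np.exp(rng.uniform(np.log(0.5), np.log(4.0))))
    transitions = []
    for frm in live:
        targets = [s for s in STATES if s != frm]
        raw = rng.dirichlet(np.ones(len(targets))) * rng.uniform(0, max_exits)
        if frm == HealthState.UDFU:
            # keep the row feasible after the healing effect is applied
            # in the intervention arm (the adjusted exit sum must stay
            # below 1 even at this model's effect size)
            from .model import apply_effect

            i_healed = targets.index(HealthState.HEALED)
            while True:
                adjusted = apply_effect(float(raw[i_healed]), healing_or, "odds")
                if adjusted + (raw.sum() - raw[i_healed]) <= max_exits:
                    break
                raw *= 0.8
        for to, p in zip(targets, raw):
            transitions.append(
                TransitionSpec(from_state=frm, to_state=to, value=float(p))
            )
    utilities = {s: float(rng.uniform(0, 1)) for s in live}
    utilities[HealthState.DEATH] = 0.0
    state_costs = {s: float(rng.uniform(0, 1000)) for s in live}
    state_costs[HealthState.DEATH] = 0.0
    event_costs = {
        (HealthState.UDFU, HealthState.IDFU): float(rng.uniform(0, 10_000)),
        (HealthState.IDFU, HealthState.POSTAMPUTATION): float(rng.uniform(0, 10_000)),
    }
    return ParameterSet(
        transitions=tuple(transitions),
        utilities=utilities,
        state_costs=state_costs,
        event_costs=event_costs,
        drug_cost_monthly=float(rng.uniform(0, 1000)),
        healing_or=healing_or,
        discount_rate_annual=float(rng.uniform(0, 0.05)),
        horizon_cycles=int(rng.integers(1, 61)),
        effect_mode="odds",
        name=f"random-{seed}",
    )
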