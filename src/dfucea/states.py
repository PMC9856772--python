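"""Health states of the diabetic foot ulcer disease-progression model.

The model tracks a cohort of patients with an uninfected diabetic foot
ulcer (uDFU) through six mutually exclusive states: the ulcer can heal,
become infected (iDFU), progress to gangrene, lead to amputation
(postamputation), or the patient can die.  Death is absorbing.
"""

from __future__ import annotations

from enum import Enum


class HealthState(str, Enum):
    """One of the six mutually exclusive health states."""

    HEALED = "healed"
    UDFU = "uDFU"
    IDFU = "iDFU"
    GANGRENE = "gangrene"
    POSTAMPUTATION = "postamputation"
    DEATH = "death"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


#: Canonical state ordering used for all vectors and matrices.
STATES: tuple[HealthState, ...] = (
    HealthState.HEALED,
    HealthState.UDFU,
    HealthState.IDFU,
    HealthState.GANGRENE,
    HealthState.POSTAMPUTATION,
    HealthState.DEATH,
)

N_STATES = len(STATES)

#: Index of each state in the canonical ordering.
STATE_INDEX: dict[HealthState, int] = {s: i for i, s in enumerate(STATES)}

ABSORBING: frozenset[HealthState] = frozenset({HealthState.DEATH})


def state_from_label(label: str) -> HealthState:
    """Parse a state label, case-insensitively, into a :class:`HealthState`."""
    for s in STATES:
        if s.value.lower() == str(label).lower():
            return s
    raise ValueError(
        f"unknown health state {label!r}; expected one of "
        + ", ".join(s.value for s in STATES)
    )
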