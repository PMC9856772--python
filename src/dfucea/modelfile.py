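"""Reading and validating model-definition files.

A model file is a YAML document listing the states, every transition
(with its printed value, sensitivity range, sampling distribution and
interpretation tag), the health utilities, the monthly state costs, the
one-time event costs with their triggering transitions, the drug-cost
accrual rule and the treatment effect size.  The shipped default file
(``data/on101_taiwan.yaml``) encodes the published Taiwan ON101 model
inputs verbatim and is guarded by a checksum.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, replace
from importlib import resources
from pathlib import Path
from typing import Any

import yaml

from .model import (
    EFFECT_MODES,
    INTERPRETATION_TAGS,
    ModelValidationError,
    ParameterSet,
    StrategyConfig,
    TransitionSpec,
)
from .states import STATES, HealthState, state_from_label

DEFAULT_MODEL_RESOURCE = "on101_taiwan.yaml"

_DIST_FAMILIES = ("beta", "uniform", "triangular", "lognormal")


class ModelFileError(ModelValidationError):
    """The model file violates the schema; the message names the entry."""


def _req(mapping: dict, key: str, where: str) -> Any:
    if key not in mapping:
        raise ModelFileError(f"{where}: missing required key {key!r}")
    return mapping[key]


def _num(value: Any, where: str) -> float:
    if not isinstance(value, (int, float)) or isinstance(value, bool):
        raise ModelFileError(f"{where}: expected a number, got {value!r}")
    return float(value)


def _check_range(base: float, low: float | None, high: float | None, where: str) -> None:
    if low is not None and high is not None and not (low <= base <= high):
        raise ModelFileError(f"{where}: range [{low}, {high}] does not bracket {base}")


def _check_family(fam: str, where: str) -> str:
    if fam not in _DIST_FAMILIES:
        raise ModelFileError(
            f"{where}: unknown distribution {fam!r}; expected one of {_DIST_FAMILIES}"
        )
    return fam


@dataclass(frozen=True)
class ValueRecord:
    """A numeric input with its sensitivity range and sampling family."""

    value: float
    low: float | None
    high: float | None
    distribution: str


@dataclass(frozen=True)
class EventCostRecord:
    """A one-time cost charged on each of its triggering transitions."""

    label: str
    record: ValueRecord
    transitions: tuple[tuple[HealthState, HealthState], ...]


@dataclass(frozen=True)
class ModelDefinition:
    """Parsed model file: parameters plus distributions and provenance."""

    name: str
    transitions: tuple[TransitionSpec, ...]
    residual_to: dict[HealthState, HealthState]
    utilities: dict[HealthState, ValueRecord]
    state_costs: dict[HealthState, ValueRecord]
    event_costs: tuple[EventCostRecord, ...]
    initial_event: ValueRecord
    drug: ValueRecord
    drug_states: frozenset[HealthState]
    drug_cap_cycles: int | None
    effect: ValueRecord
    effect_mode: str
    effect_transition: tuple[HealthState, HealthState]
    discount_rate_annual: float
    horizon_cycles: int
    wtp_thresholds: tuple[float, ...]
    initial_state: HealthState
    source_path: str | None = None

    # -- parameter naming ------------------------------------------------
    # Sampled/varied parameters are addressed by these names everywhere
    # (PSA, DSA, scenario overrides).

    def value_records(self) -> dict[str, ValueRecord]:
        """All named numeric inputs with their ranges and families."""
        records: dict[str, ValueRecord] = {}
        for t in self.transitions:
            records[t.name] = ValueRecord(t.value, t.low, t.high, t.distribution)
        for s, r in self.utilities.items():
            records[f"utility: {s}"] = r
        for s, r in self.state_costs.items():
            records[f"state cost: {s}"] = r
        for e in self.event_costs:
            records[f"event cost: {e.label}"] = e.record
        records["initial event cost"] = self.initial_event
        records["monthly drug cost"] = self.drug
        records["healing odds ratio"] = self.effect
        return records

    def parameter_names(self) -> tuple[str, ...]:
        return tuple(self.value_records())

    # -- construction ----------------------------------------------------

    def parameter_set(self, samples: dict[str, float] | None = None) -> ParameterSet:
        """Materialise a :class:`ParameterSet`, optionally with sampled
        or overridden values keyed by parameter name."""
        samples = dict(samples or {})
        known = set(self.value_records())
        unknown = set(samples) - known
        if unknown:
            raise ModelValidationError(
                f"unknown parameter names: {sorted(unknown)}; "
                f"valid names are {sorted(known)}"
            )

        def get(name: str, default: float) -> float:
            return samples.get(name, default)

        transitions = tuple(
            replace(t, value=get(t.name, t.value)) for t in self.transitions
        )
        utilities = {
            s: get(f"utility: {s}", r.value) for s, r in self.utilities.items()
        }
        utilities[HealthState.DEATH] = 0.0
        state_costs = {
            s: get(f"state cost: {s}", r.value) for s, r in self.state_costs.items()
        }
        state_costs[HealthState.DEATH] = 0.0
        event_costs: dict[tuple[HealthState, HealthState], float] = {}
        for e in self.event_costs:
            c = get(f"event cost: {e.label}", e.record.value)
            for pair in e.transitions:
                event_costs[pair] = event_costs.get(pair, 0.0) + c
        return ParameterSet(
            transitions=transitions,
            utilities=utilities,
            state_costs=state_costs,
            event_costs=event_costs,
            drug_cost_monthly=get("monthly drug cost", self.drug.value),
            healing_or=get("healing odds ratio", self.effect.value),
            discount_rate_annual=self.discount_rate_annual,
            horizon_cycles=self.horizon_cycles,
            wtp_thresholds=self.wtp_thresholds,
            initial_event_cost=get("initial event cost", self.initial_event.value),
            initial_state=self.initial_state,
            effect_mode=self.effect_mode,
            effect_transition=self.effect_transition,
            residual_to=dict(self.residual_to),
            name=self.name,
        )

    def strategies(self) -> tuple[StrategyConfig, StrategyConfig]:
        """The (comparator, intervention) strategy pair of the file."""
        comparator = StrategyConfig(label="GWC", apply_healing_or=False)
        intervention = StrategyConfig(
            label="ON101+GWC",
            apply_healing_or=True,
            drug_cost_states=self.drug_states,
            drug_duration_cap_cycles=self.drug_cap_cycles,
        )
        return comparator, intervention

    def config_digest(self) -> str:
        """Stable hash of the full numeric configuration."""
        payload = {
            "name": self.name,
            "records": {
                k: (r.value, r.low, r.high, r.distribution)
                for k, r in sorted(self.value_records().items())
            },
            "interpretations": [
                (t.name, t.interpretation, t.parent, t.parent_complement)
                for t in self.transitions
            ],
            "residual_to": {str(k): str(v) for k, v in sorted(self.residual_to.items())},
            "effect_mode": self.effect_mode,
            "horizon": self.horizon_cycles,
            "discount": self.discount_rate_annual,
            "drug_states": sorted(str(s) for s in self.drug_states),
            "drug_cap": self.drug_cap_cycles,
        }
        blob = json.dumps(payload, sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()


def _parse_value_record(
    entry: dict, where: str, value_key: str = "value"
) -> ValueRecord:
    base = _num(_req(entry, value_key, where), where)
    low = entry.get("low")
    high = entry.get("high")
    low = None if low is None else _num(low, f"{where}.low")
    high = None if high is None else _num(high, f"{where}.high")
    _check_range(base, low, high, where)
    fam = _check_family(entry.get("distribution", "beta"), where)
    return ValueRecord(base, low, high, fam)


def parse_model_definition(doc: dict, source: str | None = None) -> ModelDefinition:
    """Validate a parsed YAML document and build a :class:`ModelDefinition`."""
    if not isinstance(doc, dict):
        raise ModelFileError("model file: top level must be a mapping")
    name = str(doc.get("name", "model"))

    states = doc.get("states")
    if states is not None:
        declared = [state_from_label(s) for s in states]
        if set(declared) != set(STATES) or len(declared) != len(STATES):
            raise ModelFileError(
                "states: must list exactly the six model states "
                + ", ".join(s.value for s in STATES)
            )

    settings = doc.get("settings", {})
    horizon = int(settings.get("horizon_cycles", 60))
    discount = _num(settings.get("discount_rate_annual", 0.03), "settings.discount_rate_annual")
    wtp = tuple(
        _num(x, "settings.wtp_thresholds") for x in settings.get("wtp_thresholds", [])
    )
    initial_state = state_from_label(settings.get("initial_state", "uDFU"))
    effect_mode = settings.get("effect_mode", "odds")
    if effect_mode not in EFFECT_MODES:
        raise ModelFileError(
            f"settings.effect_mode: {effect_mode!r} not one of {EFFECT_MODES}"
        )

    raw_transitions = _req(doc, "transitions", "model file")
    transitions: list[TransitionSpec] = []
    for k, entry in enumerate(raw_transitions):
        where = f"transitions[{k}]"
        frm = state_from_label(_req(entry, "from", where))
        to = state_from_label(_req(entry, "to", where))
        rec = _parse_value_record(entry, where)
        tag = entry.get("interpretation", "direct")
        if tag not in INTERPRETATION_TAGS:
            raise ModelFileError(
                f"{where}: interpretation {tag!r} not one of {INTERPRETATION_TAGS}"
            )
        try:
            transitions.append(
                TransitionSpec(
                    from_state=frm,
                    to_state=to,
                    value=rec.value,
                    low=rec.low,
                    high=rec.high,
                    distribution=rec.distribution,
                    interpretation=tag,
                    parent=entry.get("parent"),
                    parent_complement=bool(entry.get("parent_complement", False)),
                    label=entry.get("label"),
                )
            )
        except ModelValidationError as exc:
            raise ModelFileError(f"{where}: {exc}") from exc
    labels = [t.name for t in transitions]
    if len(set(labels)) != len(labels):
        raise ModelFileError("transitions: duplicate labels")
    for t in transitions:
        if t.parent is not None and t.parent not in labels:
            raise ModelFileError(
                f"transition {t.name!r}: parent {t.parent!r} not a transition label"
            )

    residual_to = {
        state_from_label(k): state_from_label(v)
        for k, v in (doc.get("residual_to") or {}).items()
    }

    def parse_state_map(key: str) -> dict[HealthState, ValueRecord]:
        out: dict[HealthState, ValueRecord] = {}
        for k, entry in enumerate(_req(doc, key, "model file")):
            where = f"{key}[{k}]"
            s = state_from_label(_req(entry, "state", where))
            out[s] = _parse_value_record(entry, where)
        missing = {s for s in STATES if s != HealthState.DEATH} - set(out)
        if missing:
            raise ModelFileError(f"{key}: missing states {sorted(str(s) for s in missing)}")
        return out

    utilities = parse_state_map("utilities")
    for s, r in utilities.items():
        if not 0.0 <= r.value <= 1.0:
            raise ModelFileError(f"utilities: {s} value {r.value} outside [0, 1]")
    state_costs = parse_state_map("state_costs")

    event_costs: list[EventCostRecord] = []
    for k, entry in enumerate(doc.get("event_costs", [])):
        where = f"event_costs[{k}]"
        label = str(_req(entry, "label", where))
        rec = _parse_value_record(entry, where, value_key="cost")
        pairs = tuple(
            (state_from_label(a), state_from_label(b))
            for a, b in _req(entry, "transitions", where)
        )
        event_costs.append(EventCostRecord(label, rec, pairs))

    initial_event = _parse_value_record(
        _req(doc, "initial_event", "model file"), "initial_event", value_key="cost"
    )

    drug_doc = _req(doc, "drug", "model file")
    drug = _parse_value_record(drug_doc, "drug", value_key="monthly_cost")
    drug_states = frozenset(
        state_from_label(s) for s in drug_doc.get("states", ["uDFU"])
    )
    cap = drug_doc.get("duration_cap_cycles")
    cap = None if cap is None else int(cap)

    effect_doc = _req(doc, "effect", "model file")
    effect = _parse_value_record(effect_doc, "effect", value_key="odds_ratio")
    if effect.value <= 0:
        raise ModelFileError("effect.odds_ratio must be positive")
    et = effect_doc.get("transition", ["uDFU", "healed"])
    effect_transition = (state_from_label(et[0]), state_from_label(et[1]))

    return ModelDefinition(
        name=name,
        transitions=tuple(transitions),
        residual_to=residual_to,
        utilities=utilities,
        state_costs=state_costs,
        event_costs=tuple(event_costs),
        initial_event=initial_event,
        drug=drug,
        drug_states=drug_states,
        drug_cap_cycles=cap,
        effect=effect,
        effect_mode=effect_mode,
        effect_transition=effect_transition,
        discount_rate_annual=discount,
        horizon_cycles=horizon,
        wtp_thresholds=wtp,
        initial_state=initial_state,
        source_path=source,
    )


def load_model_file(path: str | Path) -> ModelDefinition:
    """Load and validate a user model file."""
    path = Path(path)
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    return parse_model_definition(doc, source=str(path))


def _default_resource_bytes() -> bytes:
    return resources.files("dfucea").joinpath("data", DEFAULT_MODEL_RESOURCE).read_bytes()


def load_default_definition(verify_checksum: bool = True) -> ModelDefinition:
    """Load the shipped Taiwan ON101 model, verifying its checksum.

    The checksum guards against silent edits of the packaged parameter
    file; a mismatch raises :class:`ModelFileError`.
    """
    raw = _default_resource_bytes()
    if verify_checksum:
        expected = (
            resources.files("dfucea")
            .joinpath("data", DEFAULT_MODEL_RESOURCE + ".sha256")
            .read_text()
            .strip()
        )
        digest = hashlib.sha256(raw).hexdigest()
        if digest != expected:
            raise ModelFileError(
                f"packaged model file checksum mismatch: {digest} != {expected}"
            )
    doc = yaml.safe_load(raw)
    return parse_model_definition(doc, source=f"package:{DEFAULT_MODEL_RESOURCE}")
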