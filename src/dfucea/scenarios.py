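"""Scenario runner and cross-setting cost adaptation.

A scenario is a named set of overrides on the base model: a shorter
horizon, a subgroup-specific healing effect size, or any named
parameter value.  The base model is never mutated.  Subgroup analyses
use the same mechanism: all inputs identical to the base case except
the healing odds ratio, which the caller supplies.

:func:`adapt_costs` implements the generic two-stage transformation
used to carry cost estimates from one health-care setting to another:
currency conversion, inflation to the target price year via a consumer
price index ratio, and rescaling by an anchor ratio computed on health
states costed in both settings.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .cohort import CEResult, compare_strategies
from .model import ModelValidationError
from .modelfile import ModelDefinition

#: Parameter-set level overrides accepted beside the named parameters.
SETTING_OVERRIDES = ("horizon_cycles", "discount_rate_annual")


@dataclass(frozen=True)
class Scenario:
    """Named partial override of the base model."""

    name: str
    overrides: dict[str, float] = field(default_factory=dict)
    description: str = ""


def run_scenario(defn: ModelDefinition, scenario: Scenario) -> CEResult:
    """Run the full two-arm comparison under a scenario's overrides.

    Overrides are keyed by parameter name (as listed by
    ``defn.parameter_names()``) or by one of the settings in
    :data:`SETTING_OVERRIDES`.  Unknown names raise a validation error
    listing the valid ones.
    """
    overrides = dict(scenario.overrides)
    horizon = overrides.pop("horizon_cycles", None)
    discount = overrides.pop("discount_rate_annual", None)
    valid = set(defn.parameter_names())
    unknown = set(overrides) - valid
    if unknown:
        raise ModelValidationError(
            f"scenario {scenario.name!r}: unknown overrides {sorted(unknown)}; "
            f"valid names: {sorted(valid | set(SETTING_OVERRIDES))}"
        )
    params = defn.parameter_set(overrides)
    if discount is not None:
        params = params.with_overrides(discount_rate_annual=float(discount))
    return compare_strategies(
        params,
        defn.strategies(),
        horizon_cycles=None if horizon is None else int(horizon),
    )


def one_year_scenario() -> Scenario:
    """The short-term scenario: same monthly parameters, 12-cycle horizon."""
    return Scenario(
        name="1-year horizon",
        overrides={"horizon_cycles": 12},
        description="Horizon restricted to 1 year; all other inputs unchanged.",
    )


def subgroup_scenario(name: str, healing_or: float) -> Scenario:
    """A subgroup run: identical inputs except the healing effect size."""
    if healing_or <= 0:
        raise ModelValidationError("subgroup healing OR must be positive")
    return Scenario(
        name=name,
        overrides={"healing odds ratio": healing_or},
        description=f"Subgroup with healing OR {healing_or}.",
    )


@dataclass(frozen=True)
class CostAdaptation:
    """Two-stage transformation of costs across settings."""

    source_costs: dict[str, float]
    fx_rate: float  # target currency units per source unit
    cpi_source_to_target_year: float  # price-index ratio to the target year
    anchor_ratio: float  # target-setting / source-setting cost ratio

    def __post_init__(self) -> None:
        for label, factor in (
            ("fx_rate", self.fx_rate),
            ("cpi_source_to_target_year", self.cpi_source_to_target_year),
            ("anchor_ratio", self.anchor_ratio),
        ):
            if factor <= 0:
                raise ModelValidationError(f"{label} must be strictly positive")


def adapt_costs(adaptation: CostAdaptation) -> dict[str, float]:
    """Apply the two-stage transformation to every source cost."""
    factor = (
        adaptation.fx_rate
        * adaptation.cpi_source_to_target_year
        * adaptation.anchor_ratio
    )
    return {k: v * factor for k, v in adaptation.source_costs.items()}
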