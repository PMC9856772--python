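"""Probabilistic and deterministic sensitivity analyses.

Probabilistic sensitivity analysis (PSA) redraws every model input from
its distribution family simultaneously, reruns both strategy arms, and
summarises the joint decision uncertainty as a cost-effectiveness
acceptability curve (CEAC).  Deterministic analyses vary one parameter
at a time over its printed range (tornado), scan the drug-cost /
effect-size plane for cost-effectiveness thresholds (two-way), and
search for the break-even drug-cost multiplier.

Distribution parameterisation from (base, low, high):

* ``beta`` - method of moments with mean = base and sd = (high-low)/3.92,
  i.e. the range is read as an approximate 95% interval;
* ``uniform`` - hard bounds [low, high];
* ``triangular`` - (low, mode = base, high);
* ``lognormal`` - median = base, sd of log = (ln high - ln low)/3.92.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .cohort import CEResult, compare_strategies
from .model import ModelValidationError
from .modelfile import ModelDefinition

#: Default willingness-to-pay grid for the CEAC, 2021 USD per QALY.
DEFAULT_WTP_GRID: tuple[float, ...] = tuple(
    sorted(set(range(0, 150_001, 1000)) | {32_787, 98_361})
)

#: Tornado entries are flagged when either extreme moves the base-case
#: ICER by more than this fraction.
TORNADO_FLAG_THRESHOLD = 0.40


@dataclass(frozen=True)
class ParameterDistribution:
    """Sampling distribution of one model input."""

    name: str
    family: str
    base: float
    low: float
    high: float

    def __post_init__(self) -> None:
        if not self.low <= self.base <= self.high:
            raise ModelValidationError(
                f"{self.name}: range [{self.low}, {self.high}] "
                f"does not bracket {self.base}"
            )


def distributions_for(defn: ModelDefinition) -> dict[str, ParameterDistribution]:
    """Sampling distributions of every ranged parameter in a model file."""
    out: dict[str, ParameterDistribution] = {}
    for name, rec in defn.value_records().items():
        if rec.low is None or rec.high is None:
            continue
        out[name] = ParameterDistribution(
            name=name, family=rec.distribution, base=rec.value,
            low=rec.low, high=rec.high,
        )
    return out


def sample_parameter(
    dist: ParameterDistribution, rng: np.random.Generator, size: int | None = None
):
    """Draw from a parameter's distribution (see module docstring).

    A degenerate range (low == base == high) yields the constant base.
    Infeasible beta moments raise :class:`ModelValidationError` naming
    the parameter.
    """
    if dist.low == dist.high:
        return dist.base if size is None else np.full(size, dist.base)
    if dist.family == "uniform":
        return rng.uniform(dist.low, dist.high, size)
    if dist.family == "triangular":
        return rng.triangular(dist.low, dist.base, dist.high, size)
    if dist.family == "lognormal":
        if dist.base <= 0 or dist.low <= 0:
            raise ModelValidationError(f"{dist.name}: lognormal needs positive range")
        sdlog = (math.log(dist.high) - math.log(dist.low)) / 3.92
        return rng.lognormal(math.log(dist.base), sdlog, size)
    if dist.family == "beta":
        mean = dist.base
        sd = (dist.high - dist.low) / 3.92
        if not 0.0 < mean < 1.0:
            raise ModelValidationError(f"{dist.name}: beta mean {mean} outside (0, 1)")
        if sd * sd >= mean * (1.0 - mean):
            raise ModelValidationError(
                f"{dist.name}: beta moments infeasible (sd^2 >= mean*(1-mean))"
            )
        k = mean * (1.0 - mean) / (sd * sd) - 1.0
        draw = rng.beta(mean * k, (1.0 - mean) * k, size)
        return np.clip(draw, 0.0, 1.0)
    raise ModelValidationError(f"{dist.name}: unknown family {dist.family!r}")


@dataclass(frozen=True)
class PSAOutput:
    """Per-iteration costs and QALYs of both arms.

    ``iterations`` has one row per iteration with columns
    ``cost_comparator, qaly_comparator, cost_intervention,
    qaly_intervention, delta_cost, delta_qaly``.
    """

    iterations: pd.DataFrame
    n_iterations: int
    seed: int
    n_resampled: int

    def icers(self) -> np.ndarray:
        """Per-iteration signed ICERs (the ratio pathology included:
        signs are not comparable across quadrants, which is why summary
        decisions use NMB instead)."""
        return (self.iterations["delta_cost"] / self.iterations["delta_qaly"]).to_numpy()

    def median_icer(self) -> float:
        return float(np.median(self.icers()))

    def mean_icer(self) -> float:
        return float(np.mean(self.icers()))


def run_psa(
    defn: ModelDefinition,
    n_iterations: int,
    seed: int,
    horizon_cycles: int | None = None,
    max_resamples: int = 1000,
) -> PSAOutput:
    """Monte-Carlo PSA: joint independent redraw of all inputs.

    Iterations whose sampled parameter set fails structural validation
    (e.g. row exits summing above 1) are resampled in full; the count of
    resampled draws is reported on the output.  Deterministic per seed.
    """
    if n_iterations < 1:
        raise ValueError("n_iterations must be at least 1")
    dists = distributions_for(defn)
    rng = np.random.default_rng(seed)
    strategies = defn.strategies()
    rows = []
    n_resampled = 0
    for _ in range(n_iterations):
        for _attempt in range(max_resamples):
            samples = {name: float(sample_parameter(d, rng)) for name, d in dists.items()}
            try:
                params = defn.parameter_set(samples)
                res = compare_strategies(
                    params, strategies, horizon_cycles=horizon_cycles
                )
                break
            except ModelValidationError:
                n_resampled += 1
        else:
            raise ModelValidationError(
                f"PSA iteration failed validation {max_resamples} times"
            )
        rows.append(
            (
                res.comparator.total_cost,
                res.comparator.qalys,
                res.intervention.total_cost,
                res.intervention.qalys,
            )
        )
    df = pd.DataFrame(
        rows,
        columns=[
            "cost_comparator",
            "qaly_comparator",
            "cost_intervention",
            "qaly_intervention",
        ],
    )
    df["delta_cost"] = df["cost_intervention"] - df["cost_comparator"]
    df["delta_qaly"] = df["qaly_intervention"] - df["qaly_comparator"]
    return PSAOutput(
        iterations=df, n_iterations=n_iterations, seed=seed, n_resampled=n_resampled
    )


def compute_ceac(
    psa: PSAOutput, wtp_grid: tuple[float, ...] = DEFAULT_WTP_GRID
) -> pd.DataFrame:
    """Probability the intervention has the higher net monetary benefit
    at each willingness-to-pay; at wtp = 0 this is the probability of
    being cost-saving."""
    if len(wtp_grid) == 0:
        raise ValueError("WTP grid must be non-empty")
    if psa.n_iterations == 0:
        raise ValueError("empty PSA output")
    dc = psa.iterations["delta_cost"].to_numpy()
    dq = psa.iterations["delta_qaly"].to_numpy()
    rows = [
        (wtp, float(np.mean(wtp * dq - dc > 0.0))) for wtp in wtp_grid
    ]
    return pd.DataFrame(rows, columns=["wtp", "probability_cost_effective"])


@dataclass(frozen=True)
class TornadoEntry:
    """One-way sensitivity of the ICER to a single parameter."""

    parameter: str
    low: float
    high: float
    icer_at_low: float | None
    icer_at_high: float | None
    dominance_at_low: str
    dominance_at_high: str
    span_pct_of_base: float
    flagged: bool


def _icer_value(res: CEResult) -> float | None:
    return res.icer


def one_way_dsa(
    defn: ModelDefinition,
    ranges: dict[str, tuple[float, float]] | None = None,
) -> list[TornadoEntry]:
    """Tornado analysis: rerun the two-arm comparison at each parameter's
    low and high, all else at base, sorted by descending ICER span.

    ``ranges`` defaults to the ranges in the model file.  Entries whose
    span exceeds 40% of the base-case ICER are flagged.  The span of a
    dominant/dominated extreme is measured from the signed cost/QALY
    ratio at that extreme (the conventional tornado rendering).
    """
    records = defn.value_records()
    if ranges is None:
        ranges = {
            name: (rec.low, rec.high)
            for name, rec in records.items()
            if rec.low is not None and rec.high is not None
        }
    unknown = set(ranges) - set(records)
    if unknown:
        raise ModelValidationError(f"unknown parameters in ranges: {sorted(unknown)}")

    strategies = defn.strategies()
    base = compare_strategies(defn.parameter_set(), strategies)
    if base.icer is None:
        raise ModelValidationError("base-case ICER undefined; tornado needs a ratio")
    entries = []
    for name, (low, high) in ranges.items():
        icers = []
        doms = []
        for value in (low, high):
            res = compare_strategies(defn.parameter_set({name: value}), strategies)
            icers.append(_icer_value(res))
            doms.append(res.dominance.value)
        ratios = [
            ic if ic is not None else _signed_ratio(defn, name, v, strategies)
            for ic, v in zip(icers, (low, high))
        ]
        span = max(abs(r - base.icer) for r in ratios)
        span_pct = 100.0 * span / abs(base.icer)
        entries.append(
            TornadoEntry(
                parameter=name,
                low=low,
                high=high,
                icer_at_low=icers[0],
                icer_at_high=icers[1],
                dominance_at_low=doms[0],
                dominance_at_high=doms[1],
                span_pct_of_base=span_pct,
                flagged=span_pct > 100.0 * TORNADO_FLAG_THRESHOLD,
            )
        )
    entries.sort(key=lambda e: -e.span_pct_of_base)
    return entries


def _signed_ratio(defn, name, value, strategies) -> float:
    res = compare_strategies(defn.parameter_set({name: value}), strategies)
    if math.isclose(res.delta_qalys, 0.0, abs_tol=1e-12):
        return math.inf
    return res.delta_cost / res.delta_qalys


@dataclass(frozen=True)
class ThresholdResult:
    """Root of a cost-effectiveness criterion, or why none exists."""

    value: float | None
    status: str  # "root", "always", "never"


def two_way_threshold(
    defn: ModelDefinition,
    drug_cost_values: tuple[float, ...],
    or_range: tuple[float, float],
    wtp: float,
    tol: float = 0.005,
) -> dict[float, ThresholdResult]:
    """Minimum healing effect size making the intervention cost-effective
    at ``wtp``, for each candidate monthly drug cost.

    The root solves NMB(intervention) = NMB(comparator) by bisection on
    the odds ratio; a range whose NMB difference does not change sign is
    reported as ``always`` (cost-effective over the whole range) or
    ``never`` rather than raising.
    """
    lo, hi = or_range
    if not 0 < lo < hi:
        raise ValueError("or_range must be increasing and positive")
    strategies = defn.strategies()

    def nmb_diff(or_value: float, drug_cost: float) -> float:
        params = defn.parameter_set(
            {"healing odds ratio": or_value, "monthly drug cost": drug_cost}
        )
        return compare_strategies(params, strategies).nmb_difference(wtp)

    out: dict[float, ThresholdResult] = {}
    for cost in drug_cost_values:
        f_lo, f_hi = nmb_diff(lo, cost), nmb_diff(hi, cost)
        if f_lo > 0 and f_hi > 0:
            out[cost] = ThresholdResult(value=lo, status="always")
        elif f_lo < 0 and f_hi < 0:
            out[cost] = ThresholdResult(value=None, status="never")
        else:
            root = brentq(nmb_diff, lo, hi, args=(cost,), xtol=tol)
            out[cost] = ThresholdResult(value=float(root), status="root")
    return out


def break_even_multiplier(
    defn: ModelDefinition,
    criterion: str = "cost_saving",
    wtp: float | None = None,
    bracket: tuple[float, float] = (0.0, 10.0),
    tol: float = 0.001,
) -> ThresholdResult:
    """Drug-cost multiplier at which the intervention reaches a criterion.

    ``cost_saving`` solves incremental cost = 0; ``wtp_threshold``
    solves ICER = ``wtp``.  Incremental cost is strictly increasing in
    the multiplier (drug cost enters the intervention arm positively),
    so a bracketed root is unique.  An unbracketed criterion returns an
    explicit no-root result.
    """
    if criterion not in ("cost_saving", "wtp_threshold"):
        raise ValueError("criterion must be 'cost_saving' or 'wtp_threshold'")
    if criterion == "wtp_threshold" and wtp is None:
        raise ValueError("wtp_threshold criterion requires a wtp value")
    base_drug = defn.drug.value
    strategies = defn.strategies()

    def objective(multiplier: float) -> float:
        params = defn.parameter_set({"monthly drug cost": base_drug * multiplier})
        res = compare_strategies(params, strategies)
        if criterion == "cost_saving":
            return res.delta_cost
        return res.delta_cost - wtp * res.delta_qalys

    lo, hi = bracket
    f_lo, f_hi = objective(lo), objective(hi)
    if f_lo * f_hi > 0:
        status = "always" if f_lo < 0 and f_hi < 0 else "never"
        return ThresholdResult(value=None, status=status)
    root = brentq(objective, lo, hi, xtol=tol)
    return ThresholdResult(value=float(root), status="root")
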