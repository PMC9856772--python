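"""Report bundle generation: tables, figures and a reproducibility manifest.

Rendered tables follow the publication's precision: costs to whole
dollars, QALYs to four decimals, ICERs to whole dollars per QALY.  The
manifest records every seed, the model configuration digest and the
package version so a run can be reproduced exactly.
"""

from __future__ import annotations

import json
from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import pandas as pd

from . import __version__
from .cohort import CEResult, CohortTrace
from .microsim import EVENT_STATES, EventSummary
from .modelfile import ModelDefinition
from .states import STATES
from .uncertainty import PSAOutput, TornadoEntry, compute_ceac


def summary_table(result: CEResult) -> pd.DataFrame:
    """Base-case comparison, one row per strategy, publication rounding."""
    rows = []
    for arm, inc_cost, inc_qaly, icer in (
        (result.comparator, None, None, None),
        (result.intervention, result.delta_cost, result.delta_qalys, result.icer),
    ):
        rows.append(
            {
                "strategy": arm.strategy,
                "total_cost": round(arm.total_cost),
                "incremental_cost": None if inc_cost is None else round(inc_cost),
                "life_years": round(arm.life_years, 4),
                "qalys": round(arm.qalys, 4),
                "incremental_qalys": None if inc_qaly is None else round(inc_qaly, 4),
                "icer": None if icer is None else round(icer),
                "dominance": result.dominance.value if inc_cost is not None else None,
            }
        )
    return pd.DataFrame(rows)


def trace_table(trace: CohortTrace) -> pd.DataFrame:
    """Tidy per-cycle occupancy (cycle, state, occupancy)."""
    rows = [
        {"cycle": t, "state": str(s), "occupancy": float(trace.occupancy[t, i])}
        for t in range(trace.occupancy.shape[0])
        for i, s in enumerate(STATES)
    ]
    return pd.DataFrame(rows)


def event_table(
    intervention: EventSummary, comparator: EventSummary
) -> pd.DataFrame:
    from .microsim import compare_event_totals

    diffs = compare_event_totals(intervention, comparator)
    rows = []
    for s in EVENT_STATES:
        d, se = diffs[s]
        rows.append(
            {
                "event": f"entry into {s}",
                "intervention_total": intervention.totals[s],
                "comparator_total": comparator.totals[s],
                "difference": d,
                "mc_standard_error": round(se, 1),
            }
        )
    return pd.DataFrame(rows)


def tornado_table(entries: list[TornadoEntry]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "parameter": e.parameter,
                "low": e.low,
                "high": e.high,
                "icer_at_low": e.icer_at_low,
                "icer_at_high": e.icer_at_high,
                "dominance_at_low": e.dominance_at_low,
                "dominance_at_high": e.dominance_at_high,
                "span_pct_of_base": round(e.span_pct_of_base, 1),
                "flagged_over_40pct": e.flagged,
            }
            for e in entries
        ]
    )


def plot_ceac(ceac: pd.DataFrame, path: Path, wtp_marks: tuple[float, ...] = ()) -> None:
    fig, ax = plt.subplots(figsize=(6, 4))
    ax.plot(ceac["wtp"], ceac["probability_cost_effective"], lw=2)
    for w in wtp_marks:
        ax.axvline(w, ls="--", color="grey", lw=0.8)
    ax.set_xlabel("Willingness to pay (USD/QALY)")
    ax.set_ylabel("P(intervention cost-effective)")
    ax.set_ylim(0, 1)
    ax.set_title("Cost-effectiveness acceptability curve")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_ce_plane(psa: PSAOutput, path: Path, wtp: float | None = None) -> None:
    fig, ax = plt.subplots(figsize=(6, 5))
    ax.scatter(
        psa.iterations["delta_qaly"], psa.iterations["delta_cost"], s=3, alpha=0.25
    )
    ax.axhline(0, color="k", lw=0.8)
    ax.axvline(0, color="k", lw=0.8)
    if wtp is not None:
        xs = ax.get_xlim()
        ax.plot(xs, [wtp * x for x in xs], ls="--", color="grey", lw=0.8)
    ax.set_xlabel("Incremental QALYs")
    ax.set_ylabel("Incremental cost (USD)")
    ax.set_title("Incremental cost-effectiveness plane")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_tornado(entries: list[TornadoEntry], base_icer: float, path: Path) -> None:
    shown = [e for e in entries if e.flagged] or entries[:5]
    fig, ax = plt.subplots(figsize=(7, 0.5 * len(shown) + 1.5))
    labels = []
    for k, e in enumerate(reversed(shown)):
        lo = e.icer_at_low if e.icer_at_low is not None else base_icer
        hi = e.icer_at_high if e.icer_at_high is not None else base_icer
        left, right = min(lo, hi), max(lo, hi)
        ax.barh(k, right - left, left=left, height=0.6, color="#4878a8")
        labels.append(e.parameter)
    ax.axvline(base_icer, color="k", lw=1)
    ax.set_yticks(range(len(shown)), labels)
    ax.set_xlabel("ICER (USD/QALY)")
    ax.set_title("One-way sensitivity (tornado)")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def generate_report(
    out_dir: str | Path,
    defn: ModelDefinition,
    base_result: CEResult,
    psa: PSAOutput | None = None,
    tornado: list[TornadoEntry] | None = None,
    microsim: tuple[EventSummary, EventSummary] | None = None,
    seeds: dict[str, int] | None = None,
) -> dict[str, object]:
    """Write the report bundle and return the manifest.

    At least the base-case result is required.  The output directory
    must be creatable/writable; this is checked before any file is
    produced.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    probe = out / ".write_probe"
    try:
        probe.write_text("ok")
    finally:
        if probe.exists():
            probe.unlink()

    written: list[str] = []

    def save(df: pd.DataFrame, name: str) -> None:
        df.to_csv(out / name, index=False)
        written.append(name)

    save(summary_table(base_result), "summary.csv")
    if psa is not None:
        save(psa.iterations, "psa_iterations.csv")
        from .uncertainty import DEFAULT_WTP_GRID

        ceac = compute_ceac(psa, DEFAULT_WTP_GRID)
        save(ceac, "ceac.csv")
        plot_ceac(ceac, out / "ceac.png", defn.wtp_thresholds)
        written.append("ceac.png")
        plot_ce_plane(psa, out / "ce_plane.png", max(defn.wtp_thresholds, default=None))
        written.append("ce_plane.png")
    if tornado is not None:
        save(tornado_table(tornado), "tornado.csv")
        if base_result.icer is not None:
            plot_tornado(tornado, base_result.icer, out / "tornado.png")
            written.append("tornado.png")
    if microsim is not None:
        save(event_table(*microsim), "events.csv")

    manifest = {
        "package": "dfucea",
        "version": __version__,
        "model": defn.name,
        "config_digest": defn.config_digest(),
        "seeds": seeds or {},
        "psa_iterations": None if psa is None else psa.n_iterations,
        "psa_resampled": None if psa is None else psa.n_resampled,
        "microsim_n": None if microsim is None else microsim[0].n_patients,
        "files": written,
        "note": (
            "Mean signed ICERs across PSA iterations mix quadrants of the "
            "CE plane and can be misleading; decision summaries use NMB."
        ),
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest
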