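"""Per-signal verdicts and batch summaries.

A signal is *abnormal* if at least one abnormality is flagged, *normal* if
none are, and *unclassifiable* when it is degenerate (constant or a single
monotone section).  Batch percentages follow the convention of reporting
each subgroup's total against the grand total of anomalies across all
signals.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .anomaly_rules import (SUBGROUPS, Analysis, AnomalyFlag, ParameterSet,
                            RuleConstants, DEFAULT_CONSTANTS, Subgroup, run_all)
from .signal_io import Signal

__all__ = ["ClassificationResult", "BatchSummary", "classify", "summarize",
           "render_overview", "render_signal"]

_COLORS = {
    Subgroup.LOW_PEAK: "#1f77b4",
    Subgroup.MIDDLE_PEAK: "#9467bd",
    Subgroup.OSCILLATION: "#d62728",
    Subgroup.DOUBLE_PEAK: "#ff7f0e",
    Subgroup.IRREGULAR_PHASE: "#2ca02c",
    Subgroup.PLATEAU: "#8c564b",
}


@dataclass
class ClassificationResult:
    signal_id: str
    verdict: str  # "normal" | "abnormal" | "unclassifiable"
    counts: dict[Subgroup, int]
    flags: list[AnomalyFlag]
    n_transients: int
    analysis: Analysis | None = field(default=None, repr=False)

    @property
    def total_count(self) -> int:
        return sum(self.counts.values())


def classify(signal: Signal, params: ParameterSet,
             constants: RuleConstants = DEFAULT_CONSTANTS) -> ClassificationResult:
    """Run the detection pipeline and assign a verdict."""
    analysis = run_all(signal, params, constants)
    counts = analysis.counts()
    if analysis.unclassifiable:
        verdict = "unclassifiable"
    elif sum(counts.values()) >= 1:
        verdict = "abnormal"
    else:
        verdict = "normal"
    return ClassificationResult(
        signal_id=signal.id,
        verdict=verdict,
        counts=counts,
        flags=analysis.flags,
        n_transients=len(analysis.transients),
        analysis=analysis,
    )


@dataclass
class BatchSummary:
    n_signals: int
    n_abnormal: int
    pct_abnormal: float
    totals: dict[Subgroup, int]
    percentages: dict[Subgroup, float]  # subgroup total / grand total, percent
    total_anomalies: int
    rows: list[tuple[str, dict[Subgroup, int]]]  # abnormal signals only

    def sorted_rows(self, by: Subgroup | str | None = None):
        """Overview rows in non-increasing order of a subgroup count (or the
        total), ties broken by signal id."""
        if by is None:
            key = lambda row: (-sum(row[1].values()), row[0])
        else:
            sg = Subgroup(by)
            key = lambda row: (-row[1][sg], row[0])
        return sorted(self.rows, key=key)


def summarize(results: list[ClassificationResult]) -> BatchSummary:
    """Aggregate per-signal results into batch totals and overview rows."""
    if not results:
        raise ValueError("results must be non-empty")
    totals = {sg: 0 for sg in SUBGROUPS}
    rows = []
    n_abnormal = 0
    for r in results:
        for sg in SUBGROUPS:
            totals[sg] += r.counts[sg]
        if r.verdict == "abnormal":
            n_abnormal += 1
            rows.append((r.signal_id, dict(r.counts)))
    grand = sum(totals.values())
    percentages = {sg: (100.0 * totals[sg] / grand if grand else 0.0)
                   for sg in SUBGROUPS}
    return BatchSummary(
        n_signals=len(results),
        n_abnormal=n_abnormal,
        pct_abnormal=100.0 * n_abnormal / len(results),
        totals=totals,
        percentages=percentages,
        total_anomalies=grand,
        rows=rows,
    )


def render_overview(summary: BatchSummary, path) -> None:
    """Write a stacked-bar overview: one bar per abnormal signal, stacking
    shows how its anomalies distribute over the subgroups."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    rows = summary.sorted_rows()
    fig, ax = plt.subplots(figsize=(max(4.0, 0.4 * len(rows) + 2.0), 4.0))
    if not rows:
        ax.text(0.5, 0.5, "no abnormal signals", ha="center", va="center",
                transform=ax.transAxes)
    else:
        x = np.arange(len(rows))
        bottom = np.zeros(len(rows))
        for sg in SUBGROUPS:
            vals = np.array([counts[sg] for _, counts in rows], dtype=float)
            ax.bar(x, vals, bottom=bottom, color=_COLORS[sg], label=sg.value)
            bottom += vals
        ax.set_xticks(x)
        ax.set_xticklabels([sid for sid, _ in rows], rotation=90, fontsize=7)
        ax.legend(fontsize=7)
    ax.set_ylabel("anomalies per signal")
    ax.set_title(f"abnormal signals: {summary.n_abnormal}/{summary.n_signals}"
                 f" ({summary.pct_abnormal:.1f}%)")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def render_signal(signal: Signal, result: ClassificationResult, path) -> None:
    """Detail plot: trace, the three reference lines, alternating section
    markers, and colour-coded flag spans."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(10, 4))
    ax.plot(signal.t, signal.y, color="black", lw=0.8)
    an = result.analysis
    if an is not None and an.lines is not None:
        x = np.arange(len(signal))
        for line_fn, style in ((an.lines.top, "-"), (an.lines.bottom, "-"),
                               (an.lines.middle, "--")):
            ax.plot(signal.t, line_fn(x), color="gold", ls=style, lw=1.0)
        for k, sec in enumerate(an.sections):
            shade = 0.85 if k % 2 == 0 else 0.6
            ax.axvspan(signal.t[sec.start], signal.t[min(sec.stop, len(signal)) - 1],
                       ymin=0.97, ymax=1.0, color=str(shade))
    seen = set()
    for f in result.flags:
        label = f.subgroup.value if f.subgroup not in seen else None
        seen.add(f.subgroup)
        ax.axvspan(signal.t[f.start], signal.t[min(f.stop, len(signal)) - 1],
                   color=_COLORS[f.subgroup], alpha=0.25, label=label)
    if seen:
        ax.legend(fontsize=7)
    ax.set_xlabel("time (s)")
    ax.set_ylabel("F340/F380 ratio")
    ax.set_title(f"{signal.id}: {result.verdict}")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
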