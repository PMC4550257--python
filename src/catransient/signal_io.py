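"""Reading Ca2+ signal files and writing classification reports.

The interchange format is plain delimited text (comma, tab or whitespace,
auto-detected) with one or two numeric columns: either time + ratio value,
or value only, in which case the caller supplies the sampling frequency.
An optional single header line is skipped.  Signals are treated as
uniformly sampled; time columns with more than 10% relative jitter between
successive intervals are rejected rather than resampled.
"""

from __future__ import annotations

import io
import re
from dataclasses import dataclass
from pathlib import Path

import numpy as np

__all__ = [
    "Signal", "SignalError", "UnreadableFileError", "NonNumericDataError",
    "TooShortError", "NonIncreasingTimeError", "IrregularSamplingError",
    "NonFiniteError", "read_signal", "write_signal", "write_report",
]

MIN_SAMPLES = 8
MAX_JITTER = 0.10


class SignalError(ValueError):
    """Base class for signal input errors."""


class UnreadableFileError(SignalError):
    pass


class NonNumericDataError(SignalError):
    pass


class TooShortError(SignalError):
    pass


class NonIncreasingTimeError(SignalError):
    pass


class IrregularSamplingError(SignalError):
    pass


class NonFiniteError(SignalError):
    pass


@dataclass(frozen=True)
class Signal:
    """A uniformly sampled Fura-2 ratio trace from a single cell.

    ``t`` holds sample times in seconds (strictly increasing), ``y`` the
    dimensionless F340/F380 ratio values, and ``fs`` the sampling frequency
    in Hz derived from the time axis.
    """

    id: str
    t: np.ndarray
    y: np.ndarray
    fs: float

    @classmethod
    def from_arrays(cls, id: str, t, y) -> "Signal":
        t = np.asarray(t, dtype=float)
        y = np.asarray(y, dtype=float)
        if t.shape != y.shape or t.ndim != 1:
            raise SignalError("t and y must be 1-d arrays of equal length")
        if t.size < MIN_SAMPLES:
            raise TooShortError(f"signal has {t.size} samples; need >= {MIN_SAMPLES}")
        if not np.all(np.isfinite(y)) or not np.all(np.isfinite(t)):
            raise NonFiniteError("signal contains non-finite values")
        dt = np.diff(t)
        if np.any(dt <= 0):
            raise NonIncreasingTimeError("time column is not strictly increasing")
        mean_dt = float(dt.mean())
        if float(np.max(np.abs(dt - mean_dt))) > MAX_JITTER * mean_dt:
            raise IrregularSamplingError(
                "sampling jitter exceeds 10%; signals must be uniformly sampled")
        return cls(id=id, t=t, y=y, fs=1.0 / mean_dt)

    @classmethod
    def from_values(cls, id: str, y, fs: float) -> "Signal":
        y = np.asarray(y, dtype=float)
        if fs <= 0:
            raise SignalError(f"fs must be positive, got {fs}")
        t = np.arange(y.size, dtype=float) / fs
        return cls.from_arrays(id, t, y)

    def __len__(self) -> int:
        return self.y.size

    @property
    def duration(self) -> float:
        return float(self.t[-1] - self.t[0])


def _parse_table(text: str, path: Path) -> np.ndarray:
    rows: list[list[float]] = []
    header_allowed = True
    for raw in text.splitlines():
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        parts = [p for p in re.split(r"[,\t;]|\s+", line) if p]
        try:
            rows.append([float(p) for p in parts])
        except ValueError:
            if header_allowed:
                header_allowed = False  # skip one leading header line
                continue
            raise NonNumericDataError(f"{path}: non-numeric payload: {line!r}") from None
        header_allowed = False
    if not rows:
        raise NonNumericDataError(f"{path}: no numeric data found")
    width = len(rows[0])
    if width not in (1, 2) or any(len(r) != width for r in rows):
        raise NonNumericDataError(
            f"{path}: expected 1 or 2 numeric columns of equal width")
    return np.asarray(rows, dtype=float)


def read_signal(path, fs: float | None = None) -> Signal:
    """Read one signal from a delimited text file.

    With a two-column file the first column is time in seconds; with a
    value-only file ``fs`` must be supplied and the time axis is
    synthesized.  The signal id is the file stem.
    """
    path = Path(path)
    try:
        text = path.read_text()
    except OSError as exc:
        raise UnreadableFileError(f"cannot read {path}: {exc}") from exc
    data = _parse_table(text, path)
    if data.shape[1] == 2:
        return Signal.from_arrays(path.stem, data[:, 0], data[:, 1])
    if fs is None:
        raise SignalError(
            f"{path}: value-only file requires a sampling frequency (fs)")
    return Signal.from_values(path.stem, data[:, 0], fs)


def write_signal(signal: Signal, path) -> None:
    """Write a signal as two-column (time, value) text, round-trippable."""
    path = Path(path)
    with open(path, "w") as fh:
        fh.write("time_s\tratio\n")
        for ti, yi in zip(signal.t, signal.y):
            fh.write(f"{ti:.6f}\t{yi:.6f}\n")


# ---------------------------------------------------------------------------
# reports
# ---------------------------------------------------------------------------

def _format_report(results, fmt: str) -> str:
    from .anomaly_rules import SUBGROUPS
    from .classification import summarize

    if not results:
        raise ValueError("results must be non-empty")
    summary = summarize(results)
    cols = [sg.value for sg in SUBGROUPS]
    buf = io.StringIO()
    if fmt == "table":
        buf.write("id\tverdict\t" + "\t".join(cols) + "\ttotal\n")
        for r in results:
            counts = [str(r.counts[sg]) for sg in SUBGROUPS]
            buf.write(f"{r.signal_id}\t{r.verdict}\t" + "\t".join(counts)
                      + f"\t{r.total_count}\n")
    elif fmt == "detail":
        for r in results:
            buf.write(f"signal: {r.signal_id}\n")
            buf.write(f"  verdict: {r.verdict}\n")
            buf.write(f"  transients: {r.n_transients}\n")
            for sg in SUBGROUPS:
                buf.write(f"  {sg.value}: {r.counts[sg]}\n")
            for f in r.flags:
                buf.write(f"  flag: {f.subgroup.value} span=[{f.start},{f.stop})\n")
    else:
        raise ValueError(f"unknown report format {fmt!r}")
    buf.write("#\n# batch summary\n")
    buf.write(f"# signals: {summary.n_signals}\n")
    buf.write(f"# abnormal signals: {summary.n_abnormal} ({summary.pct_abnormal:.1f}%)\n")
    buf.write(f"# total anomalies: {summary.total_anomalies}\n")
    for sg in SUBGROUPS:
        buf.write(f"# {sg.value}: {summary.totals[sg]}"
                  f" ({summary.percentages[sg]:.1f}%)\n")
    return buf.getvalue()


def write_report(results, path, fmt: str = "table") -> None:
    """Write a classification report.

    ``fmt='table'``: one tab-delimited row per signal (id, verdict, six
    per-subgroup counts, total), followed by a ``#``-prefixed footer with
    batch totals, per-subgroup percentages of all anomalies, and the percent
    of signals classified abnormal.  ``fmt='detail'`` writes a structured
    key/value block per signal instead of the table.
    """
    text = _format_report(list(results), fmt)
    try:
        Path(path).write_text(text)
    except OSError as exc:
        raise SignalError(f"cannot write report to {path}: {exc}") from exc
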