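"""Noise-tolerant monotone segmentation of Ca2+ signals.

A *section* is a maximal stretch of the signal that ascends or descends
monotonously up to a noise tolerance: while tracking an ascending run, a
downward excursion only ends the run once the drop from the running maximum
exceeds the noise threshold (and symmetrically for descending runs).  The
threshold is expressed as a percentage of the global data range, which keeps
it stable under photobleaching-induced amplitude fade.  Section boundaries
are placed at the running extremum itself, so section heights equal true
local ranges.  Two adjacent sections — a rise followed by a decay — form one
Ca2+ *transient*.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import IntEnum

import numpy as np

__all__ = ["Direction", "Section", "Transient", "segment", "pair_transients"]


class Direction(IntEnum):
    ASCENDING = 1
    DESCENDING = -1


@dataclass(frozen=True)
class Section:
    """One noise-tolerant monotone run, spanning samples [start, stop).

    Spans tile the signal without overlap, but each run *begins* at the
    terminal extremum of the previous run: extrema and height are therefore
    taken over the closed window that includes the boundary extremum at the
    span's left edge, so an ascending section's minimum is the trough it
    rises from and a descending section's maximum is the peak it falls
    from, and the section height is the true local data range.
    """

    start: int
    stop: int
    direction: Direction
    i_min: int
    i_max: int
    v_min: float
    v_max: float
    degenerate: bool = False

    @property
    def span(self) -> tuple[int, int]:
        return (self.start, self.stop)

    @property
    def height(self) -> float:
        """Local data range in the section (ratio units)."""
        return self.v_max - self.v_min

    def __len__(self) -> int:
        return self.stop - self.start


@dataclass(frozen=True)
class Transient:
    """A Ca2+ rise and the decay immediately following it.

    ``i_base`` is the index of the transient minimum preceding the rise (the
    previous section's trough when one exists), and ``amplitude`` is the peak
    value minus that preceding minimum.
    """

    index: int
    sec_index: int  # index of the rise within the section list
    rise: Section
    decay: Section
    i_peak: int
    i_base: int
    v_peak: float
    v_base: float

    @property
    def amplitude(self) -> float:
        return self.v_peak - self.v_base

    @property
    def span(self) -> tuple[int, int]:
        return (self.rise.start, self.decay.stop)


def _close(y: np.ndarray, start: int, stop: int, direction: Direction,
           degenerate: bool = False) -> Section:
    lo = max(start - 1, 0)  # include the shared boundary extremum
    seg = y[lo:stop]
    i_min = lo + int(np.argmin(seg))
    i_max = lo + int(np.argmax(seg))
    return Section(start, stop, direction, i_min, i_max,
                   float(y[i_min]), float(y[i_max]), degenerate)


def segment(y: np.ndarray, noise_pct: float) -> list[Section]:
    """Partition ``y`` into alternating ascending/descending sections.

    Parameters
    ----------
    y : array_like
        Signal values (ratio units).
    noise_pct : float
        Noise threshold in percent of the global data range
        ``max(y) - min(y)``.  Direction reversals smaller than this are
        absorbed into the current run; at 0 the decomposition is the exact
        monotone one (ties extend the current run).

    Returns
    -------
    list of Section
        Sections tile the signal without gaps or overlap and alternate in
        direction.  A constant signal yields a single section with
        ``degenerate=True`` so downstream rules can skip the signal.
    """
    y = np.asarray(y, dtype=float)
    n = y.size
    if n < 2:
        raise ValueError("signal must contain at least 2 samples")
    if not 0.0 <= noise_pct <= 100.0:
        raise ValueError(f"noise_pct must be in [0, 100], got {noise_pct}")
    global_range = float(y.max() - y.min())
    if global_range == 0.0:
        return [_close(y, 0, n, Direction.ASCENDING, degenerate=True)]
    thr = noise_pct / 100.0 * global_range

    sections: list[Section] = []
    start = 0
    d = 0  # 0 = direction not yet confirmed
    hi = lo = float(y[0])
    ihi = ilo = 0
    for i in range(1, n):
        v = float(y[i])
        if d == 0:
            if v > hi:
                hi, ihi = v, i
            if v < lo:
                lo, ilo = v, i
            if hi - lo > thr:
                d = 1 if ihi > ilo else -1
        elif d == 1:
            if v > hi:
                hi, ihi = v, i
            elif hi - v > thr:
                # all samples in (ihi, i) stayed within thr of hi, so v is
                # the strict minimum of the new descending run
                sections.append(_close(y, start, ihi + 1, Direction.ASCENDING))
                start = ihi + 1
                d = -1
                lo, ilo = v, i
        else:
            if v < lo:
                lo, ilo = v, i
            elif v - lo > thr:
                sections.append(_close(y, start, ilo + 1, Direction.DESCENDING))
                start = ilo + 1
                d = 1
                hi, ihi = v, i
    if d == 0:
        # total variation never exceeded the threshold: one section, signed
        # by the net endpoint movement
        d = 1 if y[n - 1] >= y[start] else -1
    sections.append(_close(y, start, n,
                           Direction.ASCENDING if d == 1 else Direction.DESCENDING))
    return sections


def pair_transients(sections: list[Section], y: np.ndarray) -> list[Transient]:
    """Pair each (ascending, descending) adjacent section pair into a Transient.

    A leading descending section and a trailing unpaired ascending section are
    retained in the section list as partial context but produce no transient.
    """
    y = np.asarray(y, dtype=float)
    transients: list[Transient] = []
    for k in range(len(sections) - 1):
        a, b = sections[k], sections[k + 1]
        if a.direction != Direction.ASCENDING or b.direction != Direction.DESCENDING:
            continue
        # the rise's minimum is the trough it rises from (shared boundary
        # extremum with the previous decay, when one exists)
        i_base = a.i_min
        transients.append(Transient(
            index=len(transients),
            sec_index=k,
            rise=a,
            decay=b,
            i_peak=a.i_max,
            i_base=i_base,
            v_peak=a.v_max,
            v_base=float(y[i_base]),
        ))
    return transients
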