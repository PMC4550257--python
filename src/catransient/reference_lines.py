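"""Top/bottom/middle reference lines fitted to section extrema.

The amplitude of a Ca2+ signal fades over a recording as the indicator
photobleaches, so fixed thresholds cannot serve as reference levels.
Instead, three simple linear regression lines are fitted against sample
index: *top* through each section's local maximum, *bottom* through each
section's local minimum, and *middle* as their pointwise average.  The
*regression height* — the vertical distance between top and bottom at a
given position — is the fading-robust amplitude scale that every percentage
rule is measured against.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .segmentation import Section

__all__ = ["ReferenceLines", "fit_reference_lines"]


def _ols(x: np.ndarray, v: np.ndarray) -> tuple[float, float]:
    """Least squares line through (x, v); horizontal fallback for < 2 distinct x.

    Uses the centred normal equations so that a constant v yields an exactly
    horizontal line (slope 0.0, intercept mean(v)).
    """
    x = np.asarray(x, dtype=float)
    v = np.asarray(v, dtype=float)
    if x.size == 0:
        raise ValueError("no support points")
    if np.unique(x).size < 2:
        return 0.0, float(v.mean())
    xm = x.mean()
    vm = v.mean()
    dx = x - xm
    dv = v - vm
    slope = float(dx @ dv) / float(dx @ dx)
    return slope, vm - slope * xm


@dataclass(frozen=True)
class ReferenceLines:
    """Three fitted reference lines; slopes are per sample, intercepts in ratio units."""

    top_slope: float
    top_intercept: float
    bottom_slope: float
    bottom_intercept: float
    support: int  # number of sections behind each fit

    def top(self, x):
        return self.top_slope * np.asarray(x, dtype=float) + self.top_intercept

    def bottom(self, x):
        return self.bottom_slope * np.asarray(x, dtype=float) + self.bottom_intercept

    def middle(self, x):
        return (self.top(x) + self.bottom(x)) / 2.0

    def height(self, x):
        """Regression height: max(0, top(x) - bottom(x)), clamped if the fits cross."""
        return np.maximum(0.0, self.top(x) - self.bottom(x))


def fit_reference_lines(sections: list[Section]) -> ReferenceLines:
    """Fit the top and bottom lines to the per-section extrema.

    Every section contributes one point to each line: (i_max, v_max) to the
    top fit and (i_min, v_min) to the bottom fit.  No outlier rejection is
    performed — dwarfed oscillation peaks do pull the top line down, which is
    the documented behaviour of the rules measured against it.  A single
    section yields horizontal lines at the global extrema.
    """
    if not sections:
        raise ValueError("at least one section required")
    xs_top = np.array([s.i_max for s in sections], dtype=float)
    vs_top = np.array([s.v_max for s in sections], dtype=float)
    xs_bot = np.array([s.i_min for s in sections], dtype=float)
    vs_bot = np.array([s.v_min for s in sections], dtype=float)
    top_slope, top_icpt = _ols(xs_top, vs_top)
    bot_slope, bot_icpt = _ols(xs_bot, vs_bot)
    return ReferenceLines(top_slope, top_icpt, bot_slope, bot_icpt,
                          support=len(sections))
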