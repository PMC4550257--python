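"""Independent reference implementations used as test oracles.

These deliberately use different mechanics from the package code: the
segmentation oracle re-scans the signal from each section start instead of
keeping running state, and the line-fit oracle solves the least-squares
design matrix directly.
"""

from __future__ import annotations

import numpy as np

from catransient.segmentation import Direction, Section


def _close_section(y, start, stop, direction, degenerate=False):
    lo = max(start - 1, 0)
    window = list(y[lo:stop])
    v_min = min(window)
    v_max = max(window)
    i_min = lo + window.index(v_min)
    i_max = lo + window.index(v_max)
    return Section(start, stop, direction, i_min, i_max, float(v_min),
                   float(v_max), degenerate)


def segment_bruteforce(y, noise_pct):
    """Re-scan run builder: same hysteresis contract as segment(), O(n^2)."""
    y = [float(v) for v in y]
    n = len(y)
    rng = max(y) - min(y)
    if rng == 0:
        return [_close_section(y, 0, n, Direction.ASCENDING, degenerate=True)]
    thr = noise_pct / 100.0 * rng

    # initial direction: first prefix whose range exceeds the threshold
    d = 0
    j0 = None
    for j in range(1, n):
        seg = y[: j + 1]
        if max(seg) - min(seg) > thr:
            d = 1 if seg.index(max(seg)) > seg.index(min(seg)) else -1
            j0 = j
            break
    if d == 0:
        direction = Direction.ASCENDING if y[-1] >= y[0] else Direction.DESCENDING
        return [_close_section(y, 0, n, direction)]

    sections = []
    start = 0
    j = j0
    while j < n:
        seg = y[start: j + 1]
        if d == 1:
            ext = max(seg)
            if ext - y[j] > thr:
                i_ext = start + seg.index(ext)
                sections.append(_close_section(y, start, i_ext + 1,
                                               Direction.ASCENDING))
                start = i_ext + 1
                d = -1
        else:
            ext = min(seg)
            if y[j] - ext > thr:
                i_ext = start + seg.index(ext)
                sections.append(_close_section(y, start, i_ext + 1,
                                               Direction.DESCENDING))
                start = i_ext + 1
                d = 1
        j += 1
    sections.append(_close_section(
        y, start, n, Direction.ASCENDING if d == 1 else Direction.DESCENDING))
    return sections


def ols_lstsq(x, v):
    """Least-squares line via the design matrix (numpy lstsq)."""
    x = np.asarray(x, dtype=float)
    v = np.asarray(v, dtype=float)
    if np.unique(x).size < 2:
        return 0.0, float(v.mean())
    A = np.column_stack([x, np.ones_like(x)])
    (slope, icpt), *_ = np.linalg.lstsq(A, v, rcond=None)
    return float(slope), float(icpt)


def plateau_runs_bruteforce(sm, w, thr):
    """All maximal interior sub-threshold runs of length >= w, by exhaustive
    enumeration of every candidate interval."""
    n = len(sm)
    runs = []
    for i in range(n):
        for j in range(i, n):
            if all(abs(s) <= thr for s in sm[i:j + 1]):
                maximal = ((i == 0 or abs(sm[i - 1]) > thr)
                           and (j == n - 1 or abs(sm[j + 1]) > thr))
                if maximal and (j - i + 1) >= w and i > 0 and j < n - 1:
                    runs.append((i, j))
    return runs
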