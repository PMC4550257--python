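"""The six rule-based anomaly detectors.

Each detector expresses a visual criterion a trained observer applies to a
Ca2+ trace as an explicit rule over sections, transients and the reference
lines.  All percentage comparisons are *inclusive* (<= / >=) at the stated
bound: a feature sitting exactly at a threshold carries the named outcome,
and flips as the parameter crosses the value.  "Within X% of line L" always
means |value - L(x)| <= (X/100) * regression_height(x), evaluated at the
feature's own sample index.

Pipeline order (fixed by the exclusion clauses between the rules):
oscillation > double peak > low peak > middle peak > irregular phase >
plateau.  Oscillating transients are consumed and not analysed further.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field, replace

import numpy as np
import yaml

from .reference_lines import ReferenceLines, fit_reference_lines
from .segmentation import Direction, Section, Transient, pair_transients, segment

__all__ = [
    "Subgroup", "ParameterSet", "RuleConstants", "AnomalyFlag", "Analysis",
    "PRESETS", "detect_oscillations", "detect_double_peaks", "detect_low_peaks",
    "detect_middle_peaks", "detect_irregular_phase", "detect_plateau", "run_all",
]


class Subgroup(str, enum.Enum):
    """The six abnormality subgroups."""

    LOW_PEAK = "low_peak"
    MIDDLE_PEAK = "middle_peak"
    OSCILLATION = "oscillation"
    DOUBLE_PEAK = "double_peak"
    IRREGULAR_PHASE = "irregular_phase"
    PLATEAU = "plateau"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


SUBGROUPS = tuple(Subgroup)


@dataclass(frozen=True)
class ParameterSet:
    """User-facing detection parameters, all in percent.

    ``noise_pct`` is the segmentation hysteresis (percent of global range);
    the remaining values bound the rules relative to the local regression
    height.  Two presets ship with the package: ``rs1`` for ~10 Hz
    recordings and ``rs2`` for ~25 Hz recordings (which carry more noise per
    unit amplitude, hence the wider noise band and higher low-peak floor).
    """

    noise_pct: float = 5.0
    low_lo: float = 7.0
    low_hi: float = 61.0
    mid_lo: float = 0.0
    mid_hi: float = 70.0
    plateau_pct: float = 70.0
    osc_pct: float = 31.0
    dbl_lo: float = 20.0
    dbl_hi: float = 88.0
    irr_pct: float = 100.0

    def __post_init__(self) -> None:
        for name, v in self.as_dict().items():
            if not 0.0 <= v <= 100.0:
                raise ValueError(f"{name} must be in [0, 100], got {v}")
        for lo, hi in (("low_lo", "low_hi"), ("mid_lo", "mid_hi"), ("dbl_lo", "dbl_hi")):
            if getattr(self, lo) > getattr(self, hi):
                raise ValueError(f"{lo} must not exceed {hi}")

    def as_dict(self) -> dict[str, float]:
        return {f: float(getattr(self, f)) for f in self.__dataclass_fields__}

    @classmethod
    def preset(cls, name: str) -> "ParameterSet":
        try:
            return PRESETS[name]
        except KeyError:
            raise KeyError(f"unknown preset {name!r}; available: {sorted(PRESETS)}") from None

    @classmethod
    def from_config(cls, path) -> "ParameterSet":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = set(cls.__dataclass_fields__)
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown parameter keys: {sorted(unknown)}")
        return cls(**data)

    def to_config(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.as_dict(), fh, sort_keys=False)

    def replace(self, **kw) -> "ParameterSet":
        return replace(self, **kw)


PRESETS: dict[str, ParameterSet] = {
    "rs1": ParameterSet(noise_pct=5.0, low_lo=7.0, low_hi=61.0, mid_lo=0.0,
                        mid_hi=70.0, plateau_pct=70.0, osc_pct=31.0,
                        dbl_lo=20.0, dbl_hi=88.0, irr_pct=100.0),
    "rs2": ParameterSet(noise_pct=8.0, low_lo=10.0, low_hi=61.0, mid_lo=0.0,
                        mid_hi=70.0, plateau_pct=70.0, osc_pct=31.0,
                        dbl_lo=20.0, dbl_hi=88.0, irr_pct=100.0),
}


@dataclass(frozen=True)
class RuleConstants:
    """Predefined rule constants (percent unless noted); overridable via config."""

    low_min_prox: float = 15.0    # base must sit within this band above the bottom line
    low_symmetry: float = 10.0    # decay/rise trough symmetry for the low-peak pair
    mid_max_band: float = 60.0    # middle-peak maximum band around the middle line
    mid_min_band: float = 40.0    # middle-peak minimum band around the middle line
    mid_surround: float = 75.0    # middle-peak section height vs surrounding sections
    dbl_top_prox: float = 40.0    # double-peak junction maximum proximity to top line
    dbl_follow_sym: float = 25.0  # double-peak dip vs following-rise height symmetry
    osc_min_peaks: int = 3        # minimum dwarfed run length for an oscillation (count)
    plateau_flank: float = 25.0   # movement required on each side of a pause,
                                  # percent of the section height

    def as_dict(self) -> dict:
        return {f: getattr(self, f) for f in self.__dataclass_fields__}

    @classmethod
    def from_config(cls, path) -> "RuleConstants":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        unknown = set(data) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown constant keys: {sorted(unknown)}")
        return cls(**data)

    def to_config(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.as_dict(), fh, sort_keys=False)

    def replace(self, **kw) -> "RuleConstants":
        return replace(self, **kw)


DEFAULT_CONSTANTS = RuleConstants()


@dataclass(frozen=True)
class AnomalyFlag:
    """One detected anomaly: subgroup, half-open sample span, contributors."""

    subgroup: Subgroup
    start: int
    stop: int
    members: tuple[int, ...] = ()     # transient indices contributing
    peaks: tuple[int, ...] = ()       # peak sample indices (double peak / oscillation)
    count_weight: int = 1

    @property
    def span(self) -> tuple[int, int]:
        return (self.start, self.stop)


# ---------------------------------------------------------------------------
# individual detectors
# ---------------------------------------------------------------------------

def detect_oscillations(
    transients: list[Transient],
    lines: ReferenceLines,
    params: ParameterSet,
    constants: RuleConstants = DEFAULT_CONSTANTS,
) -> tuple[list[AnomalyFlag], set[int]]:
    """Flag maximal runs of >= osc_min_peaks consecutive dwarfed transients.

    A transient is *dwarfed* when its amplitude is at most osc_pct% of the
    local regression height AND its base does not return to the bottom band
    (the same 15% band the low-peak rule uses).  Runs of exactly two dwarfed
    peaks are left to the double-peak detector.  Returns the flags and the
    set of consumed transient indices, which are not analysed further.
    """
    dwarfed = []
    for T in transients:
        H = float(lines.height(T.i_peak))
        Hb = float(lines.height(T.i_base))
        is_dwarfed = (
            H > 0.0
            and T.amplitude <= params.osc_pct / 100.0 * H
            and (T.v_base - float(lines.bottom(T.i_base)))
            > constants.low_min_prox / 100.0 * Hb
        )
        dwarfed.append(is_dwarfed)

    flags: list[AnomalyFlag] = []
    consumed: set[int] = set()
    j = 0
    while j < len(transients):
        if not dwarfed[j]:
            j += 1
            continue
        k = j
        while k + 1 < len(transients) and dwarfed[k + 1]:
            k += 1
        run = list(range(j, k + 1))
        if len(run) >= constants.osc_min_peaks:
            flags.append(AnomalyFlag(
                Subgroup.OSCILLATION,
                start=transients[j].rise.start,
                stop=transients[k].decay.stop,
                members=tuple(run),
                peaks=tuple(transients[m].i_peak for m in run),
            ))
            consumed.update(run)
        j = k + 1
    return flags, consumed


def detect_double_peaks(
    sections: list[Section],
    transients: list[Transient],
    lines: ReferenceLines,
    params: ParameterSet,
    constants: RuleConstants = DEFAULT_CONSTANTS,
    consumed: set[int] = frozenset(),
) -> list[AnomalyFlag]:
    """Flag pairs of peaks whose connecting dip fails to reach the bottom band.

    Only the descending (junction) sections are examined.  The junction
    between transients j and j+1 qualifies when, with H the regression height
    at the junction midpoint:

    1. the junction maximum lies within dbl_top_prox% of the top line;
    2. the junction height is within [dbl_lo, dbl_hi]% of H;
    3. the dip bottom lies within dbl_hi% of H below the top line
       (100% would be the bottom line, 50% the middle line);
    4. the junction height is within +/- dbl_follow_sym% of the following
       (rise) section's height.

    A flag spans exactly two peaks; junctions whose left transient already
    belongs to a flag are skipped, so chains never merge.
    """
    flags: list[AnomalyFlag] = []
    used: set[int] = set()
    for j in range(len(transients) - 1):
        A, B = transients[j], transients[j + 1]
        if B.sec_index != A.sec_index + 2:
            continue  # not section-adjacent (cannot happen with alternating runs)
        if j in consumed or j + 1 in consumed or j in used:
            continue
        d = A.decay
        mid_x = (d.start + d.stop - 1) // 2
        H = float(lines.height(mid_x))
        if H <= 0.0:
            continue
        c1 = (float(lines.top(d.i_max)) - d.v_max) <= constants.dbl_top_prox / 100.0 * H
        c2 = params.dbl_lo / 100.0 * H <= d.height <= params.dbl_hi / 100.0 * H
        c3 = (float(lines.top(d.i_min)) - d.v_min) <= params.dbl_hi / 100.0 * H
        nxt = B.rise
        c4 = abs(d.height - nxt.height) <= constants.dbl_follow_sym / 100.0 * nxt.height
        if c1 and c2 and c3 and c4:
            flags.append(AnomalyFlag(
                Subgroup.DOUBLE_PEAK,
                start=A.rise.start,
                stop=B.decay.stop,
                members=(j, j + 1),
                peaks=(A.i_peak, B.i_peak),
            ))
            used.update((j, j + 1))
    return flags


def detect_low_peaks(
    transients: list[Transient],
    lines: ReferenceLines,
    params: ParameterSet,
    constants: RuleConstants = DEFAULT_CONSTANTS,
    consumed: set[int] = frozenset(),
    double_flags: list[AnomalyFlag] = (),
) -> list[AnomalyFlag]:
    """Flag ascending sections carrying an abnormally small transient.

    Conditions: (1) the transient minimum sits within low_min_prox% of the
    regression height above the bottom line, (2) the transient maximum,
    measured from the bottom line, is within [low_lo, low_hi]% of the
    regression height, and (3) neither neighbouring transient carries a
    double-peak flag (a missing neighbour at the signal edge satisfies this
    vacuously).  The following descending section is co-flagged when its
    minimum matches the rise minimum to within low_symmetry% of the
    regression height (a fairly symmetrical peak); the pair counts once.
    """
    dbl_members: set[int] = set()
    for f in double_flags:
        dbl_members.update(f.members)
    flags: list[AnomalyFlag] = []
    for j, T in enumerate(transients):
        if j in consumed:
            continue
        Hp = float(lines.height(T.i_peak))
        Hb = float(lines.height(T.i_base))
        if Hp <= 0.0:
            continue
        c1 = (T.v_base - float(lines.bottom(T.i_base))) <= constants.low_min_prox / 100.0 * Hb
        rel = (T.v_peak - float(lines.bottom(T.i_peak))) / Hp
        c2 = params.low_lo / 100.0 <= rel <= params.low_hi / 100.0
        c3 = (j - 1 not in dbl_members) and (j + 1 not in dbl_members)
        if not (c1 and c2 and c3):
            continue
        Hd = float(lines.height(T.decay.i_min))
        symmetric = abs(T.decay.v_min - T.rise.v_min) <= constants.low_symmetry / 100.0 * Hd
        stop = T.decay.stop if symmetric else T.rise.stop
        flags.append(AnomalyFlag(Subgroup.LOW_PEAK, start=T.rise.start, stop=stop,
                                 members=(j,), peaks=(T.i_peak,)))
    return flags


def detect_middle_peaks(
    sections: list[Section],
    transients: list[Transient],
    lines: ReferenceLines,
    params: ParameterSet,
    constants: RuleConstants = DEFAULT_CONSTANTS,
    consumed: set[int] = frozenset(),
    low_flags: list[AnomalyFlag] = (),
) -> list[AnomalyFlag]:
    """Flag small transients floating around the middle reference line.

    Conditions: (1) the rise-section height is within [mid_lo, mid_hi]% of
    the regression height, (2) the transient maximum lies within
    mid_max_band% of the middle line, (3) the transient minimum lies within
    mid_min_band% of the middle line, (4) the rise-section height is at most
    mid_surround% of both surrounding sections (the previous transient's
    decay and the next transient's rise), and (5) neither this nor the
    previous transient is low-peak flagged.  Edge transients lack a
    neighbour and are not eligible (condition 4 is untestable).
    """
    low_members: set[int] = set()
    for f in low_flags:
        low_members.update(f.members)
    flags: list[AnomalyFlag] = []
    for j, T in enumerate(transients):
        if j in consumed or j == 0 or j == len(transients) - 1:
            continue
        k = T.sec_index
        if k - 1 < 0 or k + 2 >= len(sections):
            continue
        prev_sec, next_sec = sections[k - 1], sections[k + 2]
        mid_x = (T.rise.start + T.rise.stop - 1) // 2
        H1 = float(lines.height(mid_x))
        Hp = float(lines.height(T.i_peak))
        Hb = float(lines.height(T.i_base))
        if H1 <= 0.0:
            continue
        c1 = params.mid_lo / 100.0 * H1 <= T.rise.height <= params.mid_hi / 100.0 * H1
        c2 = abs(T.v_peak - float(lines.middle(T.i_peak))) <= constants.mid_max_band / 100.0 * Hp
        c3 = abs(T.v_base - float(lines.middle(T.i_base))) <= constants.mid_min_band / 100.0 * Hb
        c4 = T.rise.height <= constants.mid_surround / 100.0 * min(prev_sec.height,
                                                                   next_sec.height)
        c5 = (j not in low_members) and (j - 1 not in low_members)
        if c1 and c2 and c3 and c4 and c5:
            flags.append(AnomalyFlag(Subgroup.MIDDLE_PEAK, start=T.rise.start,
                                     stop=T.decay.stop, members=(j,), peaks=(T.i_peak,)))
    return flags


def detect_irregular_phase(
    transients: list[Transient],
    double_flags: list[AnomalyFlag],
    params: ParameterSet,
    excluded: set[int] = frozenset(),
    lines: ReferenceLines | None = None,
    global_range: float = 0.0,
) -> list[AnomalyFlag]:
    """Flag beat intervals deviating from the median peak distance.

    Peak positions are the i_peak of anomaly-free transients plus one
    synthetic position per double-peak flag at the mean of its two peak
    indices (so a double peak counts as one beat and cannot also register as
    irregular).  An interval that bridges an excluded anomalous peak is not a
    genuine beat distance — the long gap is an artefact of dropping the peak,
    not of the rhythm — and is left out of both the median and the flagging,
    extending to the other subgroups the same no-overlap principle that
    motivates merging double peaks.  With median interval m over the genuine
    intervals, interval d is flagged when |d - m| >= (irr_pct/100) * m.
    Fewer than three eligible peaks leave the median undefined and yield no
    flags.
    """
    dbl_members: set[int] = set()
    for f in double_flags:
        dbl_members.update(f.members)
    positions: list[float] = []
    excluded_peaks: list[float] = []
    for j, T in enumerate(transients):
        if j in dbl_members:
            continue
        if j in excluded:
            excluded_peaks.append(float(T.i_peak))
            continue
        # transients below the low-peak floor, or too small to clear the
        # noise hysteresis band on both flanks, are noise-scale blips, not
        # beats: low_lo is the preset's noise / low-peak discrimination
        # line, so such wiggles must not dilute the rhythm intervals
        floor = 2.0 * params.noise_pct / 100.0 * global_range
        if lines is not None:
            H = float(lines.height(T.i_peak))
            if H > 0:
                floor = max(floor, params.low_lo / 100.0 * H)
        if T.amplitude < floor:
            continue
        positions.append(float(T.i_peak))
    for f in double_flags:
        positions.append(float(np.mean(f.peaks)))
    positions.sort()
    if len(positions) < 3:
        return []
    genuine = [
        (k, float(positions[k + 1] - positions[k]))
        for k in range(len(positions) - 1)
        if not any(positions[k] < p < positions[k + 1] for p in excluded_peaks)
    ]
    if len(genuine) < 2:
        return []
    m = float(np.median([d for _, d in genuine]))
    if m <= 0.0:
        return []
    flags: list[AnomalyFlag] = []
    for k, d in genuine:
        if abs(d - m) >= params.irr_pct / 100.0 * m:
            flags.append(AnomalyFlag(
                Subgroup.IRREGULAR_PHASE,
                start=int(round(positions[k])),
                stop=int(round(positions[k + 1])) + 1,
            ))
    return flags


def smoothing_width(fs: float) -> int:
    """Centred moving-average width for plateau slopes: max(3, round(fs*0.2 s)), odd."""
    w = max(3, int(round(fs * 0.2)))
    if w % 2 == 0:
        w += 1
    return w


def detect_plateau(
    y: np.ndarray,
    fs: float,
    sections: list[Section],
    params: ParameterSet,
    constants: RuleConstants = DEFAULT_CONSTANTS,
    consumed_sections: set[int] = frozenset(),
) -> list[AnomalyFlag]:
    """Flag sections whose rate of ascent/descent pauses mid-section.

    Within each monotone section of at least 6 samples, per-sample slopes
    are smoothed with a centred moving average of width w (see
    :func:`smoothing_width`).  With r_max the maximum |smoothed slope| in
    the section, a plateau is a contiguous *interior* run of >= w samples
    with |smoothed slope| <= (1 - plateau_pct/100) * r_max, bounded on both
    sides by above-threshold slopes.  The interior requirement is what keeps
    a decay's natural flattening toward the trough from flagging every
    normal transient: only a pause that the section subsequently recovers
    from qualifies.  Recognition is tied to the noise setting in two ways:
    sections whose r_max does not exceed the noise-equivalent per-sample
    slope, (noise_pct/100)*global_range / w, never trigger; and the monotone
    movement on each side of the run must exceed both the noise threshold
    (noise_pct/100)*global_range and plateau_flank% of the section height,
    so that noise jitter around a decay's natural flattening toward the
    trough cannot make its tail look like an interrupted movement.
    One flag per section.
    """
    y = np.asarray(y, dtype=float)
    global_range = float(y.max() - y.min())
    w = smoothing_width(fs)
    noise_equiv = params.noise_pct / 100.0 * global_range / w
    flags: list[AnomalyFlag] = []
    for k, sec in enumerate(sections):
        if k in consumed_sections or len(sec) < 6:
            continue
        slopes = np.diff(y[sec.start:sec.stop])
        if slopes.size < w:
            continue
        sm = np.convolve(slopes, np.ones(w) / w, mode="valid")
        r_max = float(np.max(np.abs(sm)))
        if r_max <= noise_equiv:
            continue
        thr = (1.0 - params.plateau_pct / 100.0) * r_max
        noise_band = params.noise_pct / 100.0 * global_range
        below = np.abs(sm) <= thr
        half = w // 2
        # maximal runs of below-threshold smoothed slopes
        i = 0
        flagged = False
        while i < below.size and not flagged:
            if not below[i]:
                i += 1
                continue
            j = i
            while j + 1 < below.size and below[j + 1]:
                j += 1
            interior = i > 0 and j < below.size - 1
            if interior and (j - i + 1) >= w:
                # the pause must interrupt the section's main movement: the
                # flanking descents/ascents must each be above-noise and a
                # substantial part of the section height
                a = sec.start + i + half        # first sample of the pause
                b = sec.start + j + half + 1    # one past the last
                need = max(noise_band,
                           constants.plateau_flank / 100.0 * sec.height)
                level = float(np.mean(y[a:b]))
                if sec.direction == Direction.DESCENDING:
                    entry, exit_ = sec.v_max, sec.v_min
                else:
                    entry, exit_ = sec.v_min, sec.v_max
                before = abs(level - entry)
                after = abs(exit_ - level)
                if before > need and after > need:
                    flags.append(AnomalyFlag(Subgroup.PLATEAU, start=a, stop=b + 1))
                    flagged = True
            i = j + 1
    return flags


# ---------------------------------------------------------------------------
# pipeline
# ---------------------------------------------------------------------------

@dataclass
class Analysis:
    """Full per-signal detection output."""

    flags: list[AnomalyFlag]
    unclassifiable: bool
    sections: list[Section] = field(default_factory=list)
    transients: list[Transient] = field(default_factory=list)
    lines: ReferenceLines | None = None

    def counts(self) -> dict[Subgroup, int]:
        out = {sg: 0 for sg in SUBGROUPS}
        for f in self.flags:
            out[f.subgroup] += f.count_weight
        return out


def run_all(signal, params: ParameterSet,
            constants: RuleConstants = DEFAULT_CONSTANTS) -> Analysis:
    """Run the full detection pipeline on a Signal.

    Order: segment -> pair -> fit lines -> oscillation -> double peak ->
    low peak -> middle peak -> irregular phase -> plateau; each detector
    sees the exclusions produced upstream.  Degenerate signals (constant or
    a single section) yield an empty flag list and ``unclassifiable=True``.
    Flags are returned sorted by span start.
    """
    y = signal.y
    sections = segment(y, params.noise_pct)
    if len(sections) < 2 or sections[0].degenerate:
        return Analysis(flags=[], unclassifiable=True, sections=sections)
    transients = pair_transients(sections, y)
    lines = fit_reference_lines(sections)

    osc_flags, consumed = detect_oscillations(transients, lines, params, constants)
    dbl_flags = detect_double_peaks(sections, transients, lines, params, constants,
                                    consumed)
    low_flags = detect_low_peaks(transients, lines, params, constants, consumed,
                                 dbl_flags)
    mid_flags = detect_middle_peaks(sections, transients, lines, params, constants,
                                    consumed, low_flags)

    flagged: set[int] = set(consumed)
    for f in low_flags + mid_flags:
        flagged.update(f.members)
    irr_flags = detect_irregular_phase(transients, dbl_flags, params, flagged,
                                       lines, float(y.max() - y.min()))

    consumed_secs: set[int] = set()
    for j in consumed:
        T = transients[j]
        consumed_secs.update((T.sec_index, T.sec_index + 1))
    plat_flags = detect_plateau(y, signal.fs, sections, params, constants,
                                consumed_secs)

    flags = sorted(osc_flags + dbl_flags + low_flags + mid_flags + irr_flags
                   + plat_flags, key=lambda f: (f.start, f.subgroup.value))
    return Analysis(flags=flags, unclassifiable=False, sections=sections,
                    transients=transients, lines=lines)
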