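"""Labelled synthetic Ca2+ signal generator.

Emulates spontaneous cardiomyocyte Ca2+ transients as recorded by
ratiometric Fura-2 imaging: a periodic train of double-exponential pulses
on a flat baseline, peak amplitude fading linearly over the recording
(photobleaching), plus additive white Gaussian noise.  Abnormalities of
each of the six subgroups can be injected at chosen beats with controlled
geometry, and the generator returns the ground-truth label and sample span
of every injection, so every detector is testable without recordings.

Injected windows replace whole beat slots and are built from half-cosine
ramp segments between explicit level knots: the levels and section heights
the detection rules measure are then controlled exactly, while ramp edges
stay smooth and monotone.

Noise convention: the signal-to-noise ratio is quoted as transient
amplitude over the peak-to-peak noise band (taken as 6 standard
deviations), matching how an experimenter judges trace noise against the
noise-threshold slider.  ``noise_sd_for_snr`` converts.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .anomaly_rules import SUBGROUPS, Subgroup
from .signal_io import Signal, write_signal

__all__ = ["Injection", "GeneratorSpec", "TruthEntry", "GroundTruth",
           "generate", "make_benchmark", "noise_sd_for_snr",
           "single_injection_spec", "clean_spec"]


def noise_sd_for_snr(amplitude: float, snr: float) -> float:
    """Noise sd giving the requested amplitude / peak-to-peak(6 sd) ratio."""
    return amplitude / (6.0 * snr)


@dataclass(frozen=True)
class Injection:
    """One injected abnormality: subgroup, beat index, optional shape params."""

    subgroup: Subgroup
    beat: int
    params: dict = field(default_factory=dict)


@dataclass(frozen=True)
class GeneratorSpec:
    """Study conditions for one synthetic recording.

    Defaults emulate the slower of the two recording systems (10 Hz, 15 s,
    ~0.67 Hz spontaneous beating) with a 15%-per-recording photobleaching
    fade and noise at SNR 10.
    """

    fs: float = 10.0
    duration: float = 15.0
    baseline: float = 1.0
    amplitude: float = 1.0
    period: float = 1.5
    rise_tau: float = 0.15
    decay_tau: float = 0.4
    bleach_slope: float = 0.01   # ratio units lost per second of recording
    noise_sd: float = 1.0 / 60.0  # SNR 10 under the peak-to-peak convention
    injections: tuple[Injection, ...] = ()
    seed: int = 0

    def __post_init__(self) -> None:
        if self.fs <= 0:
            raise ValueError("fs must be positive")
        if self.duration * self.fs < 8:
            raise ValueError("duration*fs must be >= 8 samples")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")

    def replace(self, **kw) -> "GeneratorSpec":
        return replace(self, **kw)


@dataclass(frozen=True)
class TruthEntry:
    subgroup: Subgroup
    start: int
    stop: int


@dataclass(frozen=True)
class GroundTruth:
    entries: tuple[TruthEntry, ...]

    @property
    def expected_counts(self) -> dict[Subgroup, int]:
        out = {sg: 0 for sg in SUBGROUPS}
        for e in self.entries:
            out[e.subgroup] += 1
        return out


# ---------------------------------------------------------------------------
# waveform primitives
# ---------------------------------------------------------------------------

def _pulse(s: np.ndarray, rise_tau: float, decay_tau: float) -> np.ndarray:
    """Double-exponential Ca2+ transient template, normalised to peak 1."""
    s = np.maximum(s, 0.0)
    g = (1.0 - np.exp(-s / rise_tau)) * np.exp(-s / decay_tau)
    s_star = rise_tau * math.log1p(decay_tau / rise_tau)
    g_max = (1.0 - math.exp(-s_star / rise_tau)) * math.exp(-s_star / decay_tau)
    return g / g_max


def _cosine_knots(s: np.ndarray, knots: list[tuple[float, float]]) -> np.ndarray:
    """Piecewise half-cosine interpolation through (time, level) knots.

    Monotone between consecutive knots; holds the last level afterwards.
    """
    taus = np.array([k[0] for k in knots])
    vals = np.array([k[1] for k in knots])
    out = np.empty_like(s, dtype=float)
    idx = np.clip(np.searchsorted(taus, s, side="right") - 1, 0, len(knots) - 1)
    for i in range(s.size):
        k = int(idx[i])
        if k >= len(knots) - 1:
            out[i] = vals[-1]
        else:
            t0, v0 = taus[k], vals[k]
            t1, v1 = taus[k + 1], vals[k + 1]
            f = (s[i] - t0) / (t1 - t0)
            out[i] = v0 + (v1 - v0) * (1.0 - math.cos(math.pi * f)) / 2.0
    return out


# ---------------------------------------------------------------------------
# injected-shape constructors: return (knots, rhythm_factor) where knots are
# (time within window, level relative to the local transient amplitude)
# ---------------------------------------------------------------------------

def _knots_low(p: dict, rng: np.random.Generator):
    rel = p.get("rel_amplitude")
    if rel is None:
        rel = float(rng.uniform(0.15, 0.50))
    return [(0.0, 0.0), (0.3, rel), (1.35, 0.0)]


def _knots_double(p: dict, rng: np.random.Generator):
    depth = float(p.get("dip_depth", 0.5))
    return [(0.0, 0.0), (0.3, 1.0), (0.65, 1.0 - depth), (0.95, 1.0), (1.4, 0.0)]


def _knots_middle(p: dict, rng: np.random.Generator):
    base = float(p.get("base", 0.35))
    peak = float(p.get("peak", 0.70))
    return [(0.0, 0.0), (0.3, 1.0), (0.8, base), (1.2, peak), (2.85, 0.0)]


def _knots_oscillation(p: dict, rng: np.random.Generator):
    k = int(p.get("n_peaks", 4))
    if k < 3:
        raise ValueError("oscillation injection needs n_peaks >= 3")
    base = float(p.get("base", 0.45))
    h = float(p.get("fluctuation", 0.13))
    knots = [(0.0, 0.0), (0.3, 1.0), (0.75, base)]
    t = 0.75
    for _ in range(k):
        t += 0.25
        knots.append((t, base + h))
        t += 0.25
        knots.append((t, base))
    # fill the remaining window with a slow return to baseline so the
    # injected slots carry no long noise-only flat stretch
    n_slots = math.ceil((t + 0.45) / 1.5)
    knots.append((max(t + 0.4, n_slots * 1.5 - 0.15), 0.0))
    return knots


def _knots_plateau(p: dict, rng: np.random.Generator):
    top = float(p.get("shoulder_top", 0.55))
    bot = float(p.get("shoulder_bottom", 0.50))
    return [(0.0, 0.0), (0.28, 1.0), (0.5, top), (1.1, bot), (1.38, 0.0)]


_SHAPES = {
    Subgroup.LOW_PEAK: _knots_low,
    Subgroup.DOUBLE_PEAK: _knots_double,
    Subgroup.MIDDLE_PEAK: _knots_middle,
    Subgroup.OSCILLATION: _knots_oscillation,
    Subgroup.PLATEAU: _knots_plateau,
}

_DEFAULT_IRR_FACTOR = 2.5


def _n_slots(knots, period: float) -> int:
    return max(1, math.ceil((knots[-1][0] + 0.05) / period))


# ---------------------------------------------------------------------------
# generation
# ---------------------------------------------------------------------------

def generate(spec: GeneratorSpec) -> tuple[Signal, GroundTruth]:
    """Render a spec into a Signal plus per-injection ground truth.

    Deterministic given ``spec.seed``.  Raises on overlapping injections or
    injections placed at the first/last beat (edge beats stay normal so the
    neighbour-dependent rules can see every injected feature).
    """
    rng = np.random.default_rng(spec.seed)
    n = int(round(spec.duration * spec.fs))
    t = np.arange(n, dtype=float) / spec.fs

    irr = [inj for inj in spec.injections
           if inj.subgroup == Subgroup.IRREGULAR_PHASE]
    shaped = [inj for inj in spec.injections
              if inj.subgroup != Subgroup.IRREGULAR_PHASE]
    stretch = {inj.beat: float(inj.params.get("factor", _DEFAULT_IRR_FACTOR))
               for inj in irr}
    for inj in irr:
        f = stretch[inj.beat]
        if f <= 0:
            raise ValueError("irregular-phase stretch factor must be positive")

    # beat onset schedule; an irregular injection stretches the gap after its beat
    onsets: list[float] = [0.0]
    while True:
        gap = spec.period * stretch.get(len(onsets) - 1, 1.0)
        nxt = onsets[-1] + gap
        if nxt >= spec.duration - 1e-9:
            break
        onsets.append(nxt)
    n_beats = len(onsets)
    bounds = onsets + [spec.duration]
    starts = [int(np.searchsorted(t, b - 1e-9)) for b in bounds]

    # draw shapes and validate slot occupancy
    occupied: dict[int, tuple[Injection, list, int]] = {}
    taken: set[int] = set()
    for inj in shaped:
        knots = _SHAPES[inj.subgroup](inj.params, rng)
        m = _n_slots(knots, spec.period)
        slots = range(inj.beat, inj.beat + m)
        if inj.beat < 1 or inj.beat + m > n_beats - 1:
            raise ValueError(
                f"{inj.subgroup.value} injection at beat {inj.beat} does not fit "
                f"between the first and last beat (needs {m} slots of {n_beats})")
        if taken.intersection(slots):
            raise ValueError("injections overlap in time")
        taken.update(slots)
        occupied[inj.beat] = (inj, knots, m)
    for b in stretch:
        if b < 1 or b >= n_beats - 1:
            raise ValueError(f"irregular-phase injection at beat {b} out of range")
        if b in taken or b + 1 in taken:
            raise ValueError("injections overlap in time")

    y = np.zeros(n)
    truth: list[TruthEntry] = []
    k = 0
    while k < n_beats:
        onset = onsets[k]
        amp = max(spec.amplitude - spec.bleach_slope * onset,
                  0.2 * spec.amplitude)
        i0 = starts[k]
        if k in occupied:
            inj, knots, m = occupied[k]
            i1 = starts[k + m]
            s = np.maximum(t[i0:i1] - onset, 0.0)
            y[i0:i1] = amp * _cosine_knots(s, knots)
            truth.append(TruthEntry(inj.subgroup, i0, i1))
            k += m
        else:
            i1 = starts[k + 1]
            s = np.maximum(t[i0:i1] - onset, 0.0)
            y[i0:i1] = amp * _pulse(s, spec.rise_tau, spec.decay_tau)
            k += 1
    for b in sorted(stretch):
        truth.append(TruthEntry(Subgroup.IRREGULAR_PHASE, starts[b],
                                starts[min(b + 2, n_beats)]))
    truth.sort(key=lambda e: e.start)

    y += spec.baseline
    if spec.noise_sd > 0:
        y = y + rng.normal(0.0, spec.noise_sd, n)
    sig = Signal.from_arrays(f"synthetic-{spec.seed}", t, y)
    return sig, GroundTruth(entries=tuple(truth))


def clean_spec(fs: float = 10.0, seed: int = 0, **kw) -> GeneratorSpec:
    """A spec with no injections (a normal beating cell)."""
    return GeneratorSpec(fs=fs, seed=seed, **kw)


def single_injection_spec(subgroup: Subgroup | str, fs: float = 10.0,
                          seed: int = 0, beat: int | None = None,
                          params: dict | None = None, **kw) -> GeneratorSpec:
    """A spec carrying exactly one injection, placed mid-recording."""
    sg = Subgroup(subgroup)
    if beat is None:
        beat = 3
    return GeneratorSpec(fs=fs, seed=seed,
                         injections=(Injection(sg, beat, params or {}),), **kw)


def make_benchmark(n_signals: int, mix: dict[str, float], seed: int,
                   outdir) -> tuple[list[Path], Path]:
    """Write a directory of signal files plus a ground-truth table.

    ``mix`` maps 'normal' and subgroup names to proportions (must be
    non-negative and sum to 1); counts are apportioned by largest
    remainder.  Reproducible from ``seed``: the same seed yields
    byte-identical output.
    """
    keys = ["normal"] + [sg.value for sg in SUBGROUPS]
    unknown = set(mix) - set(keys)
    if unknown:
        raise ValueError(f"unknown mix keys: {sorted(unknown)}")
    props = np.array([float(mix.get(k, 0.0)) for k in keys])
    if np.any(props < 0) or not math.isclose(props.sum(), 1.0, abs_tol=1e-9):
        raise ValueError("mix proportions must be non-negative and sum to 1")

    ideal = props * n_signals
    counts = np.floor(ideal).astype(int)
    rem = ideal - counts
    for i in np.argsort(-rem)[: n_signals - counts.sum()]:
        counts[i] += 1

    labels: list[str] = []
    for key, c in zip(keys, counts):
        labels.extend([key] * int(c))

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    ss = np.random.SeedSequence(seed)
    child_seeds = [int(s.generate_state(1)[0] % (2 ** 31)) for s in
                   ss.spawn(n_signals)]
    paths: list[Path] = []
    records = []
    for i, (label, child) in enumerate(zip(labels, child_seeds)):
        if label == "normal":
            spec = clean_spec(seed=child)
            _, truth = None, GroundTruth(entries=())
            sig, _ = generate(spec)
        else:
            spec = single_injection_spec(label, seed=child)
            sig, truth = generate(spec)
        name = f"signal_{i:03d}.tsv"
        path = outdir / name
        sig = Signal(id=path.stem, t=sig.t, y=sig.y, fs=sig.fs)
        write_signal(sig, path)
        paths.append(path)
        if truth.entries:
            for e in truth.entries:
                records.append({"file": name, "label": e.subgroup.value,
                                "span_start": e.start, "span_stop": e.stop})
        else:
            records.append({"file": name, "label": "normal",
                            "span_start": -1, "span_stop": -1})
    truth_path = outdir / "truth.tsv"
    pd.DataFrame.from_records(records).to_csv(truth_path, sep="\t", index=False)
    return paths, truth_path
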