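# Methods

## Signal model and scope

A recording is a uniformly sampled scalar time series: Fura-2 ratio
(F340/F380, dimensionless) of one spontaneously beating cell, typically
9–26 Hz and 11–23 s. Input files are plain delimited text with one (value)
or two (time, value) numeric columns; time axes with more than 10% relative
sampling jitter are rejected rather than resampled, because every rule
below assumes a uniform grid. Sample indexing is 0-based and spans are
half-open `[start, stop)` throughout.

## Segmentation: noise-tolerant monotone runs

A *section* is a maximal run in which the signal ascends or descends
monotonously up to a hysteresis tolerance: while ascending, a downward
excursion ends the run only when the drop from the running maximum exceeds
`noise_pct`% of the **global data range** (max − min of the whole trace);
descending is symmetric. The global range was chosen as the reference scale
because it is stable under photobleaching fade and matches the calibrated
preset values being small single percentages. Boundaries are placed at the
running extremum itself, not at the threshold-crossing sample, and equal
consecutive values extend the current run.

Section spans tile the signal without overlap, but each run *begins* at the
terminal extremum of the previous run. Extrema and heights are therefore
computed over the closed window including the boundary extremum at the
span's left edge: an ascending section's minimum is the trough it rises
from, a descending section's maximum is the peak it falls from, and the
section height equals the true local data range. This matters at 10 Hz,
where the sample after a trough already sits most of the way up the rise —
with strictly span-contained extrema the bottom reference line would be
fitted near mid-amplitude and every percentage rule would be distorted.

A rise followed by a decay forms one *transient*; its peak is the shared
boundary extremum, its base is the trough preceding the rise, and its
amplitude is peak minus base. A constant trace yields a single degenerate
section and the signal is reported *unclassifiable*.

## Reference lines and regression height

Ordinary least squares against sample index, computed with centred normal
equations: the *top* line through each section's `(i_max, v_max)`, the
*bottom* line through each `(i_min, v_min)`, the *middle* as their
pointwise average. With fewer than two distinct support abscissae a line
falls back to a horizontal at the mean of the available extrema. The
*regression height* `H(x) = max(0, top(x) − bottom(x))` (clamped if the
fits cross) is the local amplitude scale for all percentage comparisons.

No outlier rejection is performed: dwarfed oscillation peaks do pull the
top line down and lift the bottom line. This is deliberate — the rules are
calibrated against that self-consistent height, and the acceptance checks
measure recovery under it.

## The six rules

All comparisons are inclusive (≤/≥) at the stated percentage; "within X% of
line L" means `|value − L(x)| ≤ (X/100)·H(x)` at the feature's own index.
Detectors run in the fixed precedence oscillation ≻ double peak ≻ low peak
≻ middle peak ≻ irregular phase ≻ plateau, each seeing the exclusions
produced upstream.

**Oscillation.** A transient is *dwarfed* when its amplitude is at most
`osc_pct`%·H and its base stays more than 15%·H above the bottom line (the
same band the low-peak rule uses for "reaching baseline"; the 15% reuse is
a design choice, since no tolerance is stated for "without reaching the
baseline"). A maximal run of ≥ 3 consecutive dwarfed transients is one
oscillation; runs of exactly two are left to the double-peak detector.
Oscillating transients are consumed and not analysed further.

**Double peak.** Only descending junction sections are examined. A junction
between transients flags when (1) its maximum is within 40%·H of the top
line, (2) its height is within `[dbl_lo, dbl_hi]`%·H, (3) its dip bottom is
within `dbl_hi`%·H below the top line (100% would be the bottom line, 50%
the middle line), and (4) its height matches the following rise's height to
±25%. One flag spans exactly two peaks; a junction whose left transient is
already paired is skipped, so chains never merge. Condition (1) is read as
distance-to-top-line in units of regression height, for consistency with
condition (3)'s depth scale.

**Low peak.** An ascending section flags when the transient base is within
15%·H of the bottom line, the peak (measured from the bottom line) is
within `[low_lo, low_hi]`%·H, and neither neighbouring transient carries a
double-peak flag — a missing neighbour at the signal edge satisfies this
vacuously; members of a double pair are excluded automatically because
their partner is a neighbouring double-flagged transient. The following
decay is co-flagged when its minimum matches the rise minimum to within
±10%·H (a fairly symmetrical peak); the pair counts as one anomaly.

**Middle peak.** A transient flags when its rise height is within
`[mid_lo, mid_hi]`%·H, its maximum is within a symmetric 60%·H band around
the middle line, its minimum within a symmetric 40%·H band, its rise height
is at most 75% of both surrounding sections (the previous transient's decay
and the next transient's rise), and neither this nor the previous transient
is low-flagged. Edge transients lack a neighbour and are ineligible.

**Irregular phase.** Rhythm peaks are the peaks of anomaly-free transients;
each double-peak pair contributes one synthetic position at the mean of its
two peaks, so a double peak is one beat and cannot also register as
irregular. Two refinements keep the rule from manufacturing irregularity
out of other anomalies or noise: (a) an interval bridging an excluded
anomalous peak is not a genuine beat distance and is omitted from both the
median and the flagging — the same no-overlap principle that motivates the
double-peak merge; (b) transients below the `low_lo` floor or smaller than
twice the noise band are noise-scale blips, not beats (`low_lo` is the
presets' own noise/low-peak discrimination line, and a beat must clear the
hysteresis band on both flanks to be segmentable at all). With median
interval m, an interval d flags when `|d − m| ≥ (irr_pct/100)·m`; fewer
than three rhythm peaks yield no evaluation.

**Plateau.** Within each monotone section of ≥ 6 samples, per-sample slopes
are smoothed by a centred moving average of width
`w = max(3, round(fs·0.2 s))` (made odd; 0.2 s matches the sampling-period
ratio of the two recording systems). With `r_max` the maximum smoothed
|slope| in the section, a plateau is a contiguous *interior* run of ≥ w
samples with |slope| ≤ `(1 − plateau_pct/100)·r_max`, bounded on both sides
by above-threshold slopes. Recognition is tied to the noise setting:
sections whose `r_max` does not exceed the noise-equivalent per-sample
slope `(noise_pct/100)·range/w` never trigger, and the movement flanking
the pause on each side must exceed both the noise band and 25% of the
section height (`plateau_flank`, a predefined constant). The interior and
flank requirements encode that a plateau *interrupts* a movement the
section then resumes; without them, a decay's natural flattening toward the
trough — plus noise jitter around it — would flag nearly every normal
transient.

### Parameters and presets

User parameters (`ParameterSet`, all percentages): `noise_pct`, `low_lo`,
`low_hi`, `mid_lo`, `mid_hi`, `plateau_pct`, `osc_pct`, `dbl_lo`, `dbl_hi`,
`irr_pct`. Presets: `rs1` = (5, 7, 61, 0, 70, 70, 31, 20, 88, 100) for
~10 Hz recordings, `rs2` = (8, 10, 61, …) for ~25 Hz. Predefined constants
(`RuleConstants`, overridable via config): base band 15, low symmetry ±10,
middle bands 60/40, surround 75, top proximity 40, follow symmetry ±25,
minimum oscillation run 3, plateau flank 25. Both round-trip through flat
YAML key/value files.

### Counting

One anomaly per flag (`count_weight` 1): a low-peak rise/decay pair, a
double-peak pair, a maximal oscillation run, one irregular interval and one
plateau pause each count once. The counting unit is configurable per flag
but the default is used throughout.

## Synthetic generator

`GeneratorSpec` defaults define the study conditions: 10 Hz (or 25 Hz for
the faster system), 15 s duration, baseline 1.0 and amplitude 1.0 ratio
units, beat period 1.5 s (40 beats/min, typical of spontaneously beating
iPSC-derived cardiomyocytes), double-exponential pulse with rise τ 0.15 s
and decay τ 0.4 s, photobleaching fade 0.01 ratio units/s (15% per
recording), white Gaussian noise.

SNR is quoted as transient amplitude over the peak-to-peak noise band
(taken as 6 standard deviations): this is how an experimenter eyeballs a
trace against the noise-threshold slider, which is itself a peak-to-peak
style band. The default `noise_sd = 1/60` is SNR 10. An RMS convention
would put single-sample noise excursions above the 5% preset hysteresis —
recordings the presets were never calibrated for.

Injections replace whole beat slots and are built from half-cosine ramps
between explicit level knots, so the levels and heights the rules test are
controlled exactly while edges stay smooth and monotone; injected windows
are timed to fill their slots because long noise-only flat stretches breed
spurious sections. Default geometries sit mid-range of the manual-analysis
criteria, relative to the self-consistent regression height (which the
injections themselves drag): low peak at 15–50% relative amplitude (drawn
per seed), double peak with a 50% dip, middle peak floating at 35→70%,
oscillation of 4 fluctuations of 13% on a 45% pedestal, plateau shoulder at
~50% level with slope ~8% of the peak rate, irregular phase as one beat
interval stretched ×2.5. Injections never occupy the first or last beat so
neighbour-dependent rules can see them. Everything is deterministic given
the spec's seed; `make_benchmark` writes byte-reproducible signal files
plus a ground-truth table.

What the generator does *not* emulate: correlated or signal-dependent
(shot) noise, baseline drift separate from amplitude fade, motion
artefacts, beat-to-beat waveform variability, or compound abnormalities
sharing one locus. Passing the round-trip checks therefore demonstrates
that the rules recover cleanly expressed single abnormalities under
realistic sampling, fade and white noise — not performance on pathological
real recordings.

## Numerical choices and degenerate inputs

- Centred-x least squares so constant support yields an exactly horizontal
  line; inclusive comparisons at every stated bound (verified by boundary
  tests at exactly representable feature levels).
- Ties extend monotone runs; argmax/argmin take the first attainment.
- Degenerate signals (constant, or a single monotone section) are
  *unclassifiable*: no flags, excluded from abnormal percentages'
  numerator but kept in the denominator.
- Interval medians use the standard even-count midpoint average; peak
  distances are measured in samples (equivalent to seconds at fixed fs).
- Fewer than 2 intervals (3 rhythm peaks) → no irregularity evaluation.

## Problem sizes used in the checks

The test suite and acceptance script use: 1,000 random signals (≤ 500
samples) for segmentation-oracle equivalence; 100 random signals for the
line-fit closed form; 500 fuzzed recordings for the exclusion invariants;
100 seeds × 6 subgroups × both recording conditions at SNR 10 for detector
sensitivity (threshold ≥ 0.9) and 100 clean recordings per condition for
the false-flag rate (≤ 0.05); a 344-signal batch for throughput. These
sizes give stable rates while keeping the default run fast.

## Known limitations

- Low peaks near the `low_lo` floor are intrinsically ambiguous with noise
  blips just above the segmentation hysteresis; on abnormal recordings a
  blip can occasionally be called a low peak when other anomalies lower the
  local regression height (the clean-signal false-positive rate stays
  ≤ ~2%).
- The regression lines are global fits; a long anomalous episode drags them
  locally (accepted behaviour, see above), so rule margins shrink around
  dense oscillation runs.
- Plateaus at the very start or end of a section (e.g. at the peak itself)
  are by design not flagged — only pauses the movement recovers from.
- Whether the original interactive tool excluded anomalous sections from
  the regression support is unknown; this implementation includes all
  sections.
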