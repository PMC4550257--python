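"""Unit tests of the six rule detectors on hand-built traces.

Traces are constructed piecewise with exact values and evaluated against
explicitly constructed reference lines (top/bottom fixed), so each rule's
arithmetic is isolated from the line-fitting step.
"""

import numpy as np
import pytest

from catransient import ParameterSet, RuleConstants, Signal, Subgroup, classify
from catransient.anomaly_rules import (AnomalyFlag, detect_double_peaks,
                                       detect_irregular_phase, detect_low_peaks,
                                       detect_middle_peaks, detect_oscillations,
                                       detect_plateau, run_all, smoothing_width)
from catransient.reference_lines import ReferenceLines
from catransient.segmentation import pair_transients, segment

from reference_impls import plateau_runs_bruteforce

RS1 = ParameterSet.preset("rs1")
C = RuleConstants()


def lines_const(top, bottom):
    return ReferenceLines(0.0, top, 0.0, bottom, support=99)


def prep(y, noise=0.0):
    y = np.asarray(y, dtype=float)
    secs = segment(y, noise)
    return y, secs, pair_transients(secs, y)


# centred convention for most fixtures: baseline -0.5, full peaks +0.5,
# so top = 0.5, bottom = -0.5, middle = 0, regression height = 1.
LINES = lines_const(0.5, -0.5)


class TestParameterSet:
    def test_presets_match_published_values(self):
        rs1 = ParameterSet.preset("rs1")
        assert (rs1.noise_pct, rs1.low_lo, rs1.low_hi) == (5.0, 7.0, 61.0)
        assert (rs1.mid_lo, rs1.mid_hi, rs1.plateau_pct) == (0.0, 70.0, 70.0)
        assert (rs1.osc_pct, rs1.dbl_lo, rs1.dbl_hi, rs1.irr_pct) == \
            (31.0, 20.0, 88.0, 100.0)
        rs2 = ParameterSet.preset("rs2")
        assert (rs2.noise_pct, rs2.low_lo) == (8.0, 10.0)
        assert rs2.replace(noise_pct=5.0, low_lo=7.0) == rs1

    def test_unknown_preset(self):
        with pytest.raises(KeyError):
            ParameterSet.preset("rs3")

    def test_validation(self):
        with pytest.raises(ValueError):
            ParameterSet(noise_pct=120.0)
        with pytest.raises(ValueError):
            ParameterSet(low_lo=50.0, low_hi=10.0)

    def test_config_round_trip(self, tmp_path):
        p = RS1.replace(noise_pct=6.5, osc_pct=25.0)
        path = tmp_path / "params.yaml"
        p.to_config(path)
        assert ParameterSet.from_config(path) == p
        c = RuleConstants().replace(plateau_flank=30.0)
        cpath = tmp_path / "constants.yaml"
        c.to_config(cpath)
        assert RuleConstants.from_config(cpath) == c

    def test_config_unknown_key_rejected(self, tmp_path):
        path = tmp_path / "bad.yaml"
        path.write_text("noise_pct: 5\nwibble: 3\n")
        with pytest.raises(ValueError, match="unknown"):
            ParameterSet.from_config(path)


class TestOscillation:
    def test_five_dwarfed_non_returning_one_flag(self):
        y, secs, trs = prep([-0.5, 0.5, 0.0, 0.2, 0.0, 0.2, 0.0, 0.2, 0.0,
                             0.2, 0.0, 0.2, 0.0, 0.5, -0.5])
        flags, consumed = detect_oscillations(trs, LINES, RS1)
        assert len(flags) == 1
        f = flags[0]
        assert f.subgroup == Subgroup.OSCILLATION
        assert len(f.members) == 5
        assert consumed == set(f.members)
        assert f.start == trs[f.members[0]].rise.start
        assert f.stop == trs[f.members[-1]].decay.stop

    def test_two_subthreshold_peaks_left_to_double_detector(self):
        y, secs, trs = prep([-0.5, 0.5, 0.0, 0.2, 0.0, 0.2, 0.0, 0.5, -0.5])
        flags, consumed = detect_oscillations(trs, LINES, RS1)
        assert flags == [] and consumed == set()

    def test_full_amplitude_returning_peaks_clean(self):
        y, secs, trs = prep([-0.5, 0.5, -0.5, 0.5, -0.5, 0.5, -0.5])
        flags, consumed = detect_oscillations(trs, LINES, RS1)
        assert flags == []

    def test_returning_to_baseline_not_dwarfed(self):
        # small but baseline-returning peaks are not oscillation material
        y, secs, trs = prep([-0.5, 0.5, -0.5, -0.3, -0.5, -0.3, -0.5, -0.3,
                             -0.5, 0.5, -0.5])
        flags, _ = detect_oscillations(trs, LINES, RS1)
        assert flags == []


class TestDoublePeak:
    def test_half_depth_dip_flagged(self):
        y, secs, trs = prep([-0.5, 0.5, 0.0, 0.5, -0.5, -0.5, -0.5])
        flags = detect_double_peaks(secs, trs, LINES, RS1)
        assert len(flags) == 1
        assert flags[0].peaks == (1, 3)
        assert len(flags[0].members) == 2

    def test_dip_to_bottom_line_not_flagged(self):
        y, secs, trs = prep([-0.5, 0.5, -0.5, 0.5, -0.5])
        assert detect_double_peaks(secs, trs, LINES, RS1) == []

    def test_chains_never_span_more_than_two_peaks(self):
        # three peaks joined by two qualifying dips: greedy pairing takes the
        # first junction and leaves the third peak alone
        y, secs, trs = prep([-0.5, 0.5, 0.0, 0.5, 0.0, 0.5, -0.5])
        flags = detect_double_peaks(secs, trs, LINES, RS1)
        assert len(flags) == 1
        assert flags[0].members == (0, 1)

    def test_consumed_transients_skipped(self):
        y, secs, trs = prep([-0.5, 0.5, 0.0, 0.5, -0.5, -0.5, -0.5])
        assert detect_double_peaks(secs, trs, LINES, RS1, consumed={0}) == []

    @pytest.mark.parametrize("depth,lo,hi,expected", [
        (0.5, 20, 88, True),
        (0.1, 20, 88, False),   # dip too shallow
        (0.95, 20, 88, False),  # dip deeper than the hi limit
        (0.5, 60, 88, False),   # lo raised above the dip height
        (0.3, 20, 88, True),
    ])
    def test_depth_sweep_against_conditions(self, depth, lo, hi, expected):
        dip = 0.5 - depth
        y, secs, trs = prep([-0.5, 0.5, dip, 0.5, -0.5, -0.5])
        params = RS1.replace(dbl_lo=lo, dbl_hi=hi)
        flags = detect_double_peaks(secs, trs, LINES, params)
        assert bool(flags) == expected


class TestLowPeak:
    def test_thirty_percent_peak_from_baseline(self):
        y, secs, trs = prep([0.0, 1.0, 0.0, 0.3, 0.0, 1.0, 0.0])
        L = lines_const(1.0, 0.0)
        flags = detect_low_peaks(trs, L, RS1)
        assert len(flags) == 1
        assert flags[0].members == (1,)
        # symmetric pair: the decay is co-flagged, one anomaly
        assert flags[0].stop == trs[1].decay.stop
        assert flags[0].count_weight == 1

    def test_neighbouring_double_peak_blocks(self):
        y, secs, trs = prep([0.0, 1.0, 0.5, 1.0, 0.0, 0.3, 0.0, 1.0, 0.0])
        L = lines_const(1.0, 0.0)
        dbl = detect_double_peaks(secs, trs, L, RS1)
        assert len(dbl) == 1  # the twin peaks
        flags = detect_low_peaks(trs, L, RS1, double_flags=dbl)
        assert flags == []

    def test_above_band_not_flagged(self):
        y, secs, trs = prep([0.0, 1.0, 0.0, 0.7, 0.0, 1.0, 0.0])
        assert detect_low_peaks(trs, lines_const(1.0, 0.0), RS1) == []

    def test_elevated_base_not_flagged(self):
        y, secs, trs = prep([0.0, 1.0, 0.3, 0.6, 0.3, 1.0, 0.0])
        assert detect_low_peaks(trs, lines_const(1.0, 0.0), RS1) == []

    def test_asymmetric_decay_not_co_flagged(self):
        y, secs, trs = prep([0.0, 1.0, 0.0, 0.4, 0.3, 1.0, 0.0])
        flags = detect_low_peaks(trs, lines_const(1.0, 0.0), RS1)
        assert len(flags) == 1
        assert flags[0].stop == trs[1].rise.stop  # rise only


class TestMiddlePeak:
    FEATURE = [-0.5, 0.55, -0.25, 0.35, -0.25, 0.55, -0.5, -0.5]

    def test_floating_half_height_peak_flagged(self):
        y, secs, trs = prep(self.FEATURE)
        flags = detect_middle_peaks(secs, trs, LINES, RS1)
        assert len(flags) == 1
        assert flags[0].members == (1,)

    def test_low_flag_on_same_transient_blocks(self):
        y, secs, trs = prep(self.FEATURE)
        low = [AnomalyFlag(Subgroup.LOW_PEAK, 2, 5, members=(1,))]
        assert detect_middle_peaks(secs, trs, LINES, RS1, low_flags=low) == []

    def test_low_flag_on_previous_transient_blocks(self):
        y, secs, trs = prep(self.FEATURE)
        low = [AnomalyFlag(Subgroup.LOW_PEAK, 0, 2, members=(0,))]
        assert detect_middle_peaks(secs, trs, LINES, RS1, low_flags=low) == []

    def test_edge_transients_never_flagged(self):
        # same floating feature but placed first in the signal
        y, secs, trs = prep([-0.25, 0.35, -0.25, 0.55, -0.5, 0.55, -0.5])
        flags = detect_middle_peaks(secs, trs, LINES, RS1)
        assert flags == []

    def test_tall_section_not_flagged(self):
        y, secs, trs = prep([-0.5, 0.55, -0.45, 0.45, -0.45, 0.55, -0.5])
        # height 0.9 exceeds mid_hi = 70% of the regression height
        assert detect_middle_peaks(secs, trs, LINES, RS1) == []


def spike_train(positions, n, height=1.0):
    y = np.zeros(n)
    for p in positions:
        y[p] = height
    return y


class TestIrregularPhase:
    L = lines_const(1.0, 0.0)

    def _detect(self, y, params=RS1, double_flags=(), excluded=frozenset()):
        y, secs, trs = prep(y)
        return detect_irregular_phase(trs, list(double_flags), params,
                                      excluded, self.L, 1.0), trs

    def test_one_stretched_interval_flagged(self):
        y = spike_train([5, 15, 25, 35, 60], 70)
        flags, trs = self._detect(y)
        assert len(flags) == 1
        assert flags[0].span == (35, 61)

    def test_periodic_train_clean(self):
        flags, _ = self._detect(spike_train([5, 15, 25, 35, 45], 55))
        assert flags == []

    def test_double_pair_merged_to_single_beat(self):
        # peaks at 5,15,*22+28*,35,45: the pair's mean position 25 restores
        # perfect periodicity, so no irregularity is reported
        y = spike_train([5, 15, 22, 28, 35, 45], 55)
        _, secs, trs = (np.asarray(y), segment(y, 0.0), None)
        trs = pair_transients(secs, y)
        dbl = [AnomalyFlag(Subgroup.DOUBLE_PEAK, 20, 30, members=(2, 3),
                           peaks=(22, 28))]
        flags = detect_irregular_phase(trs, dbl, RS1, frozenset(), self.L, 1.0)
        assert flags == []

    def test_interval_bridging_excluded_peak_not_evaluated(self):
        # the anomalous beat at 25 is dropped; the 10+10 bridge interval must
        # not be reported as irregular
        y = spike_train([5, 15, 25, 35, 45], 55)
        flags, trs = self._detect(y, excluded={2})
        assert flags == []

    def test_fewer_than_three_peaks_no_evaluation(self):
        flags, _ = self._detect(spike_train([5, 25], 35))
        assert flags == []

    def test_noise_scale_blips_are_not_beats(self):
        # a 5%-amplitude wiggle inside a long gap must not split the interval
        y = spike_train([5, 15, 25, 35, 60], 70)
        y[47] = 0.05
        flags, _ = self._detect(y)
        assert len(flags) == 1


def staircase(slopes):
    return np.concatenate([[0.0], np.cumsum(slopes)])


class TestPlateau:
    def _sections(self, y, noise=0.0):
        y = np.asarray(y, float)
        return y, segment(y, noise)

    def test_shoulder_in_decay_flagged(self):
        decay = staircase([-1, -1, -1, -1, -0.1, -0.1, -0.1, -0.1, -0.1,
                           -1, -1, -1, -1]) + 10.0
        y, secs = self._sections(np.concatenate([[0.0], decay]))
        flags = detect_plateau(y, 10.0, secs, RS1)
        assert len(flags) == 1
        assert flags[0].subgroup == Subgroup.PLATEAU
        # the flagged span lies inside the shoulder
        assert flags[0].start >= 5 and flags[0].stop <= 12

    def test_smooth_decay_not_flagged(self):
        decay = staircase([-1, -0.9, -0.8, -0.7, -0.6, -0.5, -0.45, -0.4]) + 6.0
        y, secs = self._sections(np.concatenate([[0.0], decay]))
        assert detect_plateau(y, 10.0, secs, RS1) == []

    def test_pause_at_tail_not_interior(self):
        decay = staircase([-1, -1, -1, -1, -0.05, -0.05, -0.05, -0.05]) + 5.0
        y, secs = self._sections(np.concatenate([[0.0], decay]))
        assert detect_plateau(y, 10.0, secs, RS1) == []

    def test_noise_scale_section_never_triggers(self):
        # whole section's slopes below the noise-equivalent magnitude
        decay = staircase([-.01, -.01, -.01, -.001, -.001, -.001, -.01,
                           -.01, -.01]) + 1.0
        y = np.concatenate([[0.0], decay, [50.0]])  # large range -> large guard
        secs = segment(y, 5.0)
        assert detect_plateau(y, 10.0, secs, RS1) == []

    @pytest.mark.parametrize("depth", [0.05, 0.1, 0.2, 0.35, 0.5])
    @pytest.mark.parametrize("width", [3, 5, 8])
    def test_matches_bruteforce_run_scan(self, depth, width):
        shoulder = [-depth] * width
        decay = staircase([-1] * 4 + shoulder + [-1] * 4) + 10.0
        y = np.concatenate([[0.0], decay])
        secs = self._sections(y)[1]
        flags = detect_plateau(y, 10.0, secs, RS1)

        w = smoothing_width(10.0)
        expected = False
        for sec in secs:
            if sec.direction != -1 or len(sec) < 6:
                continue
            sm = np.convolve(np.diff(y[sec.start:sec.stop]), np.ones(w) / w,
                             mode="valid")
            r_max = np.max(np.abs(sm))
            runs = plateau_runs_bruteforce(list(sm), w, 0.3 * r_max)
            for i, j in runs:
                a, b = sec.start + i + w // 2, sec.start + j + w // 2 + 1
                lev = np.mean(y[a:b])
                need = 0.25 * sec.height
                if (abs(lev - sec.v_max) > need
                        and abs(sec.v_min - lev) > need):
                    expected = True
        assert bool(flags) == expected


class TestRunAll:
    def test_clean_periodic_train_empty(self):
        from catransient.synthetic import GeneratorSpec, generate
        sig, _ = generate(GeneratorSpec(noise_sd=0.0))
        an = run_all(sig, RS1)
        assert an.flags == [] and not an.unclassifiable

    def test_one_injection_of_each_type_six_flags(self):
        from catransient.synthetic import GeneratorSpec, Injection, generate
        inj = tuple(Injection(sg, b) for sg, b in [
            (Subgroup.LOW_PEAK, 1), (Subgroup.DOUBLE_PEAK, 3),
            (Subgroup.MIDDLE_PEAK, 5), (Subgroup.OSCILLATION, 8),
            (Subgroup.PLATEAU, 12), (Subgroup.IRREGULAR_PHASE, 13)])
        sig, truth = generate(GeneratorSpec(duration=25.0, injections=inj,
                                            seed=1, noise_sd=0.0))
        an = run_all(sig, RS1)
        assert len(an.flags) == 6
        assert {f.subgroup for f in an.flags} == set(Subgroup)
        for f, e in zip(an.flags, truth.entries):
            assert f.subgroup == e.subgroup
            assert f.start < e.stop and f.stop > e.start

    def test_flags_sorted_and_deterministic(self):
        from catransient.synthetic import generate, single_injection_spec
        sig, _ = generate(single_injection_spec("oscillation", seed=9))
        a1 = run_all(sig, RS1)
        a2 = run_all(sig, RS1)
        assert a1.flags == a2.flags
        starts = [f.start for f in a1.flags]
        assert starts == sorted(starts)

    def test_degenerate_signal_unclassifiable(self):
        sig = Signal.from_values("flat", np.full(20, 1.0), 10.0)
        an = run_all(sig, RS1)
        assert an.unclassifiable and an.flags == []

    def test_oscillation_consumes_everything_inside(self):
        # four full beats anchor the fitted lines; five small non-returning
        # wiggles in the middle are one oscillation and nothing else
        y = np.array([-0.5, 0.5, -0.5, 0.5, 0.0, 0.1, 0.0, 0.1, 0.0, 0.1,
                      0.0, 0.1, 0.0, 0.1, 0.0, 0.5, -0.5, 0.5, -0.5])
        sig = Signal.from_values("osc", y + 1.0, 10.0)
        an = run_all(sig, RS1)
        osc = [f for f in an.flags if f.subgroup == Subgroup.OSCILLATION]
        assert len(osc) == 1
        for f in an.flags:
            if f.subgroup in (Subgroup.LOW_PEAK, Subgroup.MIDDLE_PEAK,
                              Subgroup.DOUBLE_PEAK):
                assert f.stop <= osc[0].start or f.start >= osc[0].stop
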