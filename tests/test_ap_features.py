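"""Beat detection and AP feature measurement against generator ground truth."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cardiokit.ap import (
    beat_rate,
    detect_beats,
    rate_corrected_apd,
    summarize_features,
    CAPD_METHODS,
)
from cardiokit.synth import APShapeParams, generate_ap_trace
from cardiokit.traces import VoltageTrace


class TestDetectBeats:
    def test_flat_trace_yields_no_beats(self):
        trace = VoltageTrace(v=np.full(25000, -70.0), fs=5000.0)
        assert detect_beats(trace) == []

    def test_complete_beats_and_activation_times(self, regular_trace):
        trace, gt = regular_trace
        beats = detect_beats(trace)
        assert len(beats) == gt.beat_times.size - 2  # first/last dropped
        acts = np.array([b.activation_time for b in beats])
        truth = gt.beat_times[1:-1]
        assert np.max(np.abs(acts - truth)) < 1e-3

    def test_beat_count_invariant_to_noise_seed(self, clean_shape):
        from dataclasses import replace
        shape = replace(clean_shape, noise_sd=0.5)
        counts = []
        for seed in (1, 2):
            trace, _ = generate_ap_trace(shape, np.full(29, 2.0), seed=seed)
            counts.append(len(detect_beats(trace)))
        assert counts[0] == counts[1] == 28


class TestMeasurements:
    def test_square_pulse_has_equal_apds(self):
        # instantaneous repolarization: APD20 = APD50 = APD90 = pulse width
        fs = 5000.0
        v = np.full(int(9 * fs), -80.0)
        for t_up in (1.0, 4.0, 7.0):
            i0, i1 = int(t_up * fs), int((t_up + 0.3) * fs)
            v[i0:i1] = 40.0
        beats = detect_beats(VoltageTrace(v=v, fs=fs))
        assert len(beats) == 1
        b = beats[0]
        for apd in (b.apd20, b.apd50, b.apd90):
            assert apd == pytest.approx(300.0, abs=1.0)

    def test_round_trip_morphology(self, regular_trace, clean_shape):
        trace, _ = regular_trace
        s = summarize_features(detect_beats(trace))
        assert s.apd20 == pytest.approx(clean_shape.apd20, abs=0.5)
        assert s.apd50 == pytest.approx(clean_shape.apd50, abs=0.5)
        assert s.apd90 == pytest.approx(clean_shape.apd90, abs=0.5)
        assert s.apa == pytest.approx(clean_shape.apa, abs=0.2)
        assert s.peak == pytest.approx(clean_shape.mdp + clean_shape.apa, abs=0.2)
        assert s.mdp == pytest.approx(clean_shape.mdp, abs=0.2)
        assert s.dvdt_max == pytest.approx(clean_shape.dvdt_max, rel=0.02)

    def test_apd_ordering_and_apa_identity(self, slow_trace):
        trace, _ = slow_trace
        for b in detect_beats(trace):
            assert b.apd20 <= b.apd50 <= b.apd90
            assert b.apa == pytest.approx(b.peak_v - b.mdp_pre, abs=1e-12)

    def test_measure_beat_on_explicit_window(self, regular_trace, clean_shape):
        from cardiokit.ap import measure_beat
        trace, gt = regular_trace
        a = gt.beat_times[5]
        b = measure_beat(trace, (a - 0.9, a + 0.95))
        assert b.apd90 == pytest.approx(clean_shape.apd90, abs=0.5)
        assert b.apa == pytest.approx(clean_shape.apa, abs=0.2)

    def test_halving_fs_changes_apd_below_half_ms(self, clean_shape):
        apds = {}
        for fs in (10000.0, 5000.0):
            trace, _ = generate_ap_trace(clean_shape, np.full(9, 2.0), fs=fs)
            s = summarize_features(detect_beats(trace))
            apds[fs] = (s.apd20, s.apd50, s.apd90)
        for a, b in zip(apds[10000.0], apds[5000.0]):
            assert abs(a - b) < 0.5


class TestBeatRate:
    def test_constant_ibi_examples(self):
        assert beat_rate(np.arange(11) * 1.0) == pytest.approx(60.0)
        assert beat_rate(np.arange(11) * 4.0) == pytest.approx(15.0)

    def test_undefined_below_two_beats(self):
        assert beat_rate(np.array([1.0])) is None
        assert beat_rate(np.array([])) is None

    def test_father_like_rate_recovered_on_long_trace(self, clean_shape):
        # 17.5 beats/min <-> mean IBI 3.4286 s
        mean_ibi = 60.0 / 17.5
        trace, _ = generate_ap_trace(
            clean_shape, np.full(47, mean_ibi), fs=5000.0, duration_s=170.0
        )
        rate = beat_rate(detect_beats(trace))
        assert rate == pytest.approx(17.5, rel=0.02)


class TestRateCorrection:
    @given(st.floats(min_value=50.0, max_value=600.0))
    @settings(max_examples=50, derandomize=True, deadline=None)
    def test_identity_at_60_bpm(self, apd90):
        for method in CAPD_METHODS:
            assert rate_corrected_apd(apd90, 60.0, method) == apd90

    def test_printed_formula_hand_values(self):
        assert rate_corrected_apd(300.0, 15.0, "bazett") == pytest.approx(150.0)
        assert rate_corrected_apd(300.0, 15.0, "fridericia") == pytest.approx(
            300.0 / 4.0 ** (1 / 3)
        )
        assert rate_corrected_apd(300.0, 15.0, "hodges") == pytest.approx(221.25)
        # Framingham in seconds then back to ms
        assert rate_corrected_apd(300.0, 30.0, "framingham") == pytest.approx(
            300.0 + 154.0 * (1.0 - 2.0)
        )

    @pytest.mark.parametrize("bpm", [20.0, 35.0, 50.0, 59.0])
    def test_bazett_corrects_harder_than_fridericia_below_60(self, bpm):
        apd = 400.0
        bz = rate_corrected_apd(apd, bpm, "bazett")
        fr = rate_corrected_apd(apd, bpm, "fridericia")
        assert abs(apd - bz) > abs(apd - fr)

    def test_unknown_method_rejected(self):
        with pytest.raises(ValueError, match="unknown"):
            rate_corrected_apd(300.0, 60.0, "karjalainen")
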