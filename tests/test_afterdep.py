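"""Afterdepolarization detection, cessation, chronotropy and pacing analysis."""

import numpy as np
import pytest

from cardiokit.afterdep import (
    analyze_post_pacing,
    assess_chronotropy,
    classify_recording,
    detect_afterdepolarizations,
    detect_cessation,
    summarize_incidence,
    RecordingVerdict,
)
from cardiokit.ap import detect_beats
from cardiokit.synth import (
    AfterdepSpec,
    APShapeParams,
    IsoproterenolScenario,
    IsoSegment,
    TrainsScenario,
    generate_ap_trace,
    generate_intervention_session,
)


def _detect(trace, threshold=0.03):
    beats = detect_beats(trace)
    return beats, detect_afterdepolarizations(trace, beats, threshold)


class TestDetection:
    def test_diastolic_bump_recovered_as_dad(self, clean_shape):
        ev = AfterdepSpec(beat_index=5, latency_ms=250, amplitude_fraction=0.05)
        trace, _ = generate_ap_trace(clean_shape, np.full(10, 3.0), events=[ev])
        _, events = _detect(trace)
        assert len(events) == 1
        assert events[0].kind == "DAD"
        assert events[0].fraction_of_apa == pytest.approx(0.05, abs=0.005)

    def test_subthreshold_bump_ignored(self, clean_shape):
        ev = AfterdepSpec(beat_index=5, latency_ms=250, amplitude_fraction=0.029)
        trace, _ = generate_ap_trace(clean_shape, np.full(10, 3.0), events=[ev])
        _, events = _detect(trace)
        assert events == []

    def test_phase3_bump_recovered_as_ead(self, clean_shape):
        ev = AfterdepSpec(beat_index=5, latency_ms=-150, amplitude_fraction=0.06,
                          width_ms=50)
        trace, _ = generate_ap_trace(clean_shape, np.full(10, 3.0), events=[ev])
        _, events = _detect(trace)
        assert [e.kind for e in events] == ["EAD"]

    def test_threshold_monotonicity(self, clean_shape):
        evs = [
            AfterdepSpec(beat_index=i, latency_ms=250, amplitude_fraction=f)
            for i, f in zip((2, 5, 8, 11), (0.035, 0.05, 0.07, 0.10))
        ]
        trace, _ = generate_ap_trace(clean_shape, np.full(14, 3.0), events=evs)
        beats = detect_beats(trace)
        counts = [
            len(detect_afterdepolarizations(trace, beats, thr))
            for thr in (0.03, 0.04, 0.06, 0.08, 0.12)
        ]
        assert counts == sorted(counts, reverse=True)
        assert counts[0] == 4 and counts[-1] == 0

    def test_classification_partition(self, clean_shape):
        evs = [
            AfterdepSpec(beat_index=4, latency_ms=-150, amplitude_fraction=0.06,
                         width_ms=50),
            AfterdepSpec(beat_index=8, latency_ms=300, amplitude_fraction=0.05),
        ]
        trace, _ = generate_ap_trace(clean_shape, np.full(12, 3.0), events=evs)
        beats, events = _detect(trace)
        assert len(events) == 2
        for e in events:
            host = beats[e.host_beat]
            nxt = beats[e.host_beat + 1]
            if e.kind == "DAD":
                assert host.repol90_time < e.time < nxt.activation_time
            else:
                assert host.peak_time < e.time < host.repol90_time

    def test_event_free_noisy_traces_have_no_false_positives(self, clean_shape):
        from dataclasses import replace
        shape = replace(clean_shape, noise_sd=0.5)
        for seed in range(5):
            trace, _ = generate_ap_trace(shape, np.full(19, 3.0), seed=seed)
            _, events = _detect(trace)
            assert events == []


class TestClassifyRecording:
    def test_clean_recording_all_flags_false(self, slow_trace):
        trace, _ = slow_trace
        beats, events = _detect(trace)
        verdict = classify_recording(events, beats, trace)
        assert not any([verdict.dad_positive, verdict.ead_positive,
                        verdict.afterdep_positive, verdict.arrhythmic,
                        verdict.ceased])

    def test_single_dad_sets_union_flag(self, clean_shape):
        ev = AfterdepSpec(beat_index=5, latency_ms=250, amplitude_fraction=0.05)
        trace, _ = generate_ap_trace(clean_shape, np.full(10, 3.0), events=[ev])
        beats, events = _detect(trace)
        verdict = classify_recording(events, beats, trace)
        assert verdict.dad_positive and verdict.afterdep_positive
        assert not verdict.ead_positive

    def test_long_interval_flags_arrhythmia(self, clean_shape):
        ibis = np.full(20, 1.5)
        ibis[10] = 4.0  # > 2x median
        trace, _ = generate_ap_trace(clean_shape, ibis)
        beats, events = _detect(trace)
        verdict = classify_recording(events, beats, trace)
        assert verdict.arrhythmic and not verdict.ceased


class TestCessation:
    def test_regular_trace_has_no_cessation(self, slow_trace):
        trace, _ = slow_trace
        beats = detect_beats(trace)
        assert detect_cessation(trace, beats) == []

    def test_twelve_second_gap_with_one_second_ibi(self, clean_shape):
        ibis = np.concatenate([np.full(12, 1.0), [12.0], np.full(12, 1.0)])
        trace, gt = generate_ap_trace(clean_shape, ibis)
        beats = detect_beats(trace)
        intervals = detect_cessation(trace, beats)
        assert len(intervals) == 1
        c0, c1 = intervals[0]
        assert c1 - c0 == pytest.approx(12.0, abs=0.1)

    def test_beat_free_tail_reported(self, clean_shape):
        ibis = np.full(15, 2.0)
        trace, _ = generate_ap_trace(clean_shape, ibis, duration_s=62.0)
        beats = detect_beats(trace)  # beats end at ~31 s of a 62-s trace
        intervals = detect_cessation(trace, beats)
        assert len(intervals) == 1
        assert intervals[0][1] == pytest.approx(trace.t_end)


class TestChronotropy:
    @staticmethod
    def _session(clean_shape, segs, seed=0):
        trace, gt = generate_intervention_session(
            clean_shape, np.full(20, 2.0), IsoproterenolScenario(segs), seed=seed
        )
        return [(lbl, trace.crop(a, b)) for lbl, a, b, _ in gt.segments]

    def test_dose_escalation_is_chronotropic_without_abnormality(self, clean_shape):
        segs = tuple(IsoSegment(l, m, 40.0) for l, m in
                     [("base", 1.0), ("a", 1.1), ("b", 1.3), ("c", 1.6), ("d", 2.0)])
        res = assess_chronotropy(self._session(clean_shape, segs))
        assert res.chronotropic_positive
        assert res.abnormal_conditions == []

    def test_flat_response_is_not_chronotropic(self, clean_shape):
        segs = tuple(IsoSegment(l, 1.0, 40.0) for l in ("base", "a", "b"))
        res = assess_chronotropy(self._session(clean_shape, segs))
        assert not res.chronotropic_positive

    def test_dads_and_cessation_mark_conditions_abnormal(self, clean_shape):
        segs = (
            IsoSegment("base", 1.0, 40.0),
            IsoSegment("1e-8", 1.3, 40.0),
            IsoSegment("1e-7", 1.6, 40.0,
                       events=(AfterdepSpec(3, 250, 0.05),)),
            IsoSegment("1e-6", 2.0, 40.0, cease=True),
        )
        res = assess_chronotropy(self._session(clean_shape, segs))
        assert res.abnormal_conditions == ["1e-7", "1e-6"]


class TestPostPacing:
    @staticmethod
    def _trains(clean_shape, window_events=None, seed=0):
        sc = TrainsScenario(window_events=window_events or {})
        return generate_intervention_session(
            clean_shape, np.full(10, 2.0), sc, seed=seed
        )

    def test_clean_session_has_no_abnormal_windows(self, clean_shape):
        trace, gt = self._trains(clean_shape)
        verdicts = analyze_post_pacing(trace, gt.stim_trains)
        assert len(verdicts) == 4
        scored = [tv for tv in verdicts if tv.scored]
        assert [tv.frequency_hz for tv in scored] == [1.0, 1.5, 2.0]
        assert all(
            not (tv.verdict.dad_positive or tv.verdict.arrhythmic or tv.verdict.ceased)
            for tv in scored
        )

    def test_dad_after_2hz_train_marks_only_that_window(self, clean_shape):
        trace, gt = self._trains(
            clean_shape, window_events={2.0: ((2, AfterdepSpec(0, 250, 0.05)),)}
        )
        verdicts = analyze_post_pacing(trace, gt.stim_trains)
        flags = {tv.frequency_hz: tv.verdict.dad_positive for tv in verdicts}
        assert flags == {0.5: False, 1.0: False, 1.5: False, 2.0: True}

    def test_event_after_half_hz_train_excluded_from_tally(self, clean_shape):
        trace, gt = self._trains(
            clean_shape, window_events={0.5: ((2, AfterdepSpec(0, 250, 0.05)),)}
        )
        verdicts = analyze_post_pacing(trace, gt.stim_trains)
        abnormal_scored = [
            tv for tv in verdicts
            if tv.scored and (tv.verdict.dad_positive or tv.verdict.arrhythmic
                              or tv.verdict.ceased)
        ]
        assert abnormal_scored == []
        half = next(tv for tv in verdicts if tv.frequency_hz == 0.5)
        assert half.verdict.dad_positive and not half.scored


class TestIncidence:
    def test_printed_count_arithmetic(self):
        pos = [RecordingVerdict(dad_positive=True, afterdep_positive=True)]
        neg = [RecordingVerdict()]
        groups = {
            "son": pos * 7 + neg * 7,
            "father": pos * 8 + neg * 20,
            "control": neg * 30,
        }
        out = summarize_incidence(groups)
        assert out["son"] == (pytest.approx(50.0), 7, 14)
        assert round(out["father"][0]) == 29
        assert out["control"] == (pytest.approx(0.0), 0, 30)

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            summarize_incidence({"empty": []})
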