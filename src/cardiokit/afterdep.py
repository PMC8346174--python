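"""Afterdepolarization detection, cessation of firing, and intervention scoring.

An afterdepolarization is an abnormal depolarization whose amplitude reaches
at least 3% of the preceding beat's AP amplitude (APA): a DAD when it occurs
after completion of repolarization (operationalized here as the
90%-repolarization crossing), an EAD when it occurs between the AP peak and
that crossing.

Event amplitude is measured against a local baseline taken as the median of
flanking windows on either side of the bump (robust to the slow diastolic
depolarization).  "Arrhythmia" has no quantitative definition in the
afterdepolarization framework; the proxy used here flags any inter-beat
interval longer than twice the recording's median IBI, and is reported
separately from the DAD/EAD flags.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy.signal import find_peaks, savgol_filter

from .ap import Beat, DetectorConfig, activation_times, beat_rate, detect_beats
from .traces import VoltageTrace

__all__ = [
    "AfterdepEvent",
    "RecordingVerdict",
    "InterventionAssessment",
    "TrainVerdict",
    "detect_afterdepolarizations",
    "classify_recording",
    "detect_cessation",
    "assess_chronotropy",
    "analyze_post_pacing",
    "summarize_incidence",
]

log = logging.getLogger(__name__)

DEFAULT_THRESHOLD_FRACTION = 0.03
# Guard band (fraction of APA) absorbing the sub-sample measurement bias of the
# amplitude estimator, so a bump generated exactly at threshold is kept.
THRESHOLD_GUARD_FRACTION = 5e-4

# candidate/measurement smoothing and baseline geometry (s)
CANDIDATE_SMOOTH_S = 0.011
MEASURE_SMOOTH_S = 0.005
CANDIDATE_PROMINENCE_MV = 1.0
FLANK_GAP_S = 0.030
FLANK_WIDTH_S = 0.050
PEAK_EXCLUSION_S = 0.010
UPSTROKE_EXCLUSION_S = 0.030


@dataclass
class AfterdepEvent:
    """A detected DAD or EAD, referenced to its host beat's APA."""

    kind: str  # 'DAD' | 'EAD'
    time: float
    amplitude_mv: float
    fraction_of_apa: float
    host_beat: int


@dataclass
class RecordingVerdict:
    """Binary phenotype flags for one recording."""

    dad_positive: bool = False
    ead_positive: bool = False
    afterdep_positive: bool = False
    arrhythmic: bool = False
    ceased: bool = False
    events: list = field(default_factory=list)
    cessation_intervals: list = field(default_factory=list)


@dataclass
class InterventionAssessment:
    """Chronotropic response plus per-condition abnormality labels."""

    baseline_rate: Optional[float]
    condition_rates: list  # (label, bpm or None)
    chronotropic_positive: bool
    abnormal_conditions: list


@dataclass
class TrainVerdict:
    """Post-pacing window score for one stimulation train."""

    frequency_hz: float
    window: tuple
    verdict: RecordingVerdict
    scored: bool
    truncated: bool = False


def _odd(n: int) -> int:
    n = max(n, 3)
    return n + 1 if n % 2 == 0 else n


def _smooth(v: np.ndarray, fs: float, window_s: float) -> np.ndarray:
    w = _odd(int(round(window_s * fs)))
    if v.size <= w:
        return v.copy()
    return savgol_filter(v, w, polyorder=2)


def detect_afterdepolarizations(
    trace: VoltageTrace,
    beats: Sequence[Beat],
    threshold_fraction: float = DEFAULT_THRESHOLD_FRACTION,
) -> list[AfterdepEvent]:
    """Find DAD/EAD events whose amplitude is >= threshold_fraction of APA.

    Candidates are local maxima of the smoothed trace between a beat's AP peak
    and the next activation (upstrokes excluded).  Amplitude is the smoothed
    local maximum minus the median of flanking baseline windows; events are
    classified DAD/EAD by their position relative to the host beat's
    90%-repolarization crossing.
    """
    if threshold_fraction <= 0:
        raise ValueError("threshold_fraction must be positive")
    if len(beats) < 2:
        return []
    v_cand = _smooth(trace.v, trace.fs, CANDIDATE_SMOOTH_S)
    v_meas = _smooth(trace.v, trace.fs, MEASURE_SMOOTH_S)
    idx, _ = find_peaks(v_cand, prominence=CANDIDATE_PROMINENCE_MV)
    if idx.size == 0:
        return []
    peak_t = trace.t0 + idx / trace.fs

    fs = trace.fs
    events: list[AfterdepEvent] = []
    for j, b in enumerate(beats[:-1]):
        nxt = beats[j + 1]
        lo = b.peak_time + PEAK_EXCLUSION_S
        hi = nxt.activation_time - UPSTROKE_EXCLUSION_S
        for i in idx[(peak_t > lo) & (peak_t < hi)]:
            amp = _event_amplitude(v_meas, trace, i)
            if amp is None:
                continue
            if b.apa <= 0:
                log.info("event at %.3fs discarded: host beat has no measurable APA",
                         trace.t0 + i / fs)
                continue
            fraction = amp / b.apa
            if fraction < threshold_fraction - THRESHOLD_GUARD_FRACTION:
                continue
            t_ev = trace.t0 + i / fs
            if b.repol90_time is not None and t_ev <= b.repol90_time:
                kind = "EAD"
            else:
                kind = "DAD"
            events.append(
                AfterdepEvent(
                    kind=kind,
                    time=t_ev,
                    amplitude_mv=float(amp),
                    fraction_of_apa=float(fraction),
                    host_beat=j,
                )
            )
    events.sort(key=lambda e: e.time)
    return events


def _event_amplitude(v_meas: np.ndarray, trace: VoltageTrace, i: int) -> Optional[float]:
    """Peak height above the local baseline.

    The baseline is the line through the medians of the two flanking windows
    (evaluated at their centres), so a sloping diastolic depolarization or
    phase-3 repolarization under the bump cancels to first order.
    """
    fs = trace.fs
    gap = int(round(FLANK_GAP_S * fs))
    width = int(round(FLANK_WIDTH_S * fs))
    l0, l1 = i - gap - width, i - gap
    r0, r1 = i + gap, i + gap + width
    if l0 < 0 or r1 > trace.n:
        return None
    med_l = float(np.median(trace.v[l0:l1]))
    med_r = float(np.median(trace.v[r0:r1]))
    c_l = 0.5 * (l0 + l1 - 1)
    c_r = 0.5 * (r0 + r1 - 1)
    lo = max(i - int(round(0.010 * fs)), 0)
    hi = min(i + int(round(0.010 * fs)) + 1, trace.n)
    j = np.arange(lo, hi)
    baseline = med_l + (med_r - med_l) * (j - c_l) / (c_r - c_l)
    return float(np.max(v_meas[lo:hi] - baseline))


def classify_recording(
    events: Sequence[AfterdepEvent],
    beats: Sequence[Beat],
    trace: VoltageTrace,
    gap_factor: float = 5.0,
    min_gap_s: float = 10.0,
) -> RecordingVerdict:
    """Combine event, rhythm and cessation flags into a recording verdict."""
    verdict = RecordingVerdict(events=list(events))
    verdict.dad_positive = any(e.kind == "DAD" for e in events)
    verdict.ead_positive = any(e.kind == "EAD" for e in events)
    verdict.afterdep_positive = verdict.dad_positive or verdict.ead_positive

    acts = activation_times(beats)
    if acts.size >= 3:
        ibis = np.diff(acts)
        verdict.arrhythmic = bool(np.any(ibis > 2.0 * np.median(ibis)))

    verdict.cessation_intervals = detect_cessation(trace, beats, gap_factor, min_gap_s)
    verdict.ceased = bool(verdict.cessation_intervals)
    return verdict


def detect_cessation(
    trace: VoltageTrace,
    beats: Sequence[Beat],
    gap_factor: float = 5.0,
    min_gap_s: float = 10.0,
) -> list:
    """Intervals with no activation for max(min_gap_s, gap_factor * median IBI).

    A beat-free trace tail longer than the threshold is included.  A trace
    with fewer than two beats is one cessation interval when long enough.
    """
    acts = activation_times(beats)
    if acts.size < 2:
        if trace.duration >= min_gap_s:
            return [(trace.t0, trace.t_end)]
        return []
    ibis = np.diff(acts)
    threshold = max(min_gap_s, gap_factor * float(np.median(ibis)))
    intervals = [
        (float(acts[i]), float(acts[i + 1]))
        for i in range(ibis.size)
        if ibis[i] > threshold
    ]
    if trace.t_end - acts[-1] > threshold:
        intervals.append((float(acts[-1]), trace.t_end))
    return intervals


def assess_chronotropy(
    segments: Sequence[tuple],
    cfg: DetectorConfig = DetectorConfig(),
    threshold_fraction: float = DEFAULT_THRESHOLD_FRACTION,
) -> InterventionAssessment:
    """Score an isoproterenol dose-escalation run.

    ``segments`` is [(label, VoltageTrace), ...] with the baseline first.  A
    positive chronotropic response is a beat rate strictly above baseline in
    at least one drug condition.  Conditions with DADs, an arrhythmic rhythm,
    or cessation (including loss of all firing when the baseline fired) are
    listed in ``abnormal_conditions``.
    """
    if len(segments) < 2:
        raise ValueError("need a baseline segment plus at least one condition")
    base_label, base_trace = segments[0]
    base_beats = detect_beats(base_trace, cfg)
    base_rate = beat_rate(base_beats)

    condition_rates = []
    abnormal = []
    chrono = False
    for label, seg_trace in segments[1:]:
        beats = detect_beats(seg_trace, cfg)
        rate = beat_rate(beats)
        condition_rates.append((label, rate))
        # strict increase by any margin; the relative guard only absorbs
        # floating-point jitter between numerically identical rates
        if rate is not None and base_rate is not None and rate > base_rate * (1 + 1e-9):
            chrono = True
        events = detect_afterdepolarizations(seg_trace, beats, threshold_fraction)
        # short drug segments: treat a gap > half the segment as cessation too
        verdict = classify_recording(
            events, beats, seg_trace,
            min_gap_s=min(10.0, 0.5 * seg_trace.duration),
        )
        ceased = verdict.ceased or (rate is None and base_rate is not None)
        if verdict.dad_positive or verdict.arrhythmic or ceased:
            abnormal.append(label)
    return InterventionAssessment(
        baseline_rate=base_rate,
        condition_rates=condition_rates,
        chronotropic_positive=chrono,
        abnormal_conditions=abnormal,
    )


SCORED_TRAIN_FREQS = (1.0, 1.5, 2.0)


def analyze_post_pacing(
    trace: VoltageTrace,
    stim_trains: Sequence[tuple],
    window_s: float = 20.0,
    cfg: DetectorConfig = DetectorConfig(),
    threshold_fraction: float = DEFAULT_THRESHOLD_FRACTION,
    scored_freqs: Sequence[float] = SCORED_TRAIN_FREQS,
) -> list[TrainVerdict]:
    """Score the post-pacing window following each stimulation train.

    ``stim_trains`` is [(frequency_hz, stim_times), ...].  The window after a
    train's last stimulus is classified for DADs, arrhythmia and cessation;
    trains outside ``scored_freqs`` (the 0.5-Hz train, which faster-firing
    cells cannot follow) are recorded but flagged unscored.
    """
    verdicts = []
    for freq, stims in stim_trains:
        stims = np.asarray(stims, dtype=float)
        w0 = float(stims[-1])
        w1 = w0 + window_s
        truncated = w1 > trace.t_end
        w1 = min(w1, trace.t_end)
        sub = trace.crop(w0, w1)
        beats = detect_beats(sub, cfg)
        events = detect_afterdepolarizations(sub, beats, threshold_fraction)
        verdict = classify_recording(events, beats, sub,
                                     min_gap_s=min(10.0, 0.75 * window_s))
        verdicts.append(
            TrainVerdict(
                frequency_hz=float(freq),
                window=(w0, w1),
                verdict=verdict,
                scored=any(math.isclose(freq, f) for f in scored_freqs),
                truncated=truncated,
            )
        )
    return verdicts


def summarize_incidence(verdicts_by_group: dict, flag: str = "afterdep_positive") -> dict:
    """Percent of positive recordings per group, with counts.

    Returns {group: (percent, positives, total)}.
    """
    out = {}
    for group, verdicts in verdicts_by_group.items():
        if len(verdicts) == 0:
            raise ValueError(f"group {group!r} has no recordings")
        pos = sum(1 for v in verdicts if getattr(v, flag))
        out[group] = (100.0 * pos / len(verdicts), pos, len(verdicts))
    return out
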