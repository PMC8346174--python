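"""Preset synthetic cohorts mirroring the study conditions.

The three presets emulate the qualitative phenotypes of the patient-derived
lines: a fast-firing control-like cell (62.9 beats/min) and two slow,
long-APD mutant-like cells ("father", 17.5 bpm; "son", 14.2 bpm).  Morphology
values other than the beat rates are plausible stem-cell-derived
cardiomyocyte figures chosen once for the generator; they are presets, not
measurements.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Optional, Sequence

import numpy as np

from .afterdep import classify_recording, detect_afterdepolarizations
from .ap import DetectorConfig, detect_beats
from .synth import (
    AfterdepSpec,
    APShapeParams,
    IBIModelParams,
    generate_ap_trace,
    generate_ibi_sequence,
)

__all__ = ["COHORT_PRESETS", "CohortPreset", "make_recording",
           "afterdep_cohort_verdicts", "afterdep_incidence_pct"]


@dataclass(frozen=True)
class CohortPreset:
    label: str
    rate_bpm: float
    shape: APShapeParams


COHORT_PRESETS = {
    "control": CohortPreset(
        label="control",
        rate_bpm=62.9,
        shape=APShapeParams(mdp=-72.0, apa=105.0, dvdt_max=12.0,
                            apd20=100.0, apd50=200.0, apd90=320.0),
    ),
    "father": CohortPreset(
        label="father",
        rate_bpm=17.5,
        shape=APShapeParams(mdp=-66.0, apa=115.0, dvdt_max=10.0,
                            apd20=130.0, apd50=270.0, apd90=430.0),
    ),
    "son": CohortPreset(
        label="son",
        rate_bpm=14.2,
        shape=APShapeParams(mdp=-72.0, apa=115.0, dvdt_max=10.0,
                            apd20=130.0, apd50=270.0, apd90=430.0),
    ),
}

# Relative IBI variability of the presets (fractions of the mean IBI).
SIGMA_SHORT_FRAC = 0.02
SIGMA_LONG_FRAC = 0.04
PHI = 0.8

DAD_SPEC = dict(latency_ms=250.0, amplitude_fraction=0.05, width_ms=60.0)
EAD_SPEC = dict(latency_ms=-150.0, amplitude_fraction=0.06, width_ms=50.0)


def make_recording(
    preset: CohortPreset,
    seed: int,
    duration_s: float = 170.0,
    fs: float = 5000.0,
    dad_beats: Sequence[int] = (),
    ead_beats: Sequence[int] = (),
    noise_sd: Optional[float] = None,
):
    """One synthetic spontaneous recording from a preset, with optional events."""
    mean_ibi = 60.0 / preset.rate_bpm
    n_beats = int(math.floor((duration_s - 2.0 - preset.shape.waveform_span) / mean_ibi))
    ibis = generate_ibi_sequence(
        IBIModelParams(
            mean_ibi=mean_ibi,
            sigma_short=SIGMA_SHORT_FRAC * mean_ibi,
            sigma_long=SIGMA_LONG_FRAC * mean_ibi,
            phi=PHI,
            n_beats=n_beats - 1,
            seed=seed,
        )
    )
    shape = preset.shape
    if noise_sd is not None:
        shape = replace(shape, noise_sd=noise_sd)
    # the AR(1) component makes the beat-time random walk wander; drop
    # trailing beats whose waveform would not fit inside the recording
    acts = 1.0 + np.concatenate([[0.0], np.cumsum(ibis)])
    n_fit = int(np.sum(acts + shape.waveform_span + 0.1 < duration_s))
    ibis = ibis[: max(n_fit - 1, 1)]
    events = [AfterdepSpec(beat_index=b, **DAD_SPEC) for b in dad_beats]
    events += [AfterdepSpec(beat_index=b, **EAD_SPEC) for b in ead_beats]
    return generate_ap_trace(
        shape, ibis, events=events, fs=fs, seed=seed + 1, duration_s=duration_s
    )


def afterdep_cohort_verdicts(
    preset: CohortPreset,
    n_total: int,
    n_dad: int,
    n_ead: int,
    seed: int,
    duration_s: float = 170.0,
    fs: float = 5000.0,
    threshold_fraction: float = 0.03,
    cfg: DetectorConfig = DetectorConfig(),
):
    """Generate a cohort with events injected into a subset, then score it.

    The first ``n_dad`` recordings carry DAD bumps, the next ``n_ead`` carry
    one EAD each, the remainder are event-free.  Returns the verdict list.
    """
    if n_dad + n_ead > n_total:
        raise ValueError("more event-positive recordings than recordings")
    ss = np.random.SeedSequence(seed)
    rec_seeds = [int(s.generate_state(1)[0] % 2**31) for s in ss.spawn(n_total)]
    verdicts = []
    for i in range(n_total):
        dad_beats = (5, 12, 20) if i < n_dad else ()
        ead_beats = (8,) if n_dad <= i < n_dad + n_ead else ()
        trace, _gt = make_recording(
            preset, rec_seeds[i], duration_s=duration_s, fs=fs,
            dad_beats=dad_beats, ead_beats=ead_beats,
        )
        beats = detect_beats(trace, cfg)
        events = detect_afterdepolarizations(trace, beats, threshold_fraction)
        verdicts.append(classify_recording(events, beats, trace))
    return verdicts


def afterdep_incidence_pct(verdicts) -> float:
    """Percent of recordings with any afterdepolarization event."""
    pos = sum(1 for v in verdicts if v.afterdep_positive)
    return 100.0 * pos / len(verdicts)
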