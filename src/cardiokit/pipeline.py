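"""End-to-end orchestration: simulate -> analyze -> summarize.

``run_pipeline`` takes voltage traces (in memory or as files), runs beat
detection, AP feature extraction, afterdepolarization scoring and beat-rate
variability, and returns tidy tables plus a machine-readable manifest.  The
``demo`` scenario generates three preset cohorts (control-like, father-like,
son-like) and runs the full table set on them.
"""

from __future__ import annotations

import json
import platform
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .afterdep import classify_recording, detect_afterdepolarizations, summarize_incidence
from .ap import DetectorConfig, detect_beats, summarize_features
from .brv import brv_metrics, extract_ibis
from .cohorts import COHORT_PRESETS, make_recording
from .io import read_trace, write_trace
from .traces import VoltageTrace

__all__ = ["RunConfig", "ResultsBundle", "run_pipeline", "run_demo"]


@dataclass
class RunConfig:
    """Pipeline settings; defaults follow the analysis protocol windows."""

    seed: int = 0
    fs: float = 5000.0
    detector: DetectorConfig = field(default_factory=DetectorConfig)
    threshold_fraction: float = 0.03   # afterdepolarization cutoff, of APA
    afterdep_window_s: float = 170.0   # event-search span
    brv_window_s: float = 100.0        # beat-rate-variability span
    post_pacing_window_s: float = 20.0
    bin_width_s: float = 0.05
    out_dir: str = "results"
    log_level: str = "INFO"

    def __post_init__(self):
        if self.threshold_fraction <= 0:
            raise ValueError("threshold_fraction must be positive")
        for name in ("afterdep_window_s", "brv_window_s", "post_pacing_window_s",
                     "bin_width_s"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


@dataclass
class ResultsBundle:
    beats: pd.DataFrame
    summaries: pd.DataFrame
    events: pd.DataFrame
    verdicts: pd.DataFrame
    brv: pd.DataFrame
    incidence: pd.DataFrame
    manifest: dict

    def save(self, out_dir) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        for name in ("beats", "summaries", "events", "verdicts", "brv", "incidence"):
            getattr(self, name).to_csv(out / f"{name}.csv", index=False)
        (out / "manifest.json").write_text(json.dumps(self.manifest, indent=1))


_BEAT_COLS = ["recording", "group", "activation_time_s", "peak_time_s", "peak_mv",
              "mdp_pre_mv", "mdp_post_mv", "apa_mv", "dvdt_max_v_per_s",
              "apd20_ms", "apd50_ms", "apd90_ms", "measurable"]
_EVENT_COLS = ["recording", "group", "kind", "time_s", "amplitude_mv",
               "fraction_of_apa", "host_beat"]


def run_pipeline(config: RunConfig, inputs) -> ResultsBundle:
    """Analyze a set of recordings.

    ``inputs`` is a sequence of (recording_id, group, VoltageTrace-or-path).
    Failures in one recording are recorded in the manifest and the run
    continues with the next.
    """
    beat_rows, summary_rows, event_rows, verdict_rows, brv_rows = [], [], [], [], []
    verdicts_by_group: dict[str, list] = {}
    failures = []

    for rec_id, group, item in inputs:
        try:
            trace = item if isinstance(item, VoltageTrace) else read_trace(item)
            win = trace.crop(trace.t0, trace.t0 + config.afterdep_window_s)
            beats = detect_beats(win, config.detector)
            for b in beats:
                beat_rows.append([rec_id, group, b.activation_time, b.peak_time,
                                  b.peak_v, b.mdp_pre, b.mdp_post, b.apa, b.dvdt_max,
                                  b.apd20, b.apd50, b.apd90, b.measurable])
            summary = summarize_features(beats, win.duration)
            summary_rows.append({"recording": rec_id, "group": group,
                                 **asdict(summary)})
            events = detect_afterdepolarizations(win, beats, config.threshold_fraction)
            for e in events:
                event_rows.append([rec_id, group, e.kind, e.time, e.amplitude_mv,
                                   e.fraction_of_apa, e.host_beat])
            verdict = classify_recording(events, beats, win)
            verdicts_by_group.setdefault(group, []).append(verdict)
            verdict_rows.append({
                "recording": rec_id, "group": group,
                "dad_positive": verdict.dad_positive,
                "ead_positive": verdict.ead_positive,
                "afterdep_positive": verdict.afterdep_positive,
                "arrhythmic": verdict.arrhythmic,
                "ceased": verdict.ceased,
                "n_events": len(verdict.events),
            })
            ibis = extract_ibis(beats, config.brv_window_s, source=rec_id)
            if ibis is not None:
                m = brv_metrics(ibis, config.bin_width_s)
                brv_rows.append({"recording": rec_id, "group": group,
                                 "n_ibis": len(ibis), "mean_ibi_s": m.mean_ibi,
                                 "cov_pct": m.cov, "sd1_s": m.sd1, "sd2_s": m.sd2})
        except Exception as exc:  # keep going; report in the manifest
            failures.append({"recording": rec_id, "stage": "analysis",
                             "error": str(exc)})

    incidence_rows = []
    if verdicts_by_group:
        for flag in ("dad_positive", "ead_positive", "afterdep_positive",
                     "arrhythmic", "ceased"):
            for group, (pct, pos, total) in summarize_incidence(
                verdicts_by_group, flag
            ).items():
                incidence_rows.append({"group": group, "flag": flag,
                                       "percent": pct, "positives": pos,
                                       "n": total})

    manifest = {
        "cardiokit_version": __version__,
        "python": platform.python_version(),
        "config": {**asdict(config), "detector": asdict(config.detector)},
        "n_recordings": len(list(verdict_rows)) + len(failures),
        "failures": failures,
    }
    return ResultsBundle(
        beats=pd.DataFrame(beat_rows, columns=_BEAT_COLS),
        summaries=pd.DataFrame(summary_rows),
        events=pd.DataFrame(event_rows, columns=_EVENT_COLS),
        verdicts=pd.DataFrame(verdict_rows, columns=[
            "recording", "group", "dad_positive", "ead_positive",
            "afterdep_positive", "arrhythmic", "ceased", "n_events"]),
        brv=pd.DataFrame(brv_rows, columns=[
            "recording", "group", "n_ibis", "mean_ibi_s", "cov_pct",
            "sd1_s", "sd2_s"]),
        incidence=pd.DataFrame(incidence_rows, columns=[
            "group", "flag", "percent", "positives", "n"]),
        manifest=manifest,
    )


def run_demo(config: RunConfig, n_per_group: int = 3,
             duration_s: float = 170.0, save_traces_to=None) -> ResultsBundle:
    """Generate the three preset cohorts and run the full pipeline on them."""
    ss = np.random.SeedSequence(config.seed)
    inputs = []
    for preset, sub_ss in zip(COHORT_PRESETS.values(), ss.spawn(len(COHORT_PRESETS))):
        seeds = [int(s.generate_state(1)[0] % 2**31) for s in sub_ss.spawn(n_per_group)]
        for i, seed in enumerate(seeds):
            trace, _gt = make_recording(preset, seed, duration_s=duration_s,
                                        fs=config.fs)
            rec_id = f"{preset.label}_{i:02d}"
            trace.meta.update(cell_line=preset.label)
            if save_traces_to is not None:
                out = Path(save_traces_to)
                out.mkdir(parents=True, exist_ok=True)
                write_trace(out / f"{rec_id}.txt", trace)
            inputs.append((rec_id, preset.label, trace))
    return run_pipeline(config, inputs)
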