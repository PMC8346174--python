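"""Beat detection and action-potential feature extraction.

The measured parameter set per beat: maximum diastolic potential (MDP,
pre- and post-upstroke), AP peak, AP amplitude (APA = peak - preceding MDP),
maximal upstroke slope dV/dt_max, and APD20/50/90 — the times from the
maximal-slope instant to the first downward crossing of
peak - (x/100) * APA, with linear interpolation between samples.

Rate-corrected APD90 is provided with the four QT-correction formulas in
their conventional units (RR replaced by 60/BPM):

    Bazett       APD90 / (60/BPM)^(1/2)
    Fridericia   APD90 / (60/BPM)^(1/3)
    Hodges       APD90 + 1.75 * (BPM - 60)          [ms]
    Framingham   APD90 + 0.154 * (1 - 60/BPM)       [computed in s]
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy.signal import find_peaks, savgol_filter

from .traces import VoltageTrace

__all__ = [
    "DetectorConfig",
    "Beat",
    "APFeatureSummary",
    "detect_beats",
    "measure_beat",
    "beat_rate",
    "rate_corrected_apd",
    "summarize_features",
    "CAPD_METHODS",
]

CAPD_METHODS = ("bazett", "fridericia", "hodges", "framingham")


@dataclass(frozen=True)
class DetectorConfig:
    """Upstroke-detector settings.

    dvdt_threshold       smoothed-derivative threshold for an upstroke, V/s
    refractory_s         minimum spacing between detected upstrokes, s
    smoothing_window_ms  Savitzky-Golay window for the derivative, ms
    min_rise_mv          minimum voltage excursion around the upstroke; this
                         amplitude gate rejects derivative noise and
                         afterdepolarization bumps as beat candidates, mV
    """

    dvdt_threshold: float = 2.0
    refractory_s: float = 0.25
    smoothing_window_ms: float = 1.0
    min_rise_mv: float = 20.0

    def __post_init__(self):
        if self.dvdt_threshold <= 0:
            raise ValueError("dvdt_threshold must be positive")
        if self.refractory_s <= 0:
            raise ValueError("refractory_s must be positive")
        if self.smoothing_window_ms <= 0:
            raise ValueError("smoothing_window_ms must be positive")


@dataclass
class Beat:
    """Per-beat landmarks and measurements (times absolute, durations ms)."""

    activation_time: float
    peak_time: float
    peak_v: float
    mdp_pre: float
    mdp_post: float
    apa: float
    dvdt_max: float
    apd20: Optional[float]
    apd50: Optional[float]
    apd90: Optional[float]
    repol90_time: Optional[float]
    measurable: bool = True


@dataclass
class APFeatureSummary:
    """Per-recording means of the beat parameters plus the four cAPD90s."""

    n_beats: int
    beat_rate: Optional[float]
    mdp: Optional[float] = None
    dvdt_max: Optional[float] = None
    apa: Optional[float] = None
    peak: Optional[float] = None
    apd20: Optional[float] = None
    apd50: Optional[float] = None
    apd90: Optional[float] = None
    capd90_bazett: Optional[float] = None
    capd90_fridericia: Optional[float] = None
    capd90_hodges: Optional[float] = None
    capd90_framingham: Optional[float] = None


def _odd_window(ms: float, fs: float) -> int:
    w = max(int(round(ms * 1e-3 * fs)), 3)
    return w + 1 if w % 2 == 0 else w


def smoothed_derivative(trace: VoltageTrace, window_ms: float) -> np.ndarray:
    """Savitzky-Golay first derivative of the voltage, V/s."""
    w = _odd_window(window_ms, trace.fs)
    if trace.n <= w:
        return np.zeros(trace.n)
    # mV/s -> V/s
    return savgol_filter(trace.v, w, polyorder=2, deriv=1, delta=trace.dt) / 1e3


def _refine_extremum(y: np.ndarray, i: int) -> float:
    """Sub-sample position of a local extremum by quadratic interpolation."""
    if 0 < i < y.size - 1:
        denom = y[i - 1] - 2 * y[i] + y[i + 1]
        if denom != 0:
            return i + 0.5 * (y[i - 1] - y[i + 1]) / denom
    return float(i)


def detect_beats(trace: VoltageTrace, cfg: DetectorConfig = DetectorConfig()) -> list[Beat]:
    """Detect upstrokes and measure each complete beat.

    Upstrokes are maxima of the smoothed derivative above ``dvdt_threshold``
    separated by at least ``refractory_s``, gated on a minimum voltage rise.
    Beats without both bounding diastolic minima (the first and last upstroke
    of a recording) are dropped.  Returns an empty list when nothing fires.
    """
    if trace.n == 0 or trace.duration < 2.0:
        return []
    dvdt = smoothed_derivative(trace, cfg.smoothing_window_ms)
    distance = max(int(round(cfg.refractory_s * trace.fs)), 1)
    idx, _ = find_peaks(dvdt, height=cfg.dvdt_threshold, distance=distance)
    if idx.size == 0:
        return []

    # amplitude gate: a genuine upstroke RISES by tens of mV within ~50 ms;
    # directional (after-max minus before-min) so that derivative noise on the
    # falling repolarization cannot masquerade as an upstroke
    half = int(round(0.05 * trace.fs))
    keep = []
    for i in idx:
        lo = max(i - half, 0)
        hi = min(i + half + 1, trace.n)
        if trace.v[i:hi].max() - trace.v[lo : i + 1].min() >= cfg.min_rise_mv:
            keep.append(i)
    idx = np.asarray(keep, dtype=int)
    if idx.size < 3:
        return []  # need interior beats with both bounding minima

    beats = []
    for j in range(1, idx.size - 1):
        i_prev, i_cur, i_next = idx[j - 1], idx[j], idx[j + 1]
        beat = _measure(trace, dvdt, i_prev, i_cur, i_next)
        beats.append(beat)
    return beats


def _measure(
    trace: VoltageTrace,
    dvdt: np.ndarray,
    i_prev: int,
    i_cur: int,
    i_next: int,
) -> Beat:
    v = trace.v
    fs = trace.fs
    t0 = trace.t0

    act_i = _refine_extremum(dvdt, i_cur)
    activation = t0 + act_i / fs
    dvdt_max = float(dvdt[i_cur])

    i_peak = i_cur + int(np.argmax(v[i_cur:i_next]))
    peak_v = float(v[i_peak])
    peak_time = t0 + i_peak / fs

    mdp_pre = float(np.min(v[i_prev:i_cur]))
    mdp_post = float(np.min(v[i_cur:i_next]))
    apa = peak_v - mdp_pre

    apds = {}
    repol90_time = None
    measurable = True
    seg = v[i_peak:i_next]
    for pct in (20, 50, 90):
        level = peak_v - pct / 100.0 * apa
        below = np.nonzero(seg < level)[0]
        if below.size == 0:
            apds[pct] = None
            measurable = False
            continue
        k = int(below[0])
        if k == 0:
            cross = float(i_peak)
        else:
            v1, v2 = seg[k - 1], seg[k]
            frac = (v1 - level) / (v1 - v2)
            cross = i_peak + k - 1 + frac
        t_cross = t0 + cross / fs
        apds[pct] = (t_cross - activation) * 1e3
        if pct == 90:
            repol90_time = t_cross

    return Beat(
        activation_time=activation,
        peak_time=peak_time,
        peak_v=peak_v,
        mdp_pre=mdp_pre,
        mdp_post=mdp_post,
        apa=apa,
        dvdt_max=dvdt_max,
        apd20=apds[20],
        apd50=apds[50],
        apd90=apds[90],
        repol90_time=repol90_time,
        measurable=measurable,
    )


def measure_beat(trace: VoltageTrace, beat_window: tuple,
                 cfg: DetectorConfig = DetectorConfig()) -> Beat:
    """Measure a single beat inside a window known to contain one upstroke.

    The window must include both bounding diastolic minima; a beat whose
    repolarization never reaches the 90% level is flagged unmeasurable.
    """
    sub = trace.crop(*beat_window)
    dvdt = smoothed_derivative(sub, cfg.smoothing_window_ms)
    i_cur = int(np.argmax(dvdt))
    if dvdt[i_cur] < cfg.dvdt_threshold:
        raise ValueError("no upstroke found in the requested window")
    return _measure(sub, dvdt, 0, i_cur, sub.n)


def activation_times(beats: Sequence[Beat]) -> np.ndarray:
    return np.asarray([b.activation_time for b in beats], dtype=float)


def beat_rate(beats, duration_s: Optional[float] = None) -> Optional[float]:
    """Mean firing rate (beats/min) from complete inter-beat intervals.

    ``beats`` is a Beat sequence or an array of activation times.  With fewer
    than two beats the rate is undefined and None is returned.
    """
    if len(beats) and isinstance(beats[0], Beat):
        acts = activation_times(beats)
    else:
        acts = np.asarray(beats, dtype=float)
    if duration_s is not None and duration_s <= 0:
        raise ValueError("duration_s must be positive")
    if acts.size < 2:
        return None
    ibis = np.diff(acts)
    return float(ibis.size / ibis.sum() * 60.0)


def rate_corrected_apd(apd90_ms: float, bpm: float, method: str) -> float:
    """Rate-corrected APD90 (ms) by one of the four QT-correction formulas."""
    if bpm <= 0:
        raise ValueError("bpm must be positive")
    if apd90_ms <= 0:
        raise ValueError("apd90_ms must be positive")
    rr = 60.0 / bpm  # s
    if method == "bazett":
        return apd90_ms / rr ** 0.5
    if method == "fridericia":
        return apd90_ms / rr ** (1.0 / 3.0)
    if method == "hodges":
        return apd90_ms + 1.75 * (bpm - 60.0)
    if method == "framingham":
        # additive term is defined in seconds; converted to ms on its own so
        # the correction is exactly zero at 60 bpm
        return apd90_ms + 0.154 * (1.0 - rr) * 1e3
    raise ValueError(f"unknown rate-correction method {method!r}; "
                     f"expected one of {CAPD_METHODS}")


def summarize_features(beats: Sequence[Beat],
                       duration_s: Optional[float] = None) -> APFeatureSummary:
    """Per-recording means over measurable beats plus the cAPD90 variants.

    Beats with interrupted repolarization are excluded from the APD means but
    still count toward the firing rate.
    """
    n = len(beats)
    rate = beat_rate(beats, duration_s) if n else None
    if n == 0:
        return APFeatureSummary(n_beats=0, beat_rate=None)

    def mean_of(attr, only_measurable=False):
        vals = [
            getattr(b, attr)
            for b in beats
            if (b.measurable or not only_measurable) and getattr(b, attr) is not None
        ]
        return float(np.mean(vals)) if vals else None

    summary = APFeatureSummary(
        n_beats=n,
        beat_rate=rate,
        mdp=mean_of("mdp_pre"),
        dvdt_max=mean_of("dvdt_max"),
        apa=mean_of("apa"),
        peak=mean_of("peak_v"),
        apd20=mean_of("apd20", only_measurable=True),
        apd50=mean_of("apd50", only_measurable=True),
        apd90=mean_of("apd90", only_measurable=True),
    )
    if summary.apd90 is not None and rate is not None:
        summary.capd90_bazett = rate_corrected_apd(summary.apd90, rate, "bazett")
        summary.capd90_fridericia = rate_corrected_apd(summary.apd90, rate, "fridericia")
        summary.capd90_hodges = rate_corrected_apd(summary.apd90, rate, "hodges")
        summary.capd90_framingham = rate_corrected_apd(summary.apd90, rate, "framingham")
    return summary
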