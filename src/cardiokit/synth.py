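"""Synthetic cardiomyocyte recordings with exact ground truth.

Every downstream analysis stage (beat detection, APD measurement,
afterdepolarization scoring, beat-rate variability, voltage-clamp I-V curves,
caffeine response) is exercised against traces produced here, so each
generated quantity must be recoverable in closed form.

The action-potential waveform is deliberately phenomenological rather than an
ionic ODE model: a half-cosine upstroke whose maximal slope is exactly
``dvdt_max``, a piecewise-exponential repolarization whose level crossings hit
the APD20/50/90 targets exactly, an exponential diastolic depolarization from
the maximum diastolic potential (MDP) toward the next take-off, and optional
raised-cosine afterdepolarization bumps.  Additive noise is white Gaussian.

Inter-beat intervals follow an AR(1)-plus-white model so that the Poincare
descriptors SD1 (short-term) and SD2 (long-term variability) have analytic
expectations.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np

from .traces import CaTrace, VoltageTrace

__all__ = [
    "APShapeParams",
    "IBIModelParams",
    "AfterdepSpec",
    "ClampSimParams",
    "ClampStepRecording",
    "CaSimParams",
    "GroundTruth",
    "InjectedEvent",
    "IsoSegment",
    "IsoproterenolScenario",
    "TrainsScenario",
    "generate_ibi_sequence",
    "generate_ap_trace",
    "generate_intervention_session",
    "generate_clamp_family",
    "generate_ca_trace",
    "default_if_params",
    "default_ical_params",
    "IF_STEPS",
    "ICAL_STEPS",
    "if_steady_state_current",
    "ical_peak_current",
    "CaGroundTruth",
]

# Fraction of APA reached by the diastolic depolarization at upstroke take-off.
TAKEOFF_FRACTION = 0.08
# The post-APD90 repolarization tail never decays slower than this (s); it must
# reach the diastolic baseline well before the next beat so that the measured
# MDP equals the ground-truth value.
TAIL_TAU_MAX_S = 0.020
# Number of tail time constants allowed before the diastolic rise starts.
TAIL_SPAN = 8.0


def _require_finite(name: str, value: float) -> None:
    if not np.isfinite(value):
        raise ValueError(f"{name} must be finite, got {value!r}")


# ---------------------------------------------------------------------------
# parameter containers
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class APShapeParams:
    """Ground-truth morphology of a spontaneous action potential.

    mdp            maximum diastolic potential, mV (< 0)
    apa            action-potential amplitude (peak - MDP), mV
    dvdt_max       maximal upstroke slope, V/s
    apd20/50/90    durations at 20/50/90 % repolarization, ms, measured from
                   the instant of maximal upstroke slope
    diastolic_tau  time constant of the exponential diastolic depolarization, s
    noise_sd       additive white-noise standard deviation, mV
    """

    mdp: float = -70.0
    apa: float = 110.0
    dvdt_max: float = 10.0
    apd20: float = 120.0
    apd50: float = 250.0
    apd90: float = 400.0
    diastolic_tau: float = 0.8
    noise_sd: float = 0.5

    def __post_init__(self):
        for name in ("mdp", "apa", "dvdt_max", "apd20", "apd50", "apd90",
                     "diastolic_tau", "noise_sd"):
            _require_finite(name, getattr(self, name))
        if not (self.apd20 < self.apd50 < self.apd90):
            raise ValueError("APD ordering must satisfy apd20 < apd50 < apd90")
        if self.apa <= 0:
            raise ValueError("apa must be positive")
        if self.mdp >= 0:
            raise ValueError("mdp must be negative")
        if self.dvdt_max <= 0:
            raise ValueError("dvdt_max must be positive")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        if self.diastolic_tau <= 0:
            raise ValueError("diastolic_tau must be positive")
        if self.apd20 / 1000.0 <= self.upstroke_duration / 2:
            raise ValueError(
                "apd20 shorter than half the upstroke; increase dvdt_max or apd20"
            )

    @property
    def peak_v(self) -> float:
        return self.mdp + self.apa

    @property
    def takeoff_amp(self) -> float:
        """Diastolic-depolarization amplitude above MDP at take-off, mV."""
        return TAKEOFF_FRACTION * self.apa

    @property
    def upstroke_duration(self) -> float:
        """Half-cosine upstroke duration (s) whose peak slope is dvdt_max."""
        rise_mv = self.apa - self.takeoff_amp
        return rise_mv * math.pi / (2.0 * self.dvdt_max * 1000.0)

    def repol_taus(self):
        """Per-segment exponential time constants hitting the APD targets."""
        tu2 = self.upstroke_duration / 2
        d20, d50, d90 = (self.apd20 / 1e3, self.apd50 / 1e3, self.apd90 / 1e3)
        tau1 = (d20 - tu2) / math.log(1 / 0.8)
        tau2 = (d50 - d20) / math.log(0.8 / 0.5)
        tau3 = (d90 - d50) / math.log(0.5 / 0.1)
        tau_tail = min(tau3, TAIL_TAU_MAX_S)
        return tau1, tau2, tau3, tau_tail

    @property
    def waveform_span(self) -> float:
        """Time (s) from activation until the waveform returns to the MDP."""
        return self.apd90 / 1e3 + TAIL_SPAN * self.repol_taus()[3]


@dataclass(frozen=True)
class IBIModelParams:
    """AR(1)-plus-white inter-beat-interval model.

    IBI_n = mean_ibi + L_n + W_n with L_n = phi * L_{n-1} + eps_n,
    eps_n ~ N(0, sigma_long^2 * (1 - phi^2)), L_0 = 0, and
    W_n ~ N(0, sigma_short^2).  Values are clipped below at 0.2 * mean_ibi.
    """

    mean_ibi: float
    sigma_short: float = 0.0
    sigma_long: float = 0.0
    phi: float = 0.0
    n_beats: int = 100
    seed: Optional[int] = None

    def __post_init__(self):
        for name in ("mean_ibi", "sigma_short", "sigma_long", "phi"):
            _require_finite(name, getattr(self, name))
        if self.mean_ibi <= 0:
            raise ValueError("mean_ibi must be positive")
        if not (0 <= self.phi < 1):
            raise ValueError("phi must lie in [0, 1)")
        if self.sigma_short < 0 or self.sigma_long < 0:
            raise ValueError("sigma_short and sigma_long must be non-negative")
        if self.n_beats < 1:
            raise ValueError("n_beats must be at least 1")


@dataclass(frozen=True)
class AfterdepSpec:
    """An afterdepolarization bump to inject.

    latency_ms is measured from the host beat's 90%-repolarization crossing to
    the bump centre: positive latencies place the bump on the diastolic
    baseline (a DAD), negative latencies place it on phase-3 repolarization
    before the crossing (an EAD).  The bump is a raised cosine of height
    amplitude_fraction * APA and total width width_ms.
    """

    beat_index: int
    latency_ms: float
    amplitude_fraction: float
    width_ms: float = 60.0

    def __post_init__(self):
        if self.amplitude_fraction <= 0:
            raise ValueError("amplitude_fraction must be positive")
        if self.width_ms <= 0:
            raise ValueError("width_ms must be positive")

    @property
    def kind(self) -> str:
        return "DAD" if self.latency_ms > 0 else "EAD"


@dataclass(frozen=True)
class InjectedEvent:
    """A realized afterdepolarization: its spec plus absolute peak time."""

    spec: AfterdepSpec
    time: float
    kind: str


@dataclass
class GroundTruth:
    """Everything the generator knows about a trace, for recovery tests."""

    beat_times: np.ndarray
    shapes: list
    events: list = field(default_factory=list)
    cessation_intervals: list = field(default_factory=list)
    segments: list = field(default_factory=list)  # (label, t0, t1, rate_bpm)
    stim_trains: list = field(default_factory=list)  # (freq_hz, stim_times)
    fs: float = 0.0
    duration: float = 0.0

    def __post_init__(self):
        bt = np.asarray(self.beat_times, dtype=float)
        if bt.size > 1 and np.any(np.diff(bt) <= 0):
            raise ValueError("beat_times must be strictly increasing")
        self.beat_times = bt
        n = bt.size
        for ev in self.events:
            if not (0 <= ev.spec.beat_index < n):
                raise ValueError("injected event references a missing beat")


# ---------------------------------------------------------------------------
# inter-beat intervals
# ---------------------------------------------------------------------------


def generate_ibi_sequence(params: IBIModelParams) -> np.ndarray:
    """Draw an inter-beat-interval series from the AR(1)+white model."""
    rng = np.random.default_rng(params.seed)
    n = params.n_beats
    eps_sd = params.sigma_long * math.sqrt(1.0 - params.phi**2)
    eps = rng.normal(0.0, eps_sd, n) if eps_sd > 0 else np.zeros(n)
    long_comp = np.empty(n)
    prev = 0.0  # L_0 = 0
    for i in range(n):
        prev = params.phi * prev + eps[i]
        long_comp[i] = prev
    white = rng.normal(0.0, params.sigma_short, n) if params.sigma_short > 0 else np.zeros(n)
    ibis = params.mean_ibi + long_comp + white
    return np.maximum(ibis, 0.2 * params.mean_ibi)


# ---------------------------------------------------------------------------
# voltage-trace assembly
# ---------------------------------------------------------------------------


def _event_absolute(spec: AfterdepSpec, activation: float, shape: APShapeParams) -> float:
    """Absolute time of a bump centre given its host beat."""
    repol90 = activation + shape.apd90 / 1e3
    return repol90 + spec.latency_ms / 1e3


def _render(
    acts: np.ndarray,
    shapes: Sequence[APShapeParams],
    events: Sequence[AfterdepSpec],
    fs: float,
    duration: float,
    rng: Optional[np.random.Generator],
) -> tuple[np.ndarray, list]:
    """Assemble the voltage array; returns (v, realized events)."""
    mdp = shapes[0].mdp
    if any(s.mdp != mdp for s in shapes):
        raise ValueError("all beats within one trace must share the same MDP")
    n = int(round(duration * fs))
    v = np.full(n, mdp, dtype=float)
    dt = 1.0 / fs

    def sl(t_a: float, t_b: float):
        """Sample indices covering [t_a, t_b) with their times."""
        i0 = max(int(math.ceil(t_a * fs - 1e-9)), 0)
        i1 = min(int(math.ceil(t_b * fs - 1e-9)), n)
        return i0, i1, np.arange(i0, i1) / fs

    for k, a in enumerate(acts):
        s = shapes[k]
        tu = s.upstroke_duration
        dd = s.takeoff_amp
        t_on, t_pk = a - tu / 2, a + tu / 2
        if t_on < 0 or t_pk > duration:
            raise ValueError(f"beat {k} does not fit inside the trace")

        # upstroke: half-cosine from the take-off level to the peak
        i0, i1, tt = sl(t_on, t_pk)
        v[i0:i1] = (
            mdp + dd + (s.apa - dd) * 0.5 * (1.0 - np.cos(np.pi * (tt - t_on) / tu))
        )

        # repolarization: exponential segments pinned to the APD targets
        tau1, tau2, tau3, tau_tail = s.repol_taus()
        t20 = a + s.apd20 / 1e3
        t50 = a + s.apd50 / 1e3
        t90 = a + s.apd90 / 1e3
        t_dia = t90 + TAIL_SPAN * tau_tail
        next_on = (
            acts[k + 1] - shapes[k + 1].upstroke_duration / 2
            if k + 1 < len(acts)
            else duration
        )
        if t_dia >= next_on - dt:
            raise ValueError(
                f"beat {k}: repolarization (ends {t_dia:.3f}s) overlaps the next "
                f"upstroke at {next_on:.3f}s; shorten the APDs or slow the rate"
            )
        for t_a, t_b, f_start, tau in (
            (t_pk, t20, 1.0, tau1),
            (t20, t50, 0.8, tau2),
            (t50, t90, 0.5, tau3),
            (t90, min(t_dia, duration), 0.1, tau_tail),
        ):
            i0, i1, tt = sl(t_a, t_b)
            v[i0:i1] = mdp + s.apa * f_start * np.exp(-(tt - t_a) / tau)

        # diastolic depolarization toward the next take-off
        if k + 1 < len(acts):
            dd_next = shapes[k + 1].takeoff_amp
            tau_d = shapes[k + 1].diastolic_tau
            i0, i1, tt = sl(t_dia, next_on)
            if i1 > i0:
                num = np.exp((tt - next_on) / tau_d) - math.exp((t_dia - next_on) / tau_d)
                den = 1.0 - math.exp((t_dia - next_on) / tau_d)
                v[i0:i1] = mdp + dd_next * num / den

    realized = []
    for ev in events:
        if not (0 <= ev.beat_index < len(acts)):
            raise ValueError(f"event references beat {ev.beat_index}, which does not exist")
        a = acts[ev.beat_index]
        s = shapes[ev.beat_index]
        t_c = _event_absolute(ev, a, s)
        w = ev.width_ms / 1e3
        repol90 = a + s.apd90 / 1e3
        next_on = (
            acts[ev.beat_index + 1] - shapes[ev.beat_index + 1].upstroke_duration / 2
            if ev.beat_index + 1 < len(acts)
            else duration
        )
        if ev.latency_ms > 0:  # DAD on the diastolic baseline
            if t_c - w / 2 < repol90:
                raise ValueError(
                    f"DAD on beat {ev.beat_index}: bump (centre {t_c:.3f}s, width "
                    f"{ev.width_ms}ms) starts before repolarization completes; "
                    "increase latency_ms"
                )
            if t_c + w / 2 >= next_on - 2 * dt:
                raise ValueError(
                    f"DAD on beat {ev.beat_index}: bump would overlap the next "
                    f"upstroke at {next_on:.3f}s; reduce latency_ms or width_ms"
                )
        else:  # EAD on phase-3 repolarization
            if t_c + w / 2 > repol90:
                raise ValueError(
                    f"EAD on beat {ev.beat_index}: bump must end before the "
                    "90%-repolarization crossing; make latency_ms more negative"
                )
            if t_c - w / 2 <= a + s.upstroke_duration / 2:
                raise ValueError(
                    f"EAD on beat {ev.beat_index}: bump overlaps the AP upstroke"
                )
        i0, i1, tt = sl(t_c - w / 2, t_c + w / 2)
        h = ev.amplitude_fraction * s.apa
        v[i0:i1] += h * 0.5 * (1.0 + np.cos(2.0 * np.pi * (tt - t_c) / w))
        realized.append(InjectedEvent(spec=ev, time=t_c, kind=ev.kind))

    noise_sd = shapes[0].noise_sd
    if noise_sd > 0:
        if rng is None:
            rng = np.random.default_rng()
        v += rng.normal(0.0, noise_sd, n)
    return v, realized


def generate_ap_trace(
    shape: APShapeParams,
    ibis,
    events: Sequence[AfterdepSpec] = (),
    fs: float = 5000.0,
    seed: Optional[int] = None,
    start_offset: float = 1.0,
    duration_s: Optional[float] = None,
    shapes: Optional[Sequence[APShapeParams]] = None,
) -> tuple[VoltageTrace, GroundTruth]:
    """Render a spontaneous-AP recording from IBIs and optional events.

    ``ibis`` supplies the n-1 intervals between the n beats; the first beat
    fires at ``start_offset``.  ``shapes`` optionally overrides the morphology
    per beat (all sharing the same MDP).  Noise is drawn from ``seed``.
    """
    if fs < 1000.0:
        raise ValueError("fs must be at least 1000 Hz")
    ibis = np.asarray(ibis, dtype=float)
    if ibis.size and (not np.all(np.isfinite(ibis)) or np.any(ibis <= 0)):
        raise ValueError("IBIs must be finite and positive")
    acts = start_offset + np.concatenate([[0.0], np.cumsum(ibis)])
    beat_shapes = list(shapes) if shapes is not None else [shape] * acts.size
    if len(beat_shapes) != acts.size:
        raise ValueError("shapes must supply one entry per beat")
    if duration_s is None:
        duration_s = acts[-1] + beat_shapes[-1].waveform_span + 1.0
    if acts[-1] + beat_shapes[-1].waveform_span >= duration_s:
        raise ValueError("duration_s too short for the requested beats")
    rng = np.random.default_rng(seed)
    v, realized = _render(acts, beat_shapes, events, fs, duration_s, rng)
    trace = VoltageTrace(v=v, fs=fs, meta={"kind": "voltage"})
    gt = GroundTruth(
        beat_times=acts, shapes=beat_shapes, events=realized, fs=fs, duration=duration_s
    )
    return trace, gt


# ---------------------------------------------------------------------------
# intervention sessions: isoproterenol ramps and pacing trains
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class IsoSegment:
    """One drug concentration: the beat rate is baseline * multiplier."""

    label: str
    multiplier: float = 1.0
    duration_s: float = 60.0
    events: tuple = ()  # AfterdepSpec with beat_index local to the segment
    cease: bool = False

    def __post_init__(self):
        if self.multiplier <= 0:
            raise ValueError("rate multiplier must be positive")
        if self.duration_s <= 0:
            raise ValueError("segment duration must be positive")


@dataclass(frozen=True)
class IsoproterenolScenario:
    """Concatenated constant-rate segments; the first is the baseline."""

    segments: tuple

    def __post_init__(self):
        if len(self.segments) < 2:
            raise ValueError("need a baseline plus at least one drug segment")


@dataclass(frozen=True)
class TrainsScenario:
    """Pacing trains at increasing frequency, each followed by a pause.

    During each pause the cell resumes spontaneous firing at the base rate;
    afterdepolarizations may be injected onto those spontaneous beats via
    ``window_events`` (freq -> list of (beat_in_window, AfterdepSpec fields)),
    and ``ceased_windows`` suppresses spontaneous firing in a pause entirely.
    """

    frequencies: tuple = (0.5, 1.0, 1.5, 2.0)
    n_stimuli: int = 20
    pause_s: float = 20.0
    paced_shape: Optional[APShapeParams] = None
    window_events: dict = field(default_factory=dict)
    ceased_windows: tuple = ()

    def __post_init__(self):
        if self.n_stimuli < 1:
            raise ValueError("n_stimuli must be at least 1")
        if self.pause_s <= 0:
            raise ValueError("pause_s must be positive")


def _default_paced_shape(shape: APShapeParams, max_freq: float) -> APShapeParams:
    """Shorten the APDs so paced beats fit the fastest stimulation period."""
    period = 1.0 / max_freq
    scale = min(1.0, 0.55 * period / (shape.apd90 / 1e3))
    if scale >= 1.0:
        return shape
    return replace(
        shape,
        apd20=shape.apd20 * scale,
        apd50=shape.apd50 * scale,
        apd90=shape.apd90 * scale,
    )


def generate_intervention_session(
    shape: APShapeParams,
    base_ibis,
    scenario,
    fs: float = 5000.0,
    seed: Optional[int] = None,
) -> tuple[VoltageTrace, GroundTruth]:
    """Render an isoproterenol ramp or a pacing-train session.

    ``base_ibis`` is the spontaneous IBI pool (cycled as needed); its mean
    defines the baseline rate.
    """
    base_ibis = np.asarray(base_ibis, dtype=float)
    if base_ibis.size == 0 or np.any(base_ibis <= 0):
        raise ValueError("base_ibis must be a non-empty positive array")
    base_mean = float(np.mean(base_ibis))
    rng = np.random.default_rng(seed)

    if isinstance(scenario, IsoproterenolScenario):
        acts: list[float] = []
        shapes: list[APShapeParams] = []
        events: list[AfterdepSpec] = []
        segments = []
        cessation = []
        t_cursor = 0.5
        pool_i = 0
        for seg in scenario.segments:
            seg_start, seg_end = t_cursor, t_cursor + seg.duration_s
            seg_first_beat = len(acts)
            if not seg.cease:
                t_next = seg_start + base_ibis[pool_i % base_ibis.size] / seg.multiplier
                while t_next + shape.waveform_span + 0.2 < seg_end:
                    acts.append(t_next)
                    shapes.append(shape)
                    pool_i += 1
                    t_next += base_ibis[pool_i % base_ibis.size] / seg.multiplier
            else:
                cessation.append((seg_start, seg_end))
            for ev in seg.events:
                events.append(replace(ev, beat_index=ev.beat_index + seg_first_beat))
            segments.append(
                (seg.label, seg_start, seg_end, seg.multiplier * 60.0 / base_mean)
            )
            t_cursor = seg_end
        duration = t_cursor + 0.5
        acts_arr = np.asarray(acts)
        v, realized = _render(acts_arr, shapes, events, fs, duration, rng)
        trace = VoltageTrace(v=v, fs=fs, meta={"kind": "voltage", "protocol": "isoproterenol"})
        gt = GroundTruth(
            beat_times=acts_arr,
            shapes=shapes,
            events=realized,
            cessation_intervals=cessation,
            segments=segments,
            fs=fs,
            duration=duration,
        )
        return trace, gt

    if isinstance(scenario, TrainsScenario):
        paced_shape = scenario.paced_shape or _default_paced_shape(
            shape, max(scenario.frequencies)
        )
        stim_latency = 0.012  # electrical stimulus to upstroke, s
        acts = []
        shapes = []
        events = []
        segments = []
        cessation = []
        stim_trains = []
        t_cursor = 1.0
        for freq in scenario.frequencies:
            stims = t_cursor + np.arange(scenario.n_stimuli) / freq
            stim_trains.append((freq, stims))
            segments.append((f"train_{freq:g}Hz", stims[0], stims[-1], freq * 60.0))
            first_paced = len(acts)
            for st in stims:
                acts.append(st + stim_latency)
                shapes.append(paced_shape)
            window_start = stims[-1]
            window_end = stims[-1] + scenario.pause_s
            segments.append((f"post_{freq:g}Hz", window_start, window_end, np.nan))
            if freq in scenario.ceased_windows:
                cessation.append((window_start, window_end))
            else:
                first_window_beat = len(acts)
                t_next = acts[-1] + base_mean
                while t_next + shape.waveform_span + 0.5 < window_end:
                    acts.append(t_next)
                    shapes.append(shape)
                    t_next += base_mean
                for beat_in_window, ev in scenario.window_events.get(freq, ()):
                    events.append(
                        replace(ev, beat_index=first_window_beat + beat_in_window)
                    )
            t_cursor = window_end
        duration = t_cursor + 0.5
        acts_arr = np.asarray(acts)
        v, realized = _render(acts_arr, shapes, events, fs, duration, rng)
        trace = VoltageTrace(v=v, fs=fs, meta={"kind": "voltage", "protocol": "trains"})
        gt = GroundTruth(
            beat_times=acts_arr,
            shapes=shapes,
            events=realized,
            cessation_intervals=cessation,
            segments=segments,
            stim_trains=stim_trains,
            fs=fs,
            duration=duration,
        )
        return trace, gt

    raise TypeError("scenario must be an IsoproterenolScenario or TrainsScenario")


# ---------------------------------------------------------------------------
# voltage-clamp step families
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ClampSimParams:
    """Phenomenological whole-cell current model for step protocols.

    The activation gate is a Boltzmann a(V) = 1 / (1 + exp((V - vhalf)/slope));
    a positive slope yields activation on hyperpolarization (HCN-like I_f), a
    negative slope activation on depolarization (L-type Ca2+).  Currents are
    in pA (nS * mV), normalized downstream by the membrane capacitance cm.
    """

    gmax: float = 5.0
    vhalf: float = -90.0
    slope: float = 10.0
    erev: float = -20.0
    tau_act: float = 0.3
    cm: float = 20.0
    leak_g: float = 0.0
    tau_inact: float = 0.04  # L-type only
    f_half: float = 40.0     # L-type inactivation gate midpoint, mV
    f_slope: float = 10.0

    def __post_init__(self):
        if self.slope == 0:
            raise ValueError("slope must be non-zero")
        if self.cm <= 0:
            raise ValueError("cm must be positive")
        if self.gmax < 0:
            raise ValueError("gmax must be non-negative")
        if self.tau_act <= 0 or self.tau_inact <= 0:
            raise ValueError("time constants must be positive")


def default_if_params(**overrides) -> ClampSimParams:
    """HCN-like pacemaker-current defaults (activates on hyperpolarization)."""
    base = dict(gmax=5.0, vhalf=-90.0, slope=10.0, erev=-20.0, tau_act=0.3,
                cm=20.0, leak_g=0.0)
    base.update(overrides)
    return ClampSimParams(**base)


def default_ical_params(**overrides) -> ClampSimParams:
    """L-type Ca2+ current defaults (bell-shaped peak I-V)."""
    base = dict(gmax=3.0, vhalf=-10.0, slope=-6.0, erev=60.0, tau_act=0.002,
                cm=20.0, leak_g=0.0, tau_inact=0.04, f_half=40.0, f_slope=10.0)
    base.update(overrides)
    return ClampSimParams(**base)


IF_STEPS = tuple(range(-120, -39, 10))       # holding -40 mV, 2-s pulses
ICAL_STEPS = tuple(range(-40, 51, 10))       # holding -70 mV, 200-ms steps
IF_HOLD = -40.0
ICAL_HOLD = -70.0


def boltzmann(v, vhalf, slope):
    return 1.0 / (1.0 + np.exp((np.asarray(v, dtype=float) - vhalf) / slope))


def if_steady_state_current(params: ClampSimParams, v) -> np.ndarray:
    """Closed-form steady-state pulse current (pA), leak referenced to holding."""
    v = np.asarray(v, dtype=float)
    gated = params.gmax * boltzmann(v, params.vhalf, params.slope) * (v - params.erev)
    return gated + params.leak_g * (v - IF_HOLD)


def ical_peak_current(params: ClampSimParams, v) -> np.ndarray:
    """Closed-form peak step current (pA) of the bell-shaped L-type I(V)."""
    v = np.asarray(v, dtype=float)
    d_inf = boltzmann(v, params.vhalf, params.slope)
    f_inf = boltzmann(v, params.f_half, params.f_slope)
    return params.gmax * d_inf * f_inf * (v - params.erev)


@dataclass
class ClampStepRecording:
    """One voltage step: current trace (pA), timing windows and capacitance."""

    step_v: float
    current: np.ndarray
    fs: float
    t_step: tuple  # (start, end) of the test pulse, s
    pre_step_baseline_window: tuple
    cm: float
    protocol: str  # 'if' | 'ical'

    def __post_init__(self):
        self.current = np.asarray(self.current, dtype=float)
        if not np.all(np.isfinite(self.current)):
            raise ValueError("current trace contains non-finite values")
        if self.cm <= 0:
            raise ValueError("cm must be positive")
        if self.protocol not in ("if", "ical"):
            raise ValueError("protocol must be 'if' or 'ical'")


def generate_clamp_family(
    params: ClampSimParams,
    protocol: str,
    steps: Optional[Sequence[float]] = None,
    fs: float = 5000.0,
) -> list[ClampStepRecording]:
    """Simulate a full step family for the I_f or I_Ca,L protocol."""
    if protocol == "if":
        steps = tuple(steps) if steps is not None else IF_STEPS
        if len(steps) == 0:
            raise ValueError("step list must not be empty")
        pre, pulse, post = 0.5, 2.0, 0.3
        recs = []
        for v_step in steps:
            n = int(round((pre + pulse + post) * fs))
            t = np.arange(n) / fs
            i = np.zeros(n)
            in_pulse = (t >= pre) & (t < pre + pulse)
            tp = t[in_pulse] - pre
            i_ss = if_steady_state_current(params, v_step)
            leak = params.leak_g * (v_step - IF_HOLD)
            gated_ss = i_ss - leak
            i[in_pulse] = leak + gated_ss * (1.0 - np.exp(-tp / params.tau_act))
            recs.append(
                ClampStepRecording(
                    step_v=float(v_step),
                    current=i,
                    fs=fs,
                    t_step=(pre, pre + pulse),
                    pre_step_baseline_window=(0.1, 0.4),
                    cm=params.cm,
                    protocol="if",
                )
            )
        return recs

    if protocol == "ical":
        steps = tuple(steps) if steps is not None else ICAL_STEPS
        if len(steps) == 0:
            raise ValueError("step list must not be empty")
        pre, prepulse, pulse, post = 0.3, 0.02, 0.2, 0.2
        recs = []
        for v_step in steps:
            n = int(round((pre + prepulse + pulse + post) * fs))
            t = np.arange(n) / fs
            i = np.zeros(n)
            in_pre = (t >= pre) & (t < pre + prepulse)
            i[in_pre] = params.leak_g * (-40.0 - ICAL_HOLD)
            in_pulse = (t >= pre + prepulse) & (t < pre + prepulse + pulse)
            tp = t[in_pulse] - (pre + prepulse)
            peak = ical_peak_current(params, v_step)
            envelope = (1.0 - np.exp(-tp / params.tau_act)) * np.exp(-tp / params.tau_inact)
            i[in_pulse] = params.leak_g * (v_step - ICAL_HOLD) + peak * envelope
            recs.append(
                ClampStepRecording(
                    step_v=float(v_step),
                    current=i,
                    fs=fs,
                    t_step=(pre + prepulse, pre + prepulse + pulse),
                    pre_step_baseline_window=(0.05, 0.28),
                    cm=params.cm,
                    protocol="ical",
                )
            )
        return recs

    raise ValueError("protocol must be 'if' or 'ical'")


# ---------------------------------------------------------------------------
# Ca2+ transients with a caffeine pulse
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class CaSimParams:
    """Paced Ca2+ transients plus one caffeine-evoked SR release.

    Each transient is a normalized double-exponential
    (exp(-t/decay_tau) - exp(-t/rise_tau)) scaled to the target amplitude.
    The caffeine transient uses caffeine_amp_factor * transient_amp and its
    own decay constant; pacing resumes so that the first post-caffeine
    transient peaks post_caffeine_pause seconds after the caffeine peak.
    """

    baseline: float = 1.0
    transient_amp: float = 0.5
    rise_tau: float = 0.03
    decay_tau: float = 0.15
    pacing_hz: float = 1.0
    caffeine_time: float = 12.0
    caffeine_amp_factor: float = 2.0
    caffeine_decay_tau: float = 1.5
    post_caffeine_pause: float = 30.0
    seed: Optional[int] = None
    noise_sd: float = 0.0
    fs: float = 200.0

    def __post_init__(self):
        for name in ("rise_tau", "decay_tau", "caffeine_decay_tau"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.caffeine_amp_factor <= 0:
            raise ValueError("caffeine_amp_factor must be positive")
        if self.pacing_hz <= 0 or self.fs <= 0:
            raise ValueError("pacing_hz and fs must be positive")
        if self.rise_tau >= self.decay_tau:
            raise ValueError("rise_tau must be shorter than decay_tau")


@dataclass
class CaGroundTruth:
    """Closed-form caffeine-response metrics of a generated Ca2+ trace."""

    pre_amp: float
    caffeine_amp: float
    amp_change_pct: float
    pre_area: float
    caffeine_area: float
    area_change_pct: float
    recovery_time: float
    caffeine_peak_time: float
    paced_peak_times: np.ndarray


def _kernel_peak(rise_tau: float, decay_tau: float) -> tuple[float, float]:
    """Peak time and value of exp(-t/decay) - exp(-t/rise)."""
    tp = math.log(decay_tau / rise_tau) / (1.0 / rise_tau - 1.0 / decay_tau)
    gmax = math.exp(-tp / decay_tau) - math.exp(-tp / rise_tau)
    return tp, gmax


def generate_ca_trace(params: CaSimParams) -> tuple[CaTrace, CaGroundTruth]:
    """Render a paced Ca2+ recording with one caffeine application."""
    period = 1.0 / params.pacing_hz
    tp, gmax = _kernel_peak(params.rise_tau, params.decay_tau)
    tp_c, gmax_c = _kernel_peak(params.rise_tau, params.caffeine_decay_tau)

    # paced peaks strictly before the caffeine application
    first_peak = 2.0
    pre_peaks = np.arange(first_peak, params.caffeine_time - 0.25 * period, period)
    if pre_peaks.size < 5:
        raise ValueError("caffeine_time must allow at least 5 paced transients")

    caff_peak = params.caffeine_time + tp_c
    resume_first = caff_peak + params.post_caffeine_pause
    # caffeine signal must have decayed before pacing resumes
    residual = params.caffeine_amp_factor * params.transient_amp * math.exp(
        -(resume_first - caff_peak) / params.caffeine_decay_tau
    )
    if residual > 0.02 * params.transient_amp:
        raise ValueError(
            "caffeine transient still decaying when pacing resumes; lengthen "
            "post_caffeine_pause or shorten caffeine_decay_tau"
        )
    post_peaks = resume_first + np.arange(5) * period
    duration = post_peaks[-1] + 5 * params.decay_tau + 1.0

    n = int(round(duration * params.fs))
    t = np.arange(n) / params.fs
    sig = np.full(n, params.baseline, dtype=float)

    def add_transient(peak_time, amp, rise, decay, tpk, gm):
        onset = peak_time - tpk
        m = t >= onset
        tt = t[m] - onset
        sig[m] += amp / gm * (np.exp(-tt / decay) - np.exp(-tt / rise))

    for pk in pre_peaks:
        add_transient(pk, params.transient_amp, params.rise_tau, params.decay_tau, tp, gmax)
    caff_amp = params.caffeine_amp_factor * params.transient_amp
    add_transient(caff_peak, caff_amp, params.rise_tau, params.caffeine_decay_tau, tp_c, gmax_c)
    for pk in post_peaks:
        add_transient(pk, params.transient_amp, params.rise_tau, params.decay_tau, tp, gmax)

    if params.noise_sd > 0:
        rng = np.random.default_rng(params.seed)
        sig += rng.normal(0.0, params.noise_sd, n)

    trace = CaTrace(
        signal=sig,
        fs=params.fs,
        caffeine_time=params.caffeine_time,
        pacing_hz=params.pacing_hz,
        meta={"kind": "calcium"},
    )
    pre_area = params.transient_amp * (params.decay_tau - params.rise_tau) / gmax
    caff_area = caff_amp * (params.caffeine_decay_tau - params.rise_tau) / gmax_c
    gt = CaGroundTruth(
        pre_amp=params.transient_amp,
        caffeine_amp=caff_amp,
        amp_change_pct=100.0 * (params.caffeine_amp_factor - 1.0),
        pre_area=pre_area,
        caffeine_area=caff_area,
        area_change_pct=100.0 * (caff_area - pre_area) / pre_area,
        recovery_time=params.post_caffeine_pause,
        caffeine_peak_time=caff_peak,
        paced_peak_times=np.concatenate([pre_peaks, post_peaks]),
    )
    return trace, gt
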