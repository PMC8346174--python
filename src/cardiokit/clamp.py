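"""Current-density I-V relations from voltage-clamp step families.

I_f (HCN-like pacemaker current) is quantified as the quasi-steady-state
current over the final 100 ms of each 2-s hyperpolarizing pulse minus the
pre-step baseline, normalized by the membrane capacitance (pA/pF).  I_Ca,L is
the peak (most negative) current during each 200-ms depolarizing step minus
baseline, likewise normalized.  Densities keep their sign: inward currents
are negative.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.optimize import curve_fit

from .synth import ClampStepRecording, boltzmann

__all__ = ["IVCurve", "if_density", "ical_density", "build_iv", "fit_if_activation"]

IF_STEADY_WINDOW_S = 0.100


@dataclass
class IVCurve:
    """Step potentials (mV) vs current density (pA/pF), sorted by voltage."""

    v: np.ndarray
    density: np.ndarray
    protocol: str

    def __post_init__(self):
        self.v = np.asarray(self.v, dtype=float)
        self.density = np.asarray(self.density, dtype=float)
        if self.v.size != self.density.size:
            raise ValueError("v and density must have equal length")
        if not np.all(np.isfinite(self.density)):
            raise ValueError("densities must be finite")

    @property
    def points(self):
        return list(zip(self.v, self.density))


def _baseline(rec: ClampStepRecording) -> float:
    b0, b1 = rec.pre_step_baseline_window
    i0 = int(round(b0 * rec.fs))
    i1 = int(round(b1 * rec.fs))
    if i0 < 0 or i1 > rec.current.size or i1 <= i0:
        raise ValueError("pre-step baseline window lies outside the recording")
    return float(np.mean(rec.current[i0:i1]))


def if_density(rec: ClampStepRecording) -> float:
    """Quasi-steady-state I_f density (pA/pF) for one hyperpolarizing step."""
    if rec.protocol != "if":
        raise ValueError("recording is not an I_f step")
    s0, s1 = rec.t_step
    if s1 - s0 < 2.0:
        raise ValueError("I_f pulse must be at least 2 s long")
    i0 = int(round((s1 - IF_STEADY_WINDOW_S) * rec.fs))
    i1 = int(round(s1 * rec.fs))
    steady = float(np.mean(rec.current[i0:i1]))
    return (steady - _baseline(rec)) / rec.cm


def ical_density(rec: ClampStepRecording) -> float:
    """Peak inward I_Ca,L density (pA/pF) for one depolarizing step."""
    if rec.protocol != "ical":
        raise ValueError("recording is not an I_Ca,L step")
    s0, s1 = rec.t_step
    i0 = int(round(s0 * rec.fs))
    i1 = int(round(s1 * rec.fs))
    if i1 <= i0:
        raise ValueError("step window is empty")
    peak = float(np.min(rec.current[i0:i1]))
    return (peak - _baseline(rec)) / rec.cm


def build_iv(recs: Sequence[ClampStepRecording]) -> IVCurve:
    """One density per step voltage, duplicates averaged, sorted by voltage."""
    if len(recs) == 0:
        raise ValueError("no recordings supplied")
    protocols = {r.protocol for r in recs}
    if len(protocols) > 1:
        raise ValueError(f"mixed protocols in one family: {sorted(protocols)}")
    protocol = protocols.pop()
    density_fn = if_density if protocol == "if" else ical_density
    by_v: dict[float, list[float]] = {}
    for rec in recs:
        by_v.setdefault(rec.step_v, []).append(density_fn(rec))
    if len(by_v) < 2:
        raise ValueError("need at least 2 distinct step voltages")
    v = np.array(sorted(by_v))
    dens = np.array([np.mean(by_v[vi]) for vi in v])
    return IVCurve(v=v, density=dens, protocol=protocol)


def fit_if_activation(iv: IVCurve, erev: float) -> tuple[float, float, float]:
    """Least-squares Boltzmann fit to an I_f density curve.

    Fits density(V) = G * (V - erev) / (1 + exp((V - vhalf)/slope)) and
    returns (G in nS/pF, vhalf in mV, slope in mV).  Intended as a recovery
    check on leak-free synthetic families.
    """
    if iv.protocol != "if":
        raise ValueError("activation fit expects an I_f curve")

    def model(v, g, vhalf, slope):
        return g * boltzmann(v, vhalf, slope) * (v - erev)

    g0 = float(np.max(np.abs(iv.density)) / max(np.max(np.abs(iv.v - erev)), 1.0))
    p0 = (g0, float(np.median(iv.v)), 10.0)
    popt, _ = curve_fit(model, iv.v, iv.density, p0=p0, maxfev=20000)
    g, vhalf, slope = popt
    return float(g), float(vhalf), float(slope)
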