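"""Time-series containers for patch-clamp voltage and ratiometric Ca2+ signals.

Both containers assume a uniform sampling grid: samples are stored as a bare
array plus a sampling rate and a start time, so the time axis is implicit and
grid jitter is zero by construction.  All times are seconds, voltages mV, Ca2+
signals in ratio units (fura-style).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np

__all__ = ["VoltageTrace", "CaTrace"]


def _as_signal(x) -> np.ndarray:
    arr = np.asarray(x, dtype=float)
    if arr.ndim != 1:
        raise ValueError("trace signal must be one-dimensional")
    if arr.size and not np.all(np.isfinite(arr)):
        raise ValueError("trace signal contains non-finite values")
    return arr


@dataclass
class _UniformTrace:
    fs: float = 0.0
    t0: float = 0.0
    meta: dict = field(default_factory=dict)

    def _validate(self) -> None:
        if not np.isfinite(self.fs) or self.fs <= 0:
            raise ValueError(f"sampling rate must be positive, got {self.fs}")

    @property
    def n(self) -> int:
        return self._signal().size

    @property
    def dt(self) -> float:
        return 1.0 / self.fs

    @property
    def t(self) -> np.ndarray:
        """Time axis in seconds (computed, uniform by construction)."""
        return self.t0 + np.arange(self.n) / self.fs

    @property
    def duration(self) -> float:
        return self.n / self.fs

    @property
    def t_end(self) -> float:
        return self.t0 + self.duration

    def _signal(self) -> np.ndarray:
        raise NotImplementedError

    def index_of(self, t: float) -> int:
        """Nearest sample index for an absolute time, clipped to the trace."""
        return int(np.clip(round((t - self.t0) * self.fs), 0, max(self.n - 1, 0)))

    def crop(self, t_start: float, t_end: float):
        """Sub-trace on [t_start, t_end); absolute times are preserved."""
        i0 = int(np.clip(np.ceil((t_start - self.t0) * self.fs - 1e-9), 0, self.n))
        i1 = int(np.clip(np.floor((t_end - self.t0) * self.fs + 1e-9), 0, self.n))
        sig = self._signal()[i0:i1]
        return self._with_signal(sig, t0=self.t0 + i0 / self.fs)


@dataclass
class VoltageTrace(_UniformTrace):
    """Uniformly sampled membrane-potential recording (mV)."""

    v: np.ndarray = field(default_factory=lambda: np.empty(0))

    def __post_init__(self):
        self.v = _as_signal(self.v)
        self._validate()

    def _signal(self) -> np.ndarray:
        return self.v

    def _with_signal(self, sig, t0):
        return VoltageTrace(v=sig, fs=self.fs, t0=t0, meta=dict(self.meta))


@dataclass
class CaTrace(_UniformTrace):
    """Uniformly sampled intracellular Ca2+ signal (ratio units).

    ``caffeine_time`` marks the onset of a brief caffeine application (s,
    absolute) and ``pacing_hz`` the field-stimulation frequency, when present.
    """

    signal: np.ndarray = field(default_factory=lambda: np.empty(0))
    caffeine_time: Optional[float] = None
    pacing_hz: Optional[float] = None

    def __post_init__(self):
        self.signal = _as_signal(self.signal)
        self._validate()

    def _signal(self) -> np.ndarray:
        return self.signal

    def _with_signal(self, sig, t0):
        return CaTrace(
            signal=sig,
            fs=self.fs,
            t0=t0,
            meta=dict(self.meta),
            caffeine_time=self.caffeine_time,
            pacing_hz=self.pacing_hz,
        )
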