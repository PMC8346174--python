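"""Paced Ca2+ transient quantification and the caffeine-response parameters.

A brief caffeine application discharges the sarcoplasmic-reticulum Ca2+ store;
the response is summarized by three parameters: (1) recovery time, from the
caffeine-induced peak to the first regular transient afterwards; (2) the
percent change of the caffeine-response amplitude relative to the pre-caffeine
transient amplitude; (3) the analogous percent change in area.

Transient amplitude and area are measured above a local pre-transient
baseline; area is the trapezoidal integral from onset to return-to-baseline.
The pre-caffeine reference is the mean of the last three paced transients.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy.signal import find_peaks

from .traces import CaTrace

__all__ = ["CaTransient", "CaffeineResponse", "detect_ca_transients", "caffeine_response"]

ONSET_FRACTION = 0.05     # of amplitude, rising edge defining the onset
RETURN_FRACTION = 0.02    # of amplitude, decay level closing the area integral
RECOVERY_MIN_FRACTION = 0.25  # of pre-amp, for a transient to count as recovery


@dataclass
class CaTransient:
    onset: float
    peak_time: float
    amplitude: float
    area: float  # ratio * s above local baseline


@dataclass
class CaffeineResponse:
    recovery_time: float
    amp_change_pct: float
    area_change_pct: float
    pre_amp: float
    caffeine_amp: float
    pre_area: float
    caffeine_area: float
    caffeine_peak_time: float
    recovery_censored: bool = False


def detect_ca_transients(trace: CaTrace) -> list[CaTransient]:
    """Detect transients by prominence above a local pre-peak baseline."""
    sig = trace.signal
    if sig.size < 10:
        return []
    scale = float(np.percentile(sig, 98) - np.percentile(sig, 10))
    if scale <= 0:
        return []
    min_dist = max(int(round(0.2 * trace.fs)), 1)
    idx, _ = find_peaks(sig, prominence=0.3 * scale, distance=min_dist)
    if idx.size == 0:
        return []

    # lookback for the local baseline: a fraction of the typical peak spacing
    if idx.size > 1:
        lookback = int(round(0.6 * np.median(np.diff(idx))))
    else:
        lookback = int(round(1.0 * trace.fs))
    lookback = max(lookback, int(round(0.1 * trace.fs)))

    out = []
    for i in idx:
        lo = max(i - lookback, 0)
        baseline = float(np.min(sig[lo : i + 1]))
        amp = float(sig[i]) - baseline
        if amp <= 0:
            continue
        # onset: last pre-peak sample at or below baseline + 5% of amplitude
        pre = sig[lo : i + 1]
        below = np.nonzero(pre <= baseline + ONSET_FRACTION * amp)[0]
        i_on = lo + (int(below[-1]) if below.size else 0)
        # return: first post-peak sample back below baseline + 2% of amplitude
        post = sig[i:]
        back = np.nonzero(post <= baseline + RETURN_FRACTION * amp)[0]
        i_off = i + (int(back[0]) if back.size else post.size - 1)
        area = float(np.trapezoid(sig[i_on : i_off + 1] - baseline, dx=trace.dt))
        out.append(
            CaTransient(
                onset=trace.t0 + i_on / trace.fs,
                peak_time=trace.t0 + i / trace.fs,
                amplitude=amp,
                area=area,
            )
        )
    return out


def caffeine_response(
    trace: CaTrace,
    recovery_min_fraction: float = RECOVERY_MIN_FRACTION,
) -> CaffeineResponse:
    """Quantify the caffeine-evoked SR Ca2+ release of one recording.

    Requires ``trace.caffeine_time`` and at least three clean pre-caffeine
    transients.  When no transient follows the caffeine peak, the recovery
    time is censored at the end of the trace and flagged.
    """
    if trace.caffeine_time is None:
        raise ValueError("trace has no caffeine_time annotation")
    transients = detect_ca_transients(trace)
    pre = [tr for tr in transients if tr.peak_time < trace.caffeine_time]
    if len(pre) < 3:
        raise ValueError("need at least 3 pre-caffeine transients")
    pre3 = pre[-3:]
    pre_amp = float(np.mean([tr.amplitude for tr in pre3]))
    pre_area = float(np.mean([tr.area for tr in pre3]))

    # caffeine peak: the detected transient containing the maximum within 5 s
    w0, w1 = trace.caffeine_time, trace.caffeine_time + 5.0
    window = trace.crop(w0, w1)
    if window.n == 0:
        raise ValueError("caffeine window lies outside the trace")
    t_peak_raw = window.t0 + int(np.argmax(window.signal)) / trace.fs
    caff = min(
        (tr for tr in transients if tr.peak_time >= trace.caffeine_time),
        key=lambda tr: abs(tr.peak_time - t_peak_raw),
        default=None,
    )
    if caff is None or abs(caff.peak_time - t_peak_raw) > 0.5:
        raise ValueError("no caffeine-induced transient found after caffeine_time")

    post = [
        tr
        for tr in transients
        if tr.peak_time > caff.peak_time + 0.5
        and tr.amplitude >= recovery_min_fraction * pre_amp
    ]
    if post:
        recovery = post[0].peak_time - caff.peak_time
        censored = False
    else:
        recovery = trace.t_end - caff.peak_time
        censored = True

    return CaffeineResponse(
        recovery_time=float(recovery),
        amp_change_pct=100.0 * (caff.amplitude - pre_amp) / pre_amp,
        area_change_pct=100.0 * (caff.area - pre_area) / pre_area,
        pre_amp=pre_amp,
        caffeine_amp=caff.amplitude,
        pre_area=pre_area,
        caffeine_area=caff.area,
        caffeine_peak_time=caff.peak_time,
        recovery_censored=censored,
    )
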