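"""Plain-text trace files, ground-truth sidecars, and generic decimation.

Trace files are two delimited numeric columns (time, value) preceded by a
commented header of ``# key: value`` lines.  Required keys: ``fs`` (Hz),
``units`` (e.g. ``s,mV``), ``kind`` (``voltage`` | ``calcium``); optional:
``caffeine_time``, ``pacing_hz`` and free-form ``meta.*`` labels.  Values are
written with full float precision so a write/read round trip is bit-exact.
"""

from __future__ import annotations

import json
from dataclasses import asdict, is_dataclass
from pathlib import Path

import numpy as np
from scipy.signal import resample_poly

from .synth import GroundTruth
from .traces import CaTrace, VoltageTrace

__all__ = ["write_trace", "read_trace", "downsample", "write_ground_truth",
           "read_ground_truth"]

_TIME_FACTORS = {"s": 1.0, "ms": 1e-3}
_VALUE_FACTORS = {"mv": 1.0, "v": 1e3, "ratio": 1.0}


def write_trace(path, trace) -> None:
    """Write a VoltageTrace or CaTrace in the commented-header text format."""
    path = Path(path)
    if isinstance(trace, VoltageTrace):
        kind, units, values = "voltage", "s,mV", trace.v
    elif isinstance(trace, CaTrace):
        kind, units, values = "calcium", "s,ratio", trace.signal
    else:
        raise TypeError("trace must be a VoltageTrace or CaTrace")
    lines = [f"# fs: {trace.fs!r}", f"# units: {units}", f"# kind: {kind}"]
    if isinstance(trace, CaTrace):
        if trace.caffeine_time is not None:
            lines.append(f"# caffeine_time: {trace.caffeine_time!r}")
        if trace.pacing_hz is not None:
            lines.append(f"# pacing_hz: {trace.pacing_hz!r}")
    for key, val in trace.meta.items():
        if key != "kind":
            lines.append(f"# meta.{key}: {val}")
    t = trace.t
    with path.open("w") as fh:
        fh.write("\n".join(lines) + "\n")
        for ti, vi in zip(t, values):
            fh.write(f"{float(ti)!r}\t{float(vi)!r}\n")


def read_trace(path):
    """Read a trace file; normalizes units to (s, mV) or (s, ratio)."""
    path = Path(path)
    header: dict[str, str] = {}
    n_header = 0
    with path.open() as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            n_header += 1
            body = line[1:].strip()
            if ":" in body:
                key, _, val = body.partition(":")
                header[key.strip()] = val.strip()
    if "fs" not in header:
        raise ValueError(f"{path}: header missing required key 'fs'")
    if "kind" not in header:
        raise ValueError(f"{path}: header missing required key 'kind'")
    units = header.get("units", "s,mV")
    try:
        t_unit, v_unit = (u.strip().lower() for u in units.split(","))
        t_factor = _TIME_FACTORS[t_unit]
        v_factor = _VALUE_FACTORS[v_unit]
    except (ValueError, KeyError):
        raise ValueError(f"{path}: unsupported units {units!r}") from None

    data = np.loadtxt(path, comments="#", ndmin=2)
    if data.shape[1] != 2:
        raise ValueError(f"{path}: expected exactly 2 columns, got {data.shape[1]}")
    t = data[:, 0] * t_factor
    values = data[:, 1] * v_factor
    if t.size >= 2:
        dts = np.diff(t)
        if np.any(dts <= 0):
            bad = int(np.nonzero(dts <= 0)[0][0]) + n_header + 2
            raise ValueError(f"{path}: time column not strictly increasing at line {bad}")
        if (dts.max() - dts.min()) > 1e-6 * dts.mean():
            raise ValueError(f"{path}: non-uniform sampling grid")
    fs = float(header["fs"])
    if t.size >= 2:
        fs_data = 1.0 / float(np.mean(np.diff(t)))
        if abs(fs_data - fs) > 1e-3 * fs:
            raise ValueError(
                f"{path}: header fs {fs} inconsistent with time column ({fs_data:.6g})"
            )
    meta = {k[5:]: v for k, v in header.items() if k.startswith("meta.")}
    t0 = float(t[0]) if t.size else 0.0
    if header["kind"] == "voltage":
        return VoltageTrace(v=values, fs=fs, t0=t0, meta=meta)
    if header["kind"] == "calcium":
        caffeine = header.get("caffeine_time")
        pacing = header.get("pacing_hz")
        return CaTrace(
            signal=values,
            fs=fs,
            t0=t0,
            meta=meta,
            caffeine_time=float(caffeine) if caffeine is not None else None,
            pacing_hz=float(pacing) if pacing is not None else None,
        )
    raise ValueError(f"{path}: unknown trace kind {header['kind']!r}")


def downsample(trace, factor: int):
    """Anti-alias low-pass filter then decimate by an integer factor >= 2."""
    if int(factor) != factor or factor < 2:
        raise ValueError("factor must be an integer >= 2")
    factor = int(factor)
    sig = trace.v if isinstance(trace, VoltageTrace) else trace.signal
    # polyphase FIR decimation; line-extension padding avoids edge droop
    out = resample_poly(sig, 1, factor, padtype="line")
    if isinstance(trace, VoltageTrace):
        return VoltageTrace(v=out, fs=trace.fs / factor, t0=trace.t0,
                            meta=dict(trace.meta))
    return CaTrace(signal=out, fs=trace.fs / factor, t0=trace.t0,
                   meta=dict(trace.meta), caffeine_time=trace.caffeine_time,
                   pacing_hz=trace.pacing_hz)


class _GTEncoder(json.JSONEncoder):
    def default(self, obj):
        if isinstance(obj, np.ndarray):
            return obj.tolist()
        if isinstance(obj, (np.floating, np.integer)):
            return obj.item()
        if is_dataclass(obj) and not isinstance(obj, type):
            return asdict(obj)
        return super().default(obj)


def write_ground_truth(path, gt: GroundTruth) -> None:
    """Structured-text (JSON) sidecar with the generator's ground truth."""
    payload = {
        "beat_times": gt.beat_times,
        "shapes": gt.shapes,
        "events": gt.events,
        "cessation_intervals": gt.cessation_intervals,
        "segments": gt.segments,
        "stim_trains": [(f, list(np.asarray(s))) for f, s in gt.stim_trains],
        "fs": gt.fs,
        "duration": gt.duration,
    }
    Path(path).write_text(json.dumps(payload, cls=_GTEncoder, indent=1))


def read_ground_truth(path) -> dict:
    """Read a ground-truth sidecar back as plain dictionaries."""
    return json.loads(Path(path).read_text())
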