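"""Beat-rate-variability analysis: IBI series, COV, and Poincare SD1/SD2.

The Poincare plot scatters each inter-beat interval against its successor.
SD1 (dispersion across the identity line, short-term variability) and SD2
(dispersion along it, long-term variability) are computed with the standard
difference-based estimators, which coincide exactly with the standard
deviations of the rotated coordinates (y - x)/sqrt(2) and (x + y)/sqrt(2) of
the pair cloud; the ellipse identity sd1^2 + sd2^2 = 2 * sd^2 then holds
exactly for the pair-cloud dispersion sd.  The coefficient of variation (COV)
is reported on the full IBI series.  Sample (n-1) variance throughout.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .ap import Beat, activation_times

__all__ = ["IBISeries", "BRVMetrics", "extract_ibis", "brv_metrics", "poincare_points"]


@dataclass
class IBISeries:
    """Consecutive inter-beat intervals (s) from one recording window."""

    values: np.ndarray
    source: str = ""
    window_s: Optional[float] = None

    def __post_init__(self):
        vals = np.asarray(self.values, dtype=float)
        if vals.size and (not np.all(np.isfinite(vals)) or np.any(vals <= 0)):
            raise ValueError("IBIs must be finite and positive")
        self.values = vals

    def __len__(self):
        return self.values.size


@dataclass
class BRVMetrics:
    """COV, Poincare descriptors and an IBI histogram for one series."""

    mean_ibi: float
    sd_ibi: float
    cov: float            # percent, 100 * sd / mean on the full series
    sd1: float            # s, short-term (across-identity) dispersion
    sd2: float            # s, long-term (along-identity) dispersion
    sd_pair: float        # s, per-axis dispersion of the Poincare cloud
    histogram: tuple      # (bin edges s, counts)
    sd2_clamped: bool = False


def extract_ibis(beats, window_s: float = 100.0, source: str = "") -> Optional[IBISeries]:
    """IBIs whose starting beat falls within the first ``window_s`` seconds.

    ``beats`` is a Beat sequence or an array of activation times (absolute).
    Returns None when fewer than 3 complete intervals are available.
    """
    if len(beats) and isinstance(beats[0], Beat):
        acts = activation_times(beats)
    else:
        acts = np.asarray(beats, dtype=float)
    if acts.size < 2:
        return None
    t_start = acts[0]
    starts = acts[:-1]
    ibis = np.diff(acts)[starts - t_start <= window_s]
    if ibis.size < 3:
        return None
    return IBISeries(values=ibis, source=source, window_s=window_s)


def brv_metrics(ibis: IBISeries, bin_width_s: float = 0.05) -> BRVMetrics:
    """COV, SD1/SD2 and a fixed-bin-width histogram for an IBI series."""
    x = ibis.values if isinstance(ibis, IBISeries) else np.asarray(ibis, dtype=float)
    if x.size < 3:
        raise ValueError("need at least 3 IBIs")
    if bin_width_s <= 0:
        raise ValueError("bin_width_s must be positive")

    mean = float(np.mean(x))
    if x.max() == x.min():  # constant series: all dispersions exactly zero
        edges = np.array([x[0], x[0] + bin_width_s])
        return BRVMetrics(mean_ibi=float(x[0]), sd_ibi=0.0, cov=0.0, sd1=0.0,
                          sd2=0.0, sd_pair=0.0,
                          histogram=(edges, np.array([x.size])))
    sd = float(np.std(x, ddof=1))
    cov = 100.0 * sd / mean

    a, b = x[:-1], x[1:]
    sd1_sq = float(np.var(b - a, ddof=1)) / 2.0
    sd_pair_sq = 0.5 * (float(np.var(a, ddof=1)) + float(np.var(b, ddof=1)))
    # sd2^2 = 2*sd_pair^2 - sd1^2 algebraically; the rotated-coordinate form
    # is the numerically stable evaluation (no cancellation for alternations)
    sd2_sq = float(np.var((a + b) / np.sqrt(2.0), ddof=1))
    clamped = sd2_sq < 0
    sd2 = float(np.sqrt(max(sd2_sq, 0.0)))

    lo = np.floor(x.min() / bin_width_s) * bin_width_s
    hi = np.ceil(x.max() / bin_width_s) * bin_width_s
    n_bins = max(int(round((hi - lo) / bin_width_s)), 1)
    counts, edges = np.histogram(x, bins=n_bins, range=(lo, lo + n_bins * bin_width_s))

    return BRVMetrics(
        mean_ibi=mean,
        sd_ibi=sd,
        cov=cov,
        sd1=float(np.sqrt(sd1_sq)),
        sd2=sd2,
        sd_pair=float(np.sqrt(sd_pair_sq)),
        histogram=(edges, counts),
        sd2_clamped=clamped,
    )


def poincare_points(ibis) -> np.ndarray:
    """Ordered (IBI_n, IBI_{n+1}) pairs, shape (n-1, 2)."""
    x = ibis.values if isinstance(ibis, IBISeries) else np.asarray(ibis, dtype=float)
    if x.size < 2:
        raise ValueError("need at least 2 IBIs")
    return np.column_stack([x[:-1], x[1:]])
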