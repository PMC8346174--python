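"""Cohort-level statistics: outlier exclusion, mean +/- SEM, Holm-Sidak step.

The outlier rule is a single pass: the mean and sample standard deviation are
computed once on the full sample and values outside mean +/- 2*SD are removed;
boundary values are kept.  The rule is deliberately not iterated — re-running
it on the kept values could remove more points.

Only the exclusion rule and the Holm-Sidak step-down adjustment are bespoke;
omnibus ANOVA is left to standard statistical packages.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

__all__ = ["GroupSample", "OutlierReport", "GroupSummary",
           "exclude_outliers", "group_summary", "holm_sidak_adjust"]


@dataclass
class GroupSample:
    group: str
    metric: str
    values: np.ndarray

    def __post_init__(self):
        vals = np.asarray(self.values, dtype=float)
        if vals.size < 1:
            raise ValueError("a group sample needs at least one value")
        if not np.all(np.isfinite(vals)):
            raise ValueError("sample values must be finite")
        self.values = vals


@dataclass
class OutlierReport:
    kept: np.ndarray
    removed: np.ndarray
    mean: float
    sd: float


@dataclass
class GroupSummary:
    mean: float
    sem: Optional[float]
    n: int
    sem_defined: bool = True


def _values(sample) -> np.ndarray:
    if isinstance(sample, GroupSample):
        return sample.values
    vals = np.asarray(sample, dtype=float)
    if not np.all(np.isfinite(vals)):
        raise ValueError("sample values must be finite")
    return vals


def exclude_outliers(sample) -> OutlierReport:
    """Single-pass mean +/- 2*SD exclusion (sample SD, boundaries kept)."""
    vals = _values(sample)
    if vals.size < 3:
        raise ValueError("need at least 3 values for outlier exclusion")
    mean = float(np.mean(vals))
    sd = float(np.std(vals, ddof=1))
    if sd == 0:
        return OutlierReport(kept=vals.copy(), removed=vals[:0], mean=mean, sd=sd)
    outside = np.abs(vals - mean) > 2.0 * sd
    return OutlierReport(kept=vals[~outside], removed=vals[outside], mean=mean, sd=sd)


def group_summary(sample) -> GroupSummary:
    """Mean, SEM (= sample SD / sqrt(n)) and n; SEM undefined for n = 1."""
    vals = _values(sample)
    if vals.size < 1:
        raise ValueError("need at least one value")
    mean = float(np.mean(vals))
    if vals.size == 1:
        return GroupSummary(mean=mean, sem=None, n=1, sem_defined=False)
    sem = float(np.std(vals, ddof=1) / np.sqrt(vals.size))
    return GroupSummary(mean=mean, sem=sem, n=int(vals.size))


def holm_sidak_adjust(pvalues) -> np.ndarray:
    """Holm-Sidak step-down adjusted p-values, in the input order.

    For ascending p_(1) <= ... <= p_(m): adjusted_(i) = 1 - (1 - p_(i))^(m-i+1)
    with a running maximum to enforce monotonicity, capped at 1.
    """
    p = np.asarray(pvalues, dtype=float)
    if p.ndim != 1 or p.size == 0:
        raise ValueError("pvalues must be a non-empty 1-D sequence")
    if np.any(~np.isfinite(p)) or np.any(p < 0) or np.any(p > 1):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    adjusted_sorted = 1.0 - (1.0 - p[order]) ** (m - np.arange(m))
    adjusted_sorted = np.minimum(np.maximum.accumulate(adjusted_sorted), 1.0)
    out = np.empty(m)
    out[order] = adjusted_sorted
    return out
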