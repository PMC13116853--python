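"""Summary statistics for zero-inflated count vectors and concordance classification.

Conventions: the standard deviation uses the n-1 denominator; MAD is the
raw median absolute deviation from the median (no normal-consistency
scaling); skewness and kurtosis are moment-based with n denominators,
kurtosis non-excess (a normal distribution has kurtosis 3); the Gini
coefficient is the mean absolute pairwise difference over twice the mean.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .data import DataError, PairedObservation

__all__ = ["SummaryStats", "ConcordanceCounts", "summarize", "classify_pairs", "gini"]


@dataclass(frozen=True)
class SummaryStats:
    total_n: int
    valid_n: int
    zero_count: int
    zero_perc: float
    mean: float
    median: float
    max: float
    sd: float
    mad_median: float
    iqr: float
    gini: float
    skewness: float  # NaN when the variance is zero
    kurtosis: float  # NaN when the variance is zero


@dataclass(frozen=True)
class ConcordanceCounts:
    """Four-way classification of complete-case pairs by joint presence."""

    both_zero: int
    trap_only: int
    soil_only: int
    concordant: int

    @property
    def n(self) -> int:
        return self.both_zero + self.trap_only + self.soil_only + self.concordant

    def proportions(self) -> dict[str, float]:
        n = self.n
        return {
            "both_zero": self.both_zero / n,
            "trap_only": self.trap_only / n,
            "soil_only": self.soil_only / n,
            "concordant": self.concordant / n,
        }


def gini(x: np.ndarray) -> float:
    """Gini coefficient ``sum_ij |x_i - x_j| / (2 n^2 xbar)``; 0 for zero mean.

    Computed via the sorted-rank identity, algebraically equal to the
    pairwise-difference double sum (checked against a two-loop oracle in
    the test suite).
    """
    x = np.sort(np.asarray(x, dtype=float))
    n = x.size
    if n == 0:
        raise DataError("gini of empty vector")
    xbar = x.mean()
    if xbar == 0:
        return 0.0
    i = np.arange(1, n + 1)
    return float(np.sum((2 * i - n - 1) * x) / (n * n * xbar))


def summarize(
    counts: Iterable[int | None] | np.ndarray, total_n: int | None = None
) -> SummaryStats:
    """Per-method summary of a count vector; ``None`` entries are missing.

    ``total_n`` is the number of deployed samples including invalid ones;
    it defaults to the input length.  All statistics are computed over the
    valid (non-missing) values only.
    """
    raw = list(counts) if not isinstance(counts, np.ndarray) else list(counts)
    if total_n is None:
        total_n = len(raw)
    x = np.asarray([v for v in raw if v is not None], dtype=float)
    if x.size == 0:
        raise DataError("summarize requires at least one valid value")
    n = x.size
    zero_count = int(np.sum(x == 0))
    centered = x - x.mean()
    m2 = float(np.mean(centered**2))
    if m2 > 0:
        skew = float(np.mean(centered**3)) / m2**1.5
        kurt = float(np.mean(centered**4)) / m2**2
    else:
        skew = math.nan
        kurt = math.nan
    q75, q25 = np.percentile(x, [75, 25])  # linear interpolation (type-7)
    return SummaryStats(
        total_n=int(total_n),
        valid_n=int(n),
        zero_count=zero_count,
        zero_perc=100.0 * zero_count / n,
        mean=float(x.mean()),
        median=float(np.median(x)),
        max=float(x.max()),
        sd=float(x.std(ddof=1)) if n > 1 else 0.0,
        mad_median=float(np.median(np.abs(x - np.median(x)))),
        iqr=float(q75 - q25),
        gini=gini(x),
        skewness=skew,
        kurtosis=kurt,
    )


def classify_pairs(pairs: Sequence[PairedObservation]) -> ConcordanceCounts:
    """Classify complete-case pairs into the four concordance categories."""
    both_zero = trap_only = soil_only = concordant = 0
    for p in pairs:
        if p.soil_count is None or p.trap_count is None:
            raise DataError(
                f"missing value at (site={p.site_id}, point={p.point_id}); "
                "filter to complete cases first"
            )
        if p.soil_count == 0:
            if p.trap_count == 0:
                both_zero += 1
            else:
                trap_only += 1
        elif p.trap_count == 0:
            soil_only += 1
        else:
            concordant += 1
    return ConcordanceCounts(both_zero, trap_only, soil_only, concordant)
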