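"""Non-parametric monotonic association between soil-core and trap counts.

Spearman's rho (mid-ranks, large-sample t approximation) and Kendall's
tau-b (tie-corrected, normal approximation) — the tau-b variant matters
here because zero-inflated counts produce massive tie groups.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

from .data import DataError, PairedObservation

__all__ = ["CorrelationMethod", "CorrelationResult", "spearman", "kendall_tau_b", "correlate_pairs"]


class CorrelationMethod(str, enum.Enum):
    spearman = "spearman"
    kendall_tau_b = "kendall_tau_b"


@dataclass(frozen=True)
class CorrelationResult:
    estimate: float
    p_value: float
    n: int
    method: CorrelationMethod

    def __post_init__(self) -> None:
        if abs(self.estimate) > 1 + 1e-12:
            raise ValueError(f"|estimate| > 1: {self.estimate}")


def _validate(x, y) -> tuple[np.ndarray, np.ndarray]:
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise DataError("x and y must be 1-d vectors of equal length")
    if x.size < 3:
        raise DataError("need at least 3 observations")
    if np.all(x == x[0]) or np.all(y == y[0]):
        raise DataError("rank correlation undefined for a constant vector")
    return x, y


def spearman(x: Sequence[float], y: Sequence[float]) -> CorrelationResult:
    """Spearman's rho: Pearson correlation of mid-ranks, two-sided t test."""
    x, y = _validate(x, y)
    rho, p = stats.spearmanr(x, y)
    return CorrelationResult(float(rho), float(p), x.size, CorrelationMethod.spearman)


def kendall_tau_b(x: Sequence[float], y: Sequence[float]) -> CorrelationResult:
    """Kendall's tau-b with tie corrections, two-sided normal approximation."""
    x, y = _validate(x, y)
    tau, p = stats.kendalltau(x, y, variant="b", method="asymptotic")
    return CorrelationResult(float(tau), float(p), x.size, CorrelationMethod.kendall_tau_b)


def correlate_pairs(
    pairs: Sequence[PairedObservation],
) -> dict[str, CorrelationResult]:
    """Both rank correlations of trap on soil counts for complete-case pairs."""
    soil = [p.soil_count for p in pairs]
    trap = [p.trap_count for p in pairs]
    if any(v is None for v in soil) or any(v is None for v in trap):
        raise DataError("correlate_pairs requires complete cases")
    return {
        "spearman": spearman(soil, trap),
        "kendall_tau_b": kendall_tau_b(soil, trap),
    }
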