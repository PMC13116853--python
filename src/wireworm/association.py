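"""Presence/absence association between the two monitoring methods.

2x2 contingency construction, Pearson chi-squared with or without the
Yates continuity correction, Fisher's exact test (two-sided,
probability-mass ordering), and the Phi coefficient.

Both chi-squared variants are first-class: the species-level independence
tests in the source analyses use the uncorrected statistic, whereas the
observed statistic fed to the spatial permutation test is the
Yates-corrected form.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

from .data import DataError, PairedObservation
from .descriptive import classify_pairs

__all__ = [
    "ContingencyTable2x2",
    "TestResult",
    "contingency_from_pairs",
    "chi_square_2x2",
    "fisher_exact_2x2",
    "phi_coefficient",
]


@dataclass(frozen=True)
class ContingencyTable2x2:
    """Presence/absence cross-classification.

    Rows are soil cores (absence, presence), columns are traps
    (absence, presence): ``a`` = both absent, ``b`` = trap only,
    ``c`` = soil only, ``d`` = both present.
    """

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        for name in ("a", "b", "c", "d"):
            if getattr(self, name) < 0:
                raise DataError(f"negative cell {name}")
        if self.n < 1:
            raise DataError("empty contingency table")

    @property
    def n(self) -> int:
        return self.a + self.b + self.c + self.d

    @property
    def margins(self) -> tuple[int, int, int, int]:
        """(soil absent, soil present, trap absent, trap present)."""
        return (self.a + self.b, self.c + self.d, self.a + self.c, self.b + self.d)

    def to_array(self) -> np.ndarray:
        return np.array([[self.a, self.b], [self.c, self.d]])


@dataclass(frozen=True)
class TestResult:
    statistic: float | None
    p_value: float
    method: str
    df: int | None = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_value <= 1.0:
            raise ValueError(f"p-value out of range: {self.p_value}")


def contingency_from_pairs(pairs: Sequence[PairedObservation]) -> ContingencyTable2x2:
    """Build the 2x2 presence/absence table from complete-case pairs."""
    if not pairs:
        raise DataError("no pairs to tabulate")
    c = classify_pairs(pairs)
    return ContingencyTable2x2(c.both_zero, c.trap_only, c.soil_only, c.concordant)


def _expected(t: ContingencyTable2x2) -> np.ndarray:
    r0, r1, c0, c1 = t.margins
    return np.outer([r0, r1], [c0, c1]) / t.n


def chi_square_2x2(
    t: ContingencyTable2x2, continuity_correction: bool = False
) -> TestResult:
    """Pearson chi-squared test of independence on a 2x2 table.

    With ``continuity_correction`` the Yates adjustment subtracts 0.5 from
    each |O - E| (floored at zero).  Requires all expected counts > 0,
    i.e. no zero margin.
    """
    expected = _expected(t)
    if np.any(expected == 0):
        raise DataError("zero margin: expected cell count is 0")
    observed = t.to_array().astype(float)
    h = 0.5 if continuity_correction else 0.0
    adj = np.maximum(np.abs(observed - expected) - h, 0.0)
    stat = float(np.sum(adj**2 / expected))
    p = float(stats.chi2.sf(stat, df=1))
    label = "pearson_chi2_yates" if continuity_correction else "pearson_chi2"
    return TestResult(statistic=stat, p_value=p, method=label, df=1)


def yates_chi2_statistic(a: np.ndarray, b: np.ndarray, c: np.ndarray, d: np.ndarray) -> np.ndarray:
    """Vectorized Yates-corrected chi-squared statistic over arrays of cells.

    Used by the permutation test, where hundreds of thousands of permuted
    tables share the same margins.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    c = np.asarray(c, dtype=float)
    d = np.asarray(d, dtype=float)
    n = a + b + c + d
    r0, r1, c0, c1 = a + b, c + d, a + c, b + d
    with np.errstate(divide="ignore", invalid="ignore"):
        # |O - E| is identical for all four cells of a 2x2 table
        dev = np.maximum(np.abs(a - r0 * c0 / n) - 0.5, 0.0)
        stat = dev**2 * n * (n / (r0 * r1 * c0 * c1)) * n
    return stat


def fisher_exact_2x2(t: ContingencyTable2x2) -> TestResult:
    """Two-sided Fisher exact test, probability-mass ordering.

    The two-sided p-value sums the hypergeometric probabilities of every
    table with the observed margins whose probability does not exceed the
    observed table's (with a small relative tolerance for ties).
    """
    _, p = stats.fisher_exact(t.to_array(), alternative="two-sided")
    return TestResult(statistic=None, p_value=float(p), method="fisher_exact")


def phi_coefficient(t: ContingencyTable2x2) -> float:
    """Phi coefficient ``(ad - bc) / sqrt(product of margins)``, sign retained.

    Satisfies ``phi^2 * n == uncorrected chi-squared`` on every valid table.
    """
    r0, r1, c0, c1 = t.margins
    if min(r0, r1, c0, c1) == 0:
        raise DataError("zero margin: phi undefined")
    num = t.a * t.d - t.b * t.c
    return num / math.sqrt(float(r0) * r1 * c0 * c1)
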