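"""Diagnostics showing that Gaussian linear modeling fails for trap counts.

Ordinary least squares of (possibly transformed) trap counts on soil
counts, followed by Shapiro-Wilk on the residuals, the studentized
(Koenker) Breusch-Pagan test, and the Durbin-Watson statistic in input
row order.  These diagnostics motivate the switch to count models; no
remediation is attempted.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import statsmodels.api as sm
from scipy import stats
from statsmodels.stats.diagnostic import het_breuschpagan
from statsmodels.stats.stattools import durbin_watson

from .data import DataError, PairedObservation

__all__ = ["Transform", "DiagnosticsReport", "diagnose_lm", "diagnose_arrays"]

_SHAPIRO_MAX_N = 5000


class Transform(str, enum.Enum):
    raw = "raw"
    log1p = "log1p"
    sqrt = "sqrt"


_TRANSFORMS = {
    Transform.raw: lambda y: y,
    Transform.log1p: np.log1p,
    Transform.sqrt: np.sqrt,
}


@dataclass(frozen=True)
class DiagnosticsReport:
    transform: Transform
    shapiro_p: float
    breusch_pagan_p: float
    durbin_watson_stat: float
    durbin_watson_p: float | None
    verdicts: dict[str, str]

    def __post_init__(self) -> None:
        if not 0.0 <= self.durbin_watson_stat <= 4.0:
            raise ValueError(f"DW out of [0, 4]: {self.durbin_watson_stat}")


def _verdict(p: float, reject_label: str, ok_label: str, alpha: float = 0.05) -> str:
    return reject_label if p < alpha else ok_label


def diagnose_lm(
    pairs: Sequence[PairedObservation],
    transform: Transform | str = Transform.raw,
    *,
    n_dw_shuffles: int = 2000,
    seed: int = 0,
) -> DiagnosticsReport:
    """OLS of transformed trap counts on soil counts, with assumption tests.

    The Durbin-Watson statistic follows the input row order; since an
    exact null would depend on the design, its p-value is estimated by
    shuffling the residual order (set ``n_dw_shuffles=0`` to skip).
    Shapiro-Wilk is evaluated on a fixed-seed subsample when residuals
    exceed 5000.
    """
    tr = Transform(transform)
    soil = np.array([p.soil_count for p in pairs], dtype=float)
    trap = np.array([p.trap_count for p in pairs], dtype=float)
    if np.any(np.isnan(soil)) or np.any(np.isnan(trap)):
        raise DataError("diagnose_lm requires complete cases")
    return diagnose_arrays(
        _TRANSFORMS[tr](trap), soil, transform=tr,
        n_dw_shuffles=n_dw_shuffles, seed=seed,
    )


def diagnose_arrays(
    y: np.ndarray,
    soil: np.ndarray,
    *,
    transform: Transform = Transform.raw,
    n_dw_shuffles: int = 2000,
    seed: int = 0,
) -> DiagnosticsReport:
    """Assumption tests for an arbitrary (already transformed) response."""
    y = np.asarray(y, dtype=float)
    soil = np.asarray(soil, dtype=float)
    tr = transform
    if soil.size < 10:
        raise DataError("need at least 10 pairs")
    if np.all(soil == soil[0]):
        raise DataError("constant predictor: regression degenerate")

    X = sm.add_constant(soil)
    fit = sm.OLS(y, X).fit()
    resid = fit.resid

    sub = resid
    if sub.size > _SHAPIRO_MAX_N:
        idx = np.random.default_rng(seed).choice(sub.size, _SHAPIRO_MAX_N, replace=False)
        sub = sub[idx]
    shapiro_p = float(stats.shapiro(sub).pvalue)

    _, bp_p, _, _ = het_breuschpagan(resid, X, robust=True)  # studentized (Koenker)

    dw = float(durbin_watson(resid))
    dw_p = None
    if n_dw_shuffles > 0:
        rng = np.random.default_rng(seed)
        null = np.empty(n_dw_shuffles)
        for i in range(n_dw_shuffles):
            null[i] = durbin_watson(rng.permutation(resid))
        # two-sided: departure from the null in either direction
        frac_low = (1 + np.sum(null <= dw)) / (1 + n_dw_shuffles)
        frac_high = (1 + np.sum(null >= dw)) / (1 + n_dw_shuffles)
        dw_p = float(min(1.0, 2 * min(frac_low, frac_high)))

    verdicts = {
        "shapiro_wilk": _verdict(shapiro_p, "Not Normal", "Normal"),
        "breusch_pagan": _verdict(bp_p, "Heteroscedastic", "Homoscedastic"),
        "durbin_watson": (
            _verdict(dw_p, "Possible autocorrelation", "No autocorrelation")
            if dw_p is not None
            else "Not assessed"
        ),
    }
    return DiagnosticsReport(
        transform=tr,
        shapiro_p=shapiro_p,
        breusch_pagan_p=float(bp_p),
        durbin_watson_stat=dw,
        durbin_watson_p=dw_p,
        verdicts=verdicts,
    )
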