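"""Conversion of bait-trap damage thresholds into soil-sampling densities.

Chain: per-method ZINB moments -> trap-to-core abundance ratio with a
first-order delta-method SD (zero covariance assumed, an acknowledged
simplification since both estimates come from the same sites) -> per-core
threshold ``T / R`` -> per-square-metre threshold via the factor 88 (one
soil core of 12 cm diameter is 1/88 of a square metre).

ZINB moments: ``E(Y) = (1 - pi) mu`` and
``Var(Y) = (1 - pi)(mu + mu^2/theta) + pi(1 - pi) mu^2``.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass

import numpy as np

from .count_models import CountModelFit, Family
from .data import DataError, Species

__all__ = [
    "Method",
    "AbundanceEstimate",
    "RatioEstimate",
    "ThresholdConversion",
    "CORES_PER_M2",
    "DAMAGE_THRESHOLDS",
    "zinb_moments",
    "abundance_from_fit",
    "ratio_estimate",
    "convert_threshold",
]

#: one soil core (12 cm diameter, 30 cm depth) samples 1/88 of a square metre
CORES_PER_M2 = 88

#: established larvae-per-trap damage thresholds for maize
DAMAGE_THRESHOLDS: dict[Species, float] = {
    Species.A_brevis: 1.0,
    Species.A_sordidus: 2.0,
    Species.A_ustulatus: 5.0,
}


class Method(str, enum.Enum):
    soil_core = "soil_core"
    bait_trap = "bait_trap"


@dataclass(frozen=True)
class AbundanceEstimate:
    """Mean and SD of larvae per sampling unit for one method."""

    mean: float
    sd: float
    method: Method | None = None
    species: Species | None = None

    def __post_init__(self) -> None:
        if self.mean < 0 or self.sd < 0:
            raise DataError("abundance mean and sd must be >= 0")


@dataclass(frozen=True)
class RatioEstimate:
    """Trap-to-core abundance ratio R with delta-method SD."""

    ratio: float
    sd: float
    numerator: AbundanceEstimate
    denominator: AbundanceEstimate


@dataclass(frozen=True)
class ThresholdConversion:
    threshold_per_trap: float
    threshold_per_core: float
    threshold_per_core_sd: float
    threshold_per_m2: float
    threshold_per_m2_sd: float
    cores_per_m2: int = CORES_PER_M2


def zinb_moments(
    pi: float,
    mu: float,
    theta: float,
    *,
    method: Method | None = None,
    species: Species | None = None,
) -> AbundanceEstimate:
    """Marginal mean and SD of a ZINB(mu, theta, pi) variable."""
    if not 0.0 <= pi < 1.0:
        raise DataError(f"pi must lie in [0, 1), got {pi}")
    if mu <= 0 or theta <= 0:
        raise DataError("mu and theta must be > 0")
    mean = (1 - pi) * mu
    var = (1 - pi) * (mu + mu**2 / theta) + pi * (1 - pi) * mu**2
    return AbundanceEstimate(mean=mean, sd=math.sqrt(var), method=method, species=species)


def abundance_from_fit(
    fit: CountModelFit,
    *,
    method: Method | None = None,
    species: Species | None = None,
) -> AbundanceEstimate:
    """Abundance estimate from a fitted ZINB, averaged across observations.

    The per-observation ZINB means and variances (conditional on each
    observation's predictor value) are averaged over the dataset; the SD
    is the square root of the averaged variance.
    """
    if fit.family is not Family.zinb:
        raise DataError("abundance_from_fit expects a ZINB fit")
    pi, theta = fit.zi_prob, fit.theta
    mu = np.exp(fit.intercept + fit.slope * fit.predictor)
    means = (1 - pi) * mu
    variances = (1 - pi) * (mu + mu**2 / theta) + pi * (1 - pi) * mu**2
    return AbundanceEstimate(
        mean=float(means.mean()),
        sd=float(math.sqrt(variances.mean())),
        method=method,
        species=species,
    )


def ratio_estimate(x: AbundanceEstimate, y: AbundanceEstimate) -> RatioEstimate:
    """R = x.mean / y.mean with first-order delta-method SD, zero covariance."""
    if y.mean <= 0:
        raise DataError("denominator mean must be > 0")
    r = x.mean / y.mean
    sd = math.sqrt((x.sd / y.mean) ** 2 + (x.mean * y.sd / y.mean**2) ** 2)
    return RatioEstimate(ratio=r, sd=sd, numerator=x, denominator=y)


def convert_threshold(threshold_per_trap: float, r: RatioEstimate) -> ThresholdConversion:
    """Per-trap damage threshold -> per-core and per-m2 soil thresholds.

    ``T / R`` with SD ``T * sd(R) / R^2``; per-m2 values are 88x both the
    mean and the SD.
    """
    if threshold_per_trap <= 0:
        raise DataError("threshold_per_trap must be > 0")
    if r.ratio <= 0:
        raise DataError("ratio must be > 0")
    per_core = threshold_per_trap / r.ratio
    per_core_sd = threshold_per_trap * r.sd / r.ratio**2
    return ThresholdConversion(
        threshold_per_trap=threshold_per_trap,
        threshold_per_core=per_core,
        threshold_per_core_sd=per_core_sd,
        threshold_per_m2=per_core * CORES_PER_M2,
        threshold_per_m2_sd=per_core_sd * CORES_PER_M2,
    )
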