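"""Count-model suite for trap captures as a function of soil-core counts.

Families: Poisson, quasi-Poisson, negative binomial (NB2), zero-inflated
Poisson, zero-inflated negative binomial, hurdle NB, plus a plain linear
model as the degenerate Gaussian baseline.  The count mean uses a log
link; by default the response is the trap count with the soil count as
the single predictor, and an intercept-only design is available for
per-method abundance fits.  The zero-inflation component is always
intercept-only (one structural-zero probability per model), while the
hurdle's binary detection part carries intercept and slope.

Negative binomial convention: mean ``mu``, size ``theta``,
``Var = mu + mu^2/theta`` (``theta`` is the reciprocal of the NB2 alpha
used internally by statsmodels).

Estimated-parameter counts for AIC/BIC with the single-predictor design:
poisson 2, negbin 3, zip 3, zinb 4, hurdle_nb 5 (logit intercept + slope,
truncated-NB intercept + slope + theta), lm 3 (incl. the error variance);
intercept-only designs drop one slope parameter per component.
Quasi-Poisson has no likelihood and reports neither criterion.
"""

from __future__ import annotations

import enum
import math
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import special, stats
from statsmodels.discrete.count_model import (
    ZeroInflatedNegativeBinomialP,
    ZeroInflatedPoisson,
)
from statsmodels.discrete.discrete_model import Logit, NegativeBinomial, Poisson
from statsmodels.discrete.truncated_model import TruncatedLFNegativeBinomialP

from .data import DataError, PairedObservation

__all__ = [
    "Family",
    "CountModelFit",
    "ValidationMetrics",
    "ConvergenceError",
    "fit_count_model",
    "compare_models",
    "validate_fit",
    "predict_mean",
]

#: maximum admissible NB size parameter; theta above this is treated as
#: the Poisson limit (equidispersion) and flagged
THETA_CAP = 1e6


class Family(str, enum.Enum):
    poisson = "poisson"
    quasipoisson = "quasipoisson"
    negbin = "negbin"
    zip = "zip"
    zinb = "zinb"
    hurdle_nb = "hurdle_nb"
    lm = "lm"


# parameters beyond the count-mean coefficients
_EXTRA_PARAMS = {
    Family.poisson: 0,
    Family.quasipoisson: 0,
    Family.negbin: 1,      # theta
    Family.zip: 1,         # zero-inflation intercept
    Family.zinb: 2,        # zero-inflation intercept + theta
    Family.lm: 1,          # error variance
}

_ZERO_INFLATED = {Family.zip, Family.zinb}


class ConvergenceError(RuntimeError):
    """Raised when a maximum-likelihood fit fails to converge."""


@dataclass
class CountModelFit:
    family: Family
    intercept: float
    slope: float
    intercept_se: float
    slope_se: float
    slope_p: float
    theta: float | None = None          # NB size; None for poisson/zip/lm
    theta_capped: bool = False
    zi_prob: float | None = None        # structural-zero probability
    loglik: float | None = None
    aic: float | None = None
    bic: float | None = None
    dispersion_stat: float | None = None
    n_params: int | None = None
    nobs: int = 0
    intercept_only: bool = False
    fitted_mean: np.ndarray = field(default_factory=lambda: np.array([]))
    zero_prob: np.ndarray = field(default_factory=lambda: np.array([]))
    predictor: np.ndarray = field(default_factory=lambda: np.array([]))
    response: np.ndarray = field(default_factory=lambda: np.array([]))
    binary_coef: tuple[float, float] | None = None  # hurdle detection part

    def __post_init__(self) -> None:
        if self.fitted_mean.size and self.family is not Family.lm:
            if np.any(self.fitted_mean < -1e-9):
                raise ValueError("negative fitted mean in a count model")

    # older names kept for symmetry with the paired data model
    @property
    def soil(self) -> np.ndarray:
        return self.predictor

    @property
    def trap(self) -> np.ndarray:
        return self.response


@dataclass(frozen=True)
class ValidationMetrics:
    rmse: float
    mad_mean: float                    # mean absolute deviation of fit
    corr_pred_obs: float | None       # None when predictions are constant
    zero_freq_observed: float
    zero_freq_predicted: float | None
    irr: float


def _extract_arrays(
    pairs: Sequence[PairedObservation] | tuple[np.ndarray, np.ndarray],
    response: str,
) -> tuple[np.ndarray, np.ndarray]:
    """Return (predictor, response) arrays from pairs or a (soil, trap) tuple."""
    if isinstance(pairs, tuple):
        soil, trap = (np.asarray(a, dtype=float) for a in pairs)
    else:
        soil = np.array([p.soil_count for p in pairs], dtype=float)
        trap = np.array([p.trap_count for p in pairs], dtype=float)
    if np.any(np.isnan(soil)) or np.any(np.isnan(trap)):
        raise DataError("count models require complete cases")
    if soil.size < 10:
        raise DataError("need at least 10 complete pairs")
    if response == "trap":
        return soil, trap
    if response == "soil":
        return trap, soil
    raise DataError(f"response must be 'trap' or 'soil', got {response!r}")


def _nb_zero(mu: np.ndarray, theta: float) -> np.ndarray:
    return (theta / (theta + mu)) ** theta


def _fit_mle(model, starts, label: str):
    """Try several optimizer runs; return the best converged result."""
    best = None
    trace = []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for start, method in starts:
            try:
                res = model.fit(
                    start_params=start, method=method, maxiter=5000, disp=0
                )
            except Exception as exc:  # noqa: BLE001 - collected into the trace
                trace.append(f"{method}: {exc!r}")
                continue
            converged = res.mle_retvals.get("converged", True)
            llf = res.llf
            trace.append(f"{method}: llf={llf:.4f} converged={converged}")
            if np.isfinite(llf) and converged:
                if best is None or llf > best.llf + 1e-9:
                    best = res
        if best is None:
            # fall back to the best finite-likelihood run even if the
            # optimizer did not flag convergence
            for start, method in starts:
                try:
                    res = model.fit(
                        start_params=start, method=method, maxiter=20000, disp=0
                    )
                except Exception:  # noqa: BLE001
                    continue
                if np.isfinite(res.llf) and (best is None or res.llf > best.llf):
                    best = res
    if best is None:
        raise ConvergenceError(f"{label} fit failed; optimizer trace: {trace}")
    return best


def fit_count_model(
    pairs: Sequence[PairedObservation] | tuple[np.ndarray, np.ndarray],
    family: Family | str,
    *,
    response: str = "trap",
    intercept_only: bool = False,
) -> CountModelFit:
    """Maximum-likelihood fit of one family.

    By default models the trap count on the soil count.  ``response``
    selects which method's count is the response; ``intercept_only``
    drops the predictor (used for per-method abundance estimates).
    Accepts complete-case pairs or a ``(soil, trap)`` array tuple.
    """
    fam = Family(family)
    x, y = _extract_arrays(pairs, response)
    X = np.ones((x.size, 1)) if intercept_only else sm.add_constant(x)
    if not intercept_only and np.ptp(x) == 0:
        raise DataError("constant predictor: fit the intercept-only design instead")

    if fam is Family.lm:
        fit = _fit_lm(y, X)
    elif fam in (Family.poisson, Family.quasipoisson):
        fit = _fit_poisson(fam, y, X)
    elif fam is Family.negbin:
        fit = _fit_negbin(y, X)
    elif fam in _ZERO_INFLATED:
        fit = _fit_zero_inflated(fam, y, X)
    elif fam is Family.hurdle_nb:
        fit = _fit_hurdle(y, X)
    else:
        raise DataError(f"unknown family {family!r}")
    fit.predictor = x
    fit.response = y
    fit.intercept_only = intercept_only
    return fit


def _coefs(params: np.ndarray, ncols: int) -> tuple[float, float]:
    a = float(params[0])
    b = float(params[1]) if ncols == 2 else 0.0
    return a, b


def _slope_stats(res, offset: int, ncols: int) -> tuple[float, float, float]:
    """(intercept_se, slope_se, slope_p) for a count part starting at ``offset``."""
    if ncols == 2:
        return (
            float(res.bse[offset]),
            float(res.bse[offset + 1]),
            float(res.pvalues[offset + 1]),
        )
    return float(res.bse[offset]), math.nan, math.nan


def _finish(fam, y, X, mu, var, zero_prob, *, loglik, k, extra) -> CountModelFit:
    n = y.size
    aic = bic = None
    if loglik is not None:
        aic = -2 * loglik + 2 * k
        bic = -2 * loglik + k * math.log(n)
    dispersion = None
    if var is not None:
        with np.errstate(divide="ignore", invalid="ignore"):
            pearson = np.sum((y - mu) ** 2 / var)
        dispersion = float(pearson / (n - k))
    return CountModelFit(
        family=fam,
        nobs=n,
        fitted_mean=np.asarray(mu, dtype=float),
        zero_prob=np.asarray(zero_prob, dtype=float) if zero_prob is not None else np.array([]),
        loglik=loglik,
        aic=aic,
        bic=bic,
        dispersion_stat=dispersion,
        n_params=k,
        **extra,
    )


def _fit_lm(y, X) -> CountModelFit:
    res = sm.OLS(y, X).fit()
    ncols = X.shape[1]
    a, b = _coefs(res.params, ncols)
    i_se, b_se, b_p = _slope_stats(res, 0, ncols)
    return _finish(
        Family.lm, y, X, res.fittedvalues, None, None,
        loglik=float(res.llf), k=ncols + _EXTRA_PARAMS[Family.lm],
        extra=dict(intercept=a, slope=b, intercept_se=i_se, slope_se=b_se, slope_p=b_p),
    )


def _fit_poisson(fam, y, X) -> CountModelFit:
    res = Poisson(y, X).fit(disp=0)
    ncols = X.shape[1]
    a, b = _coefs(res.params, ncols)
    mu = np.exp(X @ res.params)
    k = ncols + _EXTRA_PARAMS[Family.poisson]
    i_se, b_se, b_p = _slope_stats(res, 0, ncols)
    loglik = float(res.llf)
    if fam is Family.quasipoisson:
        # quasi-likelihood: Poisson point estimates, dispersion-scaled SEs,
        # no true likelihood
        phi = float(np.sum((y - mu) ** 2 / mu) / (y.size - k))
        scale = math.sqrt(phi)
        i_se *= scale
        if ncols == 2:
            b_se *= scale
            b_p = float(2 * stats.norm.sf(abs(b / b_se)))
        loglik = None
    return _finish(
        fam, y, X, mu, mu, np.exp(-mu),
        loglik=loglik, k=k,
        extra=dict(intercept=a, slope=b, intercept_se=i_se, slope_se=b_se, slope_p=b_p),
    )


def _fit_negbin(y, X) -> CountModelFit:
    model = NegativeBinomial(y, X, loglike_method="nb2")
    res = _fit_mle(model, [(None, "bfgs"), (None, "nm")], "negbin")
    ncols = X.shape[1]
    a, b = _coefs(res.params, ncols)
    theta, capped = _theta_from_alpha(float(res.params[ncols]))
    mu = np.exp(X @ res.params[:ncols])
    var = mu + mu**2 / theta
    i_se, b_se, b_p = _slope_stats(res, 0, ncols)
    return _finish(
        Family.negbin, y, X, mu, var, _nb_zero(mu, theta),
        loglik=float(res.llf), k=ncols + _EXTRA_PARAMS[Family.negbin],
        extra=dict(
            intercept=a, slope=b, intercept_se=i_se, slope_se=b_se, slope_p=b_p,
            theta=theta, theta_capped=capped,
        ),
    )


def _theta_from_alpha(alpha: float) -> tuple[float, bool]:
    if alpha <= 1.0 / THETA_CAP:
        warnings.warn(
            "NB size parameter diverging (equidispersion); theta capped",
            RuntimeWarning,
            stacklevel=3,
        )
        return THETA_CAP, True
    return 1.0 / alpha, False


def _zi_starts(y, X, with_alpha: bool):
    """Starting points for zero-inflated fits: the optimizer default plus
    method-of-moments candidates (guarded against degenerate pre-fits)."""
    ncols = X.shape[1]
    count0 = np.zeros(ncols)
    count0[0] = math.log(max(y.mean(), 1e-3))
    try:
        res_p = Poisson(y, X).fit(disp=0)
        cand = np.asarray(res_p.params, dtype=float)
        if np.all(np.isfinite(cand)) and np.all(np.abs(cand) < 10):
            count0 = cand
    except Exception:  # noqa: BLE001 - fall back to the flat start
        pass
    zero_share = float(np.mean(y == 0))
    mu0 = np.exp(np.clip(X @ count0, -30, 30))
    base_zero = float(np.mean(np.exp(-mu0)))
    pi0 = max(0.02, min(0.8, (zero_share - base_zero) / max(1e-9, 1 - base_zero)))
    m, v = y.mean(), y.var()
    alpha0 = float(np.clip((v - m) / max(m**2, 1e-9), 0.1, 5.0))
    starts = [(None, "bfgs"), (None, "nm")]
    for pi_start in (pi0, 0.1, 0.4):
        g = special.logit(pi_start)
        params = np.r_[g, count0, alpha0] if with_alpha else np.r_[g, count0]
        starts.append((params, "bfgs"))
        starts.append((params, "nm"))
    return starts


def _fit_zero_inflated(fam, y, X) -> CountModelFit:
    infl = np.ones((y.size, 1))
    ncols = X.shape[1]
    if fam is Family.zip:
        model = ZeroInflatedPoisson(y, X, exog_infl=infl)
        starts = _zi_starts(y, X, with_alpha=False)
    else:
        model = ZeroInflatedNegativeBinomialP(y, X, exog_infl=infl, p=2)
        starts = _zi_starts(y, X, with_alpha=True)
    res = _fit_mle(model, starts, fam.value)

    pi = float(special.expit(res.params[0]))
    count_params = np.asarray(res.params[1 : 1 + ncols], dtype=float)
    a, b = _coefs(count_params, ncols)
    mu = np.exp(X @ count_params)
    i_se, b_se, b_p = _slope_stats(res, 1, ncols)
    if fam is Family.zip:
        theta, capped = None, False
        var = (1 - pi) * mu * (1 + pi * mu)
        zero = pi + (1 - pi) * np.exp(-mu)
    else:
        theta, capped = _theta_from_alpha(float(res.params[1 + ncols]))
        var = (1 - pi) * mu * (1 + mu / theta + pi * mu)
        zero = pi + (1 - pi) * _nb_zero(mu, theta)
    k = ncols + _EXTRA_PARAMS[fam]
    return _finish(
        fam, y, X, (1 - pi) * mu, var, zero,
        loglik=float(res.llf), k=k,
        extra=dict(
            intercept=a, slope=b, intercept_se=i_se, slope_se=b_se, slope_p=b_p,
            theta=theta, theta_capped=capped, zi_prob=pi,
        ),
    )


def _fit_hurdle(y, X) -> CountModelFit:
    """Two-part hurdle: logit detection (y > 0) + zero-truncated NB for positives."""
    positive = y > 0
    if positive.sum() < 5 or (~positive).sum() < 1:
        raise DataError("hurdle fit needs both zero and positive outcomes")
    ncols = X.shape[1]
    logit_res = Logit(positive.astype(float), X).fit(disp=0)
    g = np.asarray(logit_res.params, dtype=float)
    p_detect = special.expit(X @ g)

    trunc = TruncatedLFNegativeBinomialP(y[positive], X[positive], truncation=0, p=2)
    res = _fit_mle(trunc, [(None, "bfgs"), (None, "nm")], "truncated NB")
    a, b = _coefs(res.params, ncols)
    theta, capped = _theta_from_alpha(float(res.params[ncols]))
    i_se, b_se, b_p = _slope_stats(res, 0, ncols)

    mu_nb = np.exp(X @ np.asarray(res.params[:ncols], dtype=float))
    p0_nb = _nb_zero(mu_nb, theta)
    trunc_mean = mu_nb / (1 - p0_nb)
    trunc_m2 = (mu_nb + mu_nb**2 * (1 + 1 / theta)) / (1 - p0_nb)
    mean = p_detect * trunc_mean
    var = p_detect * trunc_m2 - mean**2
    loglik = float(logit_res.llf + res.llf)
    # structural-zero share implied by the detection part
    zi_prob = float(np.mean(1 - p_detect))
    g0 = float(g[0])
    g1 = float(g[1]) if ncols == 2 else 0.0
    k = 2 * ncols + 1  # logit coefs + truncated-NB coefs + theta
    return _finish(
        Family.hurdle_nb, y, X, mean, var, 1 - p_detect,
        loglik=loglik, k=k,
        extra=dict(
            intercept=a, slope=b, intercept_se=i_se, slope_se=b_se, slope_p=b_p,
            theta=theta, theta_capped=capped, zi_prob=zi_prob,
            binary_coef=(g0, g1),
        ),
    )


def compare_models(fits: Sequence[CountModelFit]) -> pd.DataFrame:
    """Rank fits by AIC; quasi-likelihood fits are listed without AIC/BIC.

    All fits must be on the same observations.  The returned frame is
    sorted ascending by AIC (likelihood-based fits first) and carries a
    ``delta_aic`` column relative to the best model.
    """
    if len(fits) < 2:
        raise DataError("need at least two fits to compare")
    ref = fits[0].response
    for f in fits[1:]:
        if f.response.shape != ref.shape or not np.array_equal(f.response, ref):
            raise DataError("fits were made on differing observation sets")
    rows = [
        {
            "family": f.family.value,
            "aic": f.aic,
            "bic": f.bic,
            "loglik": f.loglik,
            "dispersion": f.dispersion_stat,
            "zero_inflation": f.zi_prob,
            "theta": f.theta,
            "slope": f.slope,
            "slope_p": f.slope_p,
        }
        for f in fits
    ]
    df = pd.DataFrame(rows)
    df = df.sort_values("aic", na_position="last").reset_index(drop=True)
    best = df["aic"].min()
    df["delta_aic"] = df["aic"] - best
    return df


def validate_fit(
    fit: CountModelFit,
    pairs: Sequence[PairedObservation] | tuple[np.ndarray, np.ndarray] | None = None,
) -> ValidationMetrics:
    """Goodness-of-fit of a fitted model against its own observations.

    RMSE and the mean absolute deviation compare observed counts with the
    fitted marginal means ((1 - pi) * mu for zero-inflated families).
    The predicted zero frequency averages each observation's model
    P(Y = 0).  The IRR is exp(slope): the multiplicative change in the
    expected count per additional larva in the predictor.
    """
    if pairs is None:
        x, y = fit.predictor, fit.response
    else:
        x, y = _extract_arrays(pairs, "trap")
        if x.shape != fit.predictor.shape or not np.allclose(x, fit.predictor):
            raise DataError("fit and pairs are not aligned")
    yhat = fit.fitted_mean
    resid = y - yhat
    rmse = float(np.sqrt(np.mean(resid**2)))
    mad = float(np.mean(np.abs(resid)))
    corr = None if np.ptp(yhat) == 0 else float(np.corrcoef(yhat, y)[0, 1])
    zero_pred = float(np.mean(fit.zero_prob)) if fit.zero_prob.size else None
    return ValidationMetrics(
        rmse=rmse,
        mad_mean=mad,
        corr_pred_obs=corr,
        zero_freq_observed=float(np.mean(y == 0)),
        zero_freq_predicted=zero_pred,
        irr=float(np.exp(fit.slope)),
    )


def predict_mean(fit: CountModelFit, soil: float) -> float:
    """Expected response count at a given predictor (soil) count.

    ``(1 - pi) * exp(a + b * soil)`` for zero-inflated families,
    ``exp(a + b * soil)`` otherwise (identity link for the linear model).
    """
    if soil < 0:
        raise DataError("soil count must be >= 0")
    if fit.family is Family.lm:
        return float(fit.intercept + fit.slope * soil)
    mu = math.exp(fit.intercept + fit.slope * soil)
    if fit.family in _ZERO_INFLATED:
        return float((1 - fit.zi_prob) * mu)
    if fit.family is Family.hurdle_nb:
        g0, g1 = fit.binary_coef
        p_detect = special.expit(g0 + g1 * soil)
        p0 = float(_nb_zero(np.array([mu]), fit.theta)[0])
        return float(p_detect * mu / (1 - p0))
    return float(mu)
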