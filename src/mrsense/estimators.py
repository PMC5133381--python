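"""Causal-effect estimators for two-sample summarized Mendelian randomization.

Notation (per variant j): gamma_j is the association with the exposure,
Gamma_j the association with the outcome, and theta_j = Gamma_j / gamma_j
the variant's ratio (Wald) estimate of the causal effect theta.  Weights
w_j = se(theta_j)^-2 use the first-order standard error
se(theta_j) = se_outcome_j / gamma_j by default, which makes the
inverse-variance weighted (IVW) average of the ratio estimates exactly the
weighted regression of Gamma on gamma through the origin with weights
se_outcome^-2.

Estimators
----------
ratio_estimates   per-variant ratio estimates, SEs and weights
ivw               inverse-variance weighted estimate (fixed or multiplicative
                  random-effects)
egger             Egger regression: slope = pleiotropy-adjusted causal
                  estimate under InSIDE, intercept = average directional
                  pleiotropy
simple_median     median of the per-variant ratio estimates (consistent when
                  >50% of variants are valid instruments)
weighted_median   median of the inverse-variance-weighted empirical
                  distribution of ratio estimates (consistent when valid
                  instruments carry >50% of the weight)
multivariable_ivw weighted multivariable regression across K exposures
to_odds_ratio     rescale a log-odds estimate to an odds ratio per SD of the
                  exposure

The multiplicative random-effects model keeps the fixed-effect point
estimate and inflates standard errors by sqrt(phi), where phi is the
residual dispersion (Cochran's Q over its degrees of freedom) truncated
below at 1.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
from scipy import stats

from .data import SummaryDataset, as_arrays
from .errors import EstimationError, InsufficientVariantsError, NotIdentifiedError

__all__ = [
    "RatioEstimate",
    "MREstimate",
    "OddsRatio",
    "ratio_estimates",
    "ivw",
    "egger",
    "simple_median",
    "weighted_median",
    "multivariable_ivw",
    "to_odds_ratio",
    "get_estimator",
]

_Z975 = stats.norm.ppf(0.975)


@dataclass(frozen=True)
class RatioEstimate:
    """Causal estimate from a single variant: theta_j, its SE and IV weight."""

    variant_id: str
    theta: float
    se: float
    weight: float  # = se**-2

    def __post_init__(self) -> None:
        if not self.se > 0:
            raise EstimationError(f"{self.variant_id}: ratio SE must be > 0")


@dataclass(frozen=True)
class MREstimate:
    """A method's causal estimate with normal-approximation CI and p-value."""

    method: str
    model: str  # "fixed" | "multiplicative_random" | "not_applicable"
    beta: float
    se: float
    ci_low: float
    ci_high: float
    p_value: float
    n_variants: int
    exposure: str | None = None  # which exposure, for multivariable results
    intercept: float | None = None
    intercept_se: float | None = None
    intercept_ci: tuple[float, float] | None = None
    intercept_p: float | None = None
    dispersion: float | None = None  # variance-inflation factor phi
    outcome_scale: str = "linear"

    def __post_init__(self) -> None:
        if not (self.ci_low <= self.beta <= self.ci_high):
            raise EstimationError("CI does not bracket the point estimate")
        if self.model == "fixed" and self.dispersion not in (None, 1.0):
            raise EstimationError("fixed-effect model cannot carry dispersion != 1")


@dataclass(frozen=True)
class OddsRatio:
    """Odds ratio per 1-SD increase in the exposure, with 95% CI."""

    odds_ratio: float
    ci_low: float
    ci_high: float


def _require_oriented(data: SummaryDataset) -> None:
    if not data.oriented:
        raise EstimationError(
            "dataset is not oriented; apply orient_to_exposure() first"
        )
    if any(v.beta_exposure <= 0 for v in data.variants):
        raise EstimationError("oriented dataset must have every beta_exposure > 0")


def _normal_summary(beta: float, se: float) -> tuple[float, float, float]:
    z = beta / se
    p = float(2.0 * stats.norm.sf(abs(z)))
    return float(beta - _Z975 * se), float(beta + _Z975 * se), p


def ratio_estimates(data: SummaryDataset, *, second_order: bool = False) -> list[RatioEstimate]:
    """Per-variant ratio estimates theta_j = beta_outcome_j / beta_exposure_j.

    The default SE is first order, se_outcome_j / beta_exposure_j, which
    ties the IVW average exactly to the through-origin weighted regression.
    ``second_order=True`` adds the delta-method term for the uncertainty of
    the exposure association:
    sqrt(se_outcome^2/beta_exposure^2 + beta_outcome^2 se_exposure^2/beta_exposure^4).
    """
    _require_oriented(data)
    out = []
    for v in data.variants:
        theta = v.beta_outcome / v.beta_exposure
        se = v.se_outcome / v.beta_exposure
        if second_order:
            se = math.sqrt(
                v.se_outcome**2 / v.beta_exposure**2
                + v.beta_outcome**2 * v.se_exposure**2 / v.beta_exposure**4
            )
        out.append(RatioEstimate(v.variant_id, theta, se, se**-2))
    return out


def _ivw_core(theta: np.ndarray, weight: np.ndarray) -> tuple[float, float, float]:
    """Weighted mean, its fixed-effect SE, and Cochran's Q about the mean."""
    wsum = float(weight.sum())
    beta = float((weight * theta).sum() / wsum)
    se = wsum**-0.5
    q = float((weight * (theta - beta) ** 2).sum())
    return beta, se, q


def ivw(data: SummaryDataset, model: str = "fixed", *, second_order: bool = False) -> MREstimate:
    """Inverse-variance weighted causal estimate.

    ``model="fixed"`` assumes every variant estimates the same effect with
    no excess heterogeneity; ``model="multiplicative_random"`` keeps the
    same point estimate and inflates the SE by sqrt(phi) with
    phi = max(1, Q/(J-1)).
    """
    if model not in ("fixed", "multiplicative_random"):
        raise EstimationError(f"unknown model {model!r}")
    ratios = ratio_estimates(data, second_order=second_order)
    j = len(ratios)
    theta = np.array([r.theta for r in ratios])
    weight = np.array([r.weight for r in ratios])
    beta, se, q = _ivw_core(theta, weight)
    dispersion = None
    if model == "multiplicative_random":
        if j < 2:
            raise EstimationError("multiplicative random-effects model needs >= 2 variants")
        dispersion = max(1.0, q / (j - 1))
        se *= math.sqrt(dispersion)
    lo, hi, p = _normal_summary(beta, se)
    return MREstimate(
        method="ivw", model=model, beta=beta, se=se, ci_low=lo, ci_high=hi,
        p_value=p, n_variants=j, dispersion=dispersion, outcome_scale=data.outcome_scale,
    )


def _wls(x: np.ndarray, y: np.ndarray, w: np.ndarray) -> tuple[np.ndarray, np.ndarray, float]:
    """Weighted least squares via the normal equations.

    Returns (coefficients, unscaled covariance (X'WX)^-1, weighted RSS).
    The unscaled covariance is the fixed-effect covariance when the weights
    are true inverse variances; the multiplicative random-effects model
    scales it by the dispersion factor.
    """
    xtw = x.T * w
    xtwx = xtw @ x
    cond = np.linalg.cond(xtwx)
    if not np.isfinite(cond) or cond > 1e12:
        raise NotIdentifiedError(
            "design matrix is (near-)singular: no spread in instrument strength, "
            "so the estimate in this case would not be identified"
        )
    cov = np.linalg.inv(xtwx)
    coef = cov @ (xtw @ y)
    resid = y - x @ coef
    rss = float((w * resid**2).sum())
    return coef, cov, rss


def egger(data: SummaryDataset, model: str = "fixed") -> MREstimate:
    """Egger regression: weighted regression of outcome associations on
    exposure associations *with* an intercept.

    The slope estimates the causal effect consistently under the InSIDE
    assumption (pleiotropic effects independent of instrument strengths);
    the intercept estimates the average pleiotropic effect, and its test
    against zero is the test for directional pleiotropy.  Requires J >= 3
    and spread in the exposure associations: with identical instrument
    strengths the slope and intercept are not separable.
    """
    if model not in ("fixed", "multiplicative_random"):
        raise EstimationError(f"unknown model {model!r}")
    _require_oriented(data)
    j = len(data)
    if j < 3:
        raise InsufficientVariantsError(f"Egger regression needs >= 3 variants, got {j}")
    arr = as_arrays(data)
    if np.ptp(arr.bx) <= 1e-12 * np.abs(arr.bx).max():
        raise NotIdentifiedError(
            "all exposure associations are equal (no spread in instrument "
            "strength); the Egger estimate in this case would not be identified"
        )
    w = arr.sy**-2.0
    x = np.column_stack([np.ones(j), arr.bx])
    coef, cov, rss = _wls(x, arr.by, w)
    scale = 1.0
    dispersion = None
    if model == "multiplicative_random":
        dispersion = max(1.0, rss / (j - 2))
        scale = dispersion
    se = np.sqrt(scale * np.diag(cov))
    lo, hi, p = _normal_summary(float(coef[1]), float(se[1]))
    ilo, ihi, ip = _normal_summary(float(coef[0]), float(se[0]))
    return MREstimate(
        method="egger", model=model, beta=float(coef[1]), se=float(se[1]),
        ci_low=lo, ci_high=hi, p_value=p, n_variants=j,
        intercept=float(coef[0]), intercept_se=float(se[0]),
        intercept_ci=(ilo, ihi), intercept_p=ip,
        dispersion=dispersion, outcome_scale=data.outcome_scale,
    )


def _weighted_median(theta: np.ndarray, weight: np.ndarray, ids: Sequence[str] | None = None) -> float:
    """Median of the weighted empirical distribution of ratio estimates.

    Sort theta ascending (ties broken by variant id for reproducibility),
    form cumulative midpoint probabilities S_j = sum_{k<=j} w'_k - w'_j/2
    with normalized weights w', and linearly interpolate between the two
    estimates whose S brackets 0.5.
    """
    if ids is None:
        order = np.argsort(theta, kind="stable")
    else:
        order = np.lexsort((np.asarray(ids, dtype=object), theta))
    t = theta[order]
    w = weight[order] / weight.sum()
    s = np.cumsum(w) - 0.5 * w
    if s[0] >= 0.5:
        return float(t[0])
    if s[-1] <= 0.5:
        return float(t[-1])
    below = int(np.searchsorted(s, 0.5, side="right")) - 1
    frac = (0.5 - s[below]) / (s[below + 1] - s[below])
    return float(t[below] + frac * (t[below + 1] - t[below]))


def _median_bootstrap_se(
    data: SummaryDataset, weighted: bool, n_boot: int, seed: int
) -> float:
    """Parametric bootstrap SE: resample both association sets from normal
    sampling distributions (independently, as in the two-sample design) and
    recompute the median estimate."""
    arr = as_arrays(data)
    rng = np.random.default_rng(seed)
    bx = rng.normal(arr.bx, arr.sx, size=(n_boot, len(arr.bx)))
    by = rng.normal(arr.by, arr.sy, size=(n_boot, len(arr.by)))
    theta = by / bx
    se_theta = arr.sy / np.abs(bx)
    weights = se_theta**-2.0 if weighted else np.ones_like(theta)
    est = np.empty(n_boot)
    for b in range(n_boot):
        est[b] = _weighted_median(theta[b], weights[b])
    return float(est.std(ddof=1))


def _median_estimate(
    data: SummaryDataset, weighted: bool, n_boot: int, seed: int
) -> MREstimate:
    _require_oriented(data)
    if len(data) < 3:
        raise InsufficientVariantsError(
            f"median-based methods need >= 3 variants, got {len(data)}"
        )
    if n_boot < 1:
        raise EstimationError("n_boot must be >= 1")
    ratios = ratio_estimates(data)
    theta = np.array([r.theta for r in ratios])
    weight = (
        np.array([r.weight for r in ratios]) if weighted else np.ones(len(ratios))
    )
    beta = _weighted_median(theta, weight, ids=data.variant_ids)
    se = _median_bootstrap_se(data, weighted, n_boot, seed)
    lo, hi, p = _normal_summary(beta, se)
    return MREstimate(
        method="weighted_median" if weighted else "simple_median",
        model="not_applicable", beta=beta, se=se, ci_low=lo, ci_high=hi,
        p_value=p, n_variants=len(data), outcome_scale=data.outcome_scale,
    )


def simple_median(data: SummaryDataset, n_boot: int = 1000, seed: int = 0) -> MREstimate:
    """Unweighted median of the per-variant ratio estimates.

    Consistent when more than half of the variants are valid instruments.
    The SE comes from a seeded parametric bootstrap of the summary
    associations.
    """
    return _median_estimate(data, weighted=False, n_boot=n_boot, seed=seed)


def weighted_median(data: SummaryDataset, n_boot: int = 1000, seed: int = 0) -> MREstimate:
    """Inverse-variance weighted median of the per-variant ratio estimates.

    Consistent when valid instruments carry more than half of the total
    weight.  SE from the same parametric bootstrap as :func:`simple_median`.
    """
    return _median_estimate(data, weighted=True, n_boot=n_boot, seed=seed)


def multivariable_ivw(data: SummaryDataset, model: str = "fixed") -> list[MREstimate]:
    """Multivariable IVW: regress outcome associations on all K exposure
    association columns jointly (no intercept), weights se_outcome^-2.

    Each exposure's coefficient is its direct causal effect conditional on
    the other exposures.  Requires J >= K + 1 and a full-rank exposure
    matrix.  With K = 1 this reduces exactly to :func:`ivw`.
    """
    if model not in ("fixed", "multiplicative_random"):
        raise EstimationError(f"unknown model {model!r}")
    _require_oriented(data)
    arr = as_arrays(data)
    j = len(data)
    k = data.n_exposures
    if j <= k:
        raise InsufficientVariantsError(
            f"multivariable IVW needs more variants ({j}) than exposures ({k})"
        )
    x = arr.bx[:, None] if arr.covariates is None else np.column_stack([arr.bx, arr.covariates])
    if np.linalg.matrix_rank(x) < k:
        raise NotIdentifiedError("exposure-association matrix is rank deficient")
    w = arr.sy**-2.0
    coef, cov, rss = _wls(x, arr.by, w)
    dispersion = None
    scale = 1.0
    if model == "multiplicative_random":
        dispersion = max(1.0, rss / (j - k))
        scale = dispersion
    se = np.sqrt(scale * np.diag(cov))
    labels = [data.exposure_label] + [f"{data.exposure_label}{i}" for i in range(2, k + 1)]
    out = []
    for i in range(k):
        lo, hi, p = _normal_summary(float(coef[i]), float(se[i]))
        out.append(
            MREstimate(
                method="multivariable_ivw", model=model, beta=float(coef[i]),
                se=float(se[i]), ci_low=lo, ci_high=hi, p_value=p,
                n_variants=j, exposure=labels[i], dispersion=dispersion,
                outcome_scale=data.outcome_scale,
            )
        )
    return out


def to_odds_ratio(estimate: MREstimate, exposure_sd: float) -> OddsRatio:
    """Convert a log-odds causal estimate to an odds ratio per 1-SD increase
    in the exposure: OR = exp(beta * exposure_sd), CI endpoints likewise."""
    if estimate.outcome_scale != "log_odds":
        raise EstimationError("to_odds_ratio requires an estimate on the log-odds scale")
    if not exposure_sd > 0:
        raise EstimationError("exposure_sd must be > 0")
    return OddsRatio(
        odds_ratio=math.exp(estimate.beta * exposure_sd),
        ci_low=math.exp(estimate.ci_low * exposure_sd),
        ci_high=math.exp(estimate.ci_high * exposure_sd),
    )


#: Registry mapping method-selector strings to estimator callables.
_METHODS = {
    "ivw": lambda data, seed=None, **kw: ivw(data, model="fixed", **kw),
    "ivw_random": lambda data, seed=None, **kw: ivw(data, model="multiplicative_random", **kw),
    "egger": lambda data, seed=None, **kw: egger(data, model="fixed", **kw),
    "egger_random": lambda data, seed=None, **kw: egger(data, model="multiplicative_random", **kw),
    "simple_median": lambda data, seed=0, **kw: simple_median(data, seed=seed or 0, **kw),
    "weighted_median": lambda data, seed=0, **kw: weighted_median(data, seed=seed or 0, **kw),
}


def get_estimator(method: str, **fixed_kwargs):
    """Resolve a method-selector string to ``f(data, seed=None) -> MREstimate``.

    Known selectors: ``ivw``, ``ivw_random``, ``egger``, ``egger_random``,
    ``simple_median``, ``weighted_median``.  ``fixed_kwargs`` (e.g.
    ``n_boot``) are bound into the callable.
    """
    if callable(method):
        return method
    if method not in _METHODS:
        raise EstimationError(
            f"unknown method {method!r}; choose from {sorted(_METHODS)}"
        )
    base = _METHODS[method]

    def estimator(data: SummaryDataset, seed: int | None = None) -> MREstimate:
        return base(data, seed=seed, **fixed_kwargs)

    estimator.__name__ = method
    return estimator
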