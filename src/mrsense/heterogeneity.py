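"""Heterogeneity diagnostics: Cochran's Q, I-squared, per-variant Q
contributions, outlier pruning, and the directional-pleiotropy test.

Under homogeneity (every variant a valid instrument for the same causal
effect), the per-variant ratio estimates scatter around the IVW estimate
only through sampling error and Q = sum_j w_j (theta_j - theta_IVW)^2
follows chi-squared with J-1 degrees of freedom.  Excess heterogeneity is
a symptom of invalid instruments (e.g. pleiotropy); a variant whose own
contribution q_j exceeds the upper 95th percentile of chi-squared(1)
(3.84) is a candidate outlier.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .data import SummaryDataset
from .errors import EstimationError, InsufficientVariantsError
from .estimators import MREstimate, egger, ratio_estimates

__all__ = [
    "HeterogeneityResult",
    "PleiotropyTest",
    "cochran_q",
    "prune_outliers",
    "directional_pleiotropy_test",
    "DEFAULT_PRUNE_THRESHOLD",
]

#: Upper 95th percentile of chi-squared on 1 df (= 3.84 to 2 dp).
DEFAULT_PRUNE_THRESHOLD = float(stats.chi2.ppf(0.95, df=1))


@dataclass(frozen=True)
class HeterogeneityResult:
    """Cochran's Q with df, p-value, I-squared, and per-variant contributions."""

    Q: float
    df: int
    p_value: float
    i_squared: float
    contributions: tuple[tuple[str, float], ...]

    def contribution(self, variant_id: str) -> float:
        for vid, q in self.contributions:
            if vid == variant_id:
                return q
        raise KeyError(variant_id)


@dataclass(frozen=True)
class PleiotropyTest:
    """Egger intercept test for directional pleiotropy."""

    estimate: float
    se: float
    ci_low: float
    ci_high: float
    p_value: float
    model: str
    n_variants: int


def cochran_q(data: SummaryDataset, *, second_order: bool = False) -> HeterogeneityResult:
    """Cochran's Q test of homogeneity of the per-variant causal estimates.

    Q = sum_j w_j (theta_j - theta_IVW)^2 with w_j the inverse-variance
    weights of the ratio estimates; p from the upper tail of
    chi-squared(J-1).  I-squared = max(0, (Q - df)/Q) expresses the share
    of the variability beyond chance (0 when Q == 0).
    """
    if len(data) < 2:
        raise InsufficientVariantsError("heterogeneity needs >= 2 variants")
    ratios = ratio_estimates(data, second_order=second_order)
    theta = np.array([r.theta for r in ratios])
    weight = np.array([r.weight for r in ratios])
    beta = float((weight * theta).sum() / weight.sum())
    contrib = weight * (theta - beta) ** 2
    q = float(contrib.sum())
    df = len(data) - 1
    p = float(stats.chi2.sf(q, df))
    i2 = 0.0 if q == 0 else max(0.0, (q - df) / q)
    return HeterogeneityResult(
        Q=q, df=df, p_value=p, i_squared=i2,
        contributions=tuple(zip(data.variant_ids, contrib.tolist())),
    )


def prune_outliers(
    data: SummaryDataset,
    threshold: float = DEFAULT_PRUNE_THRESHOLD,
    iterative: bool = False,
) -> tuple[SummaryDataset, list[str]]:
    """Remove variants whose Q contribution exceeds ``threshold``.

    Default single pass: contributions are computed once on the full
    dataset and every offender is removed together.  ``iterative=True``
    instead removes the single largest offender and recomputes, repeating
    until no contribution exceeds the threshold (single-pass pruning can
    mask co-outliers).  Returns the pruned dataset and the removed ids in
    removal order.
    """
    if len(data) < 3:
        raise InsufficientVariantsError("outlier pruning needs >= 3 variants")
    removed: list[str] = []
    current = data
    while True:
        het = cochran_q(current)
        offenders = [(vid, q) for vid, q in het.contributions if q > threshold]
        if not offenders:
            break
        if iterative:
            batch = [max(offenders, key=lambda t: t[1])[0]]
        else:
            batch = [vid for vid, _ in offenders]
        if len(current) - len(batch) < 2:
            raise EstimationError(
                "pruning would leave fewer than 2 variants; removal trail: "
                + ", ".join(removed + batch)
            )
        removed.extend(batch)
        current = current.drop(batch)
        if not iterative:
            break
    return current, removed


def directional_pleiotropy_test(
    data: SummaryDataset, model: str = "multiplicative_random"
) -> PleiotropyTest:
    """Test for directional pleiotropy via the Egger regression intercept.

    A nonzero intercept means the pleiotropic effects of the variants do
    not average to zero, so the IVW estimate is biased.  The default model
    is multiplicative random effects, since heterogeneity is expected
    whenever pleiotropy is present at all.
    """
    est: MREstimate = egger(data, model=model)
    return PleiotropyTest(
        estimate=est.intercept,
        se=est.intercept_se,
        ci_low=est.intercept_ci[0],
        ci_high=est.intercept_ci[1],
        p_value=est.intercept_p,
        model=model,
        n_variants=est.n_variants,
    )
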