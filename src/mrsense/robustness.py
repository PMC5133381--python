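"""Subset-robustness (penalization-by-omission) analyses.

A causal conclusion that depends on one or two genetic variants — rather
than being supported by the bulk of the instruments — is fragile to those
variants being invalid.  These procedures re-estimate the causal effect on
subsets of the variants: systematically leaving out every single variant
(leave-one-out), every k-subset (leave-k-out; with 17 variants and k = 2
that is C(17,2) = 136 estimates), or random subsets omitting a fixed
fraction of variants many times.  If the spread of subset estimates stays
on one side of the null, the finding does not hinge on a few variants.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from itertools import combinations
from typing import Callable, Iterable, Sequence

import numpy as np

from .data import SummaryDataset
from .errors import EstimationError, InsufficientVariantsError
from .estimators import MREstimate, get_estimator

__all__ = [
    "SubsetEstimate",
    "SubsetSummary",
    "leave_one_out",
    "leave_k_out",
    "random_subsets",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class SubsetEstimate:
    """One subset analysis: which variants were omitted and the result.

    ``estimate`` is None (and ``error`` set) when the estimator's
    preconditions failed on the reduced dataset; such subsets are flagged,
    never silently skipped.
    """

    omitted_ids: frozenset[str]
    estimate: MREstimate | None = None
    error: str | None = None

    @property
    def failed(self) -> bool:
        return self.estimate is None


@dataclass(frozen=True)
class SubsetSummary:
    """Collection of subset estimates with the sign-spread summary."""

    estimates: tuple[SubsetEstimate, ...]
    fraction_positive: float
    fraction_negative: float
    fraction_zero: float
    extremes: tuple[float, float]  # (min, max) over successful betas
    n_failed: int

    @property
    def betas(self) -> np.ndarray:
        """Successful subset betas, in enumeration order."""
        return np.array([s.estimate.beta for s in self.estimates if not s.failed])

    def sorted_estimates(self) -> list[SubsetEstimate]:
        """Successful estimates ordered by signed beta ascending (the
        ordered-by-magnitude presentation)."""
        ok = [s for s in self.estimates if not s.failed]
        return sorted(ok, key=lambda s: s.estimate.beta)


def _summarize(estimates: Sequence[SubsetEstimate]) -> SubsetSummary:
    ok = [s for s in estimates if not s.failed]
    n_failed = len(estimates) - len(ok)
    if n_failed:
        logger.warning("%d subset estimate(s) failed and are excluded from fractions", n_failed)
    if not ok:
        raise EstimationError("every subset estimate failed")
    betas = np.array([s.estimate.beta for s in ok])
    n = len(betas)
    return SubsetSummary(
        estimates=tuple(estimates),
        fraction_positive=float((betas > 0).sum() / n),
        fraction_negative=float((betas < 0).sum() / n),
        fraction_zero=float((betas == 0).sum() / n),
        extremes=(float(betas.min()), float(betas.max())),
        n_failed=n_failed,
    )


def _run_subsets(
    data: SummaryDataset,
    omissions: Iterable[tuple[str, ...]],
    estimator: Callable,
    seed: int | None = None,
) -> list[SubsetEstimate]:
    out = []
    for omit in omissions:
        reduced = data.drop(omit)
        try:
            est = estimator(reduced, seed=seed)
            out.append(SubsetEstimate(frozenset(omit), estimate=est))
        except EstimationError as exc:
            out.append(SubsetEstimate(frozenset(omit), error=str(exc)))
    return out


def leave_one_out(
    data: SummaryDataset, method: str | Callable = "ivw", **method_kwargs
) -> SubsetSummary:
    """Re-estimate omitting each variant in turn (J estimates, dataset order)."""
    if len(data) < 3:
        raise InsufficientVariantsError("leave-one-out needs >= 3 variants")
    estimator = get_estimator(method, **method_kwargs)
    subsets = _run_subsets(data, ((vid,) for vid in data.variant_ids), estimator)
    return _summarize(subsets)


def leave_k_out(
    data: SummaryDataset,
    k: int,
    method: str | Callable = "ivw",
    cap: int = 10**6,
    **method_kwargs,
) -> SubsetSummary:
    """Re-estimate on every subset omitting k variants (C(J, k) estimates).

    Subsets are enumerated in lexicographic order of variant position, so
    output order is deterministic.  ``cap`` bounds the combinatorial count;
    beyond it, use :func:`random_subsets` instead.
    """
    j = len(data)
    if k < 1:
        raise EstimationError("k must be >= 1")
    if j < k + 2:
        raise InsufficientVariantsError(f"leave-{k}-out needs >= {k + 2} variants, got {j}")
    n_subsets = math.comb(j, k)
    if n_subsets > cap:
        raise EstimationError(
            f"C({j},{k}) = {n_subsets} exceeds the cap ({cap}); use random_subsets"
        )
    estimator = get_estimator(method, **method_kwargs)
    subsets = _run_subsets(data, combinations(data.variant_ids, k), estimator)
    return _summarize(subsets)


def random_subsets(
    data: SummaryDataset,
    omit_fraction: float,
    n_reps: int,
    seed: int,
    method: str | Callable = "ivw",
    **method_kwargs,
) -> SubsetSummary:
    """Re-estimate on ``n_reps`` uniformly random subsets, each omitting
    round(J * omit_fraction) variants without replacement.

    Rounding is round-half-to-even.  Fully reproducible under a fixed
    ``seed`` (which also seeds any bootstrap inside the estimator).
    """
    j = len(data)
    if not 0 < omit_fraction < 1:
        raise EstimationError("omit_fraction must be strictly between 0 and 1")
    if n_reps < 1:
        raise EstimationError("n_reps must be >= 1")
    n_omit = round(j * omit_fraction)
    n_omit = max(1, n_omit)
    if j - n_omit < 2:
        raise EstimationError(
            f"omitting {n_omit} of {j} variants leaves too few for estimation"
        )
    estimator = get_estimator(method, **method_kwargs)
    rng = np.random.default_rng(seed)
    ids = np.array(data.variant_ids, dtype=object)
    omissions = [tuple(rng.choice(ids, size=n_omit, replace=False)) for _ in range(n_reps)]
    subsets = _run_subsets(data, omissions, estimator, seed=seed)
    return _summarize(subsets)
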