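"""Synthetic two-sample summarized MR data with known truth, and Monte
Carlo evaluation of estimator operating characteristics.

The generator works directly on the summary-statistic scale: per variant j
a true instrument strength gamma_j ~ Uniform(gamma_range) and a direct
(pleiotropic) effect alpha_j are drawn, the true outcome association is
Gamma_j = theta * gamma_j + alpha_j, and the observed associations are
independent normal draws around the truths (the two-sample structure:
exposure and outcome sampling errors are independent).

Pleiotropy architectures for the invalid variants:

``balanced``         alpha_j ~ Normal(0, scale^2): pleiotropy averages to
                     zero and is independent of instrument strength, so the
                     InSIDE assumption holds and IVW is unbiased though
                     over-dispersed.
``directional``      alpha_j ~ Uniform(0, scale): mean pleiotropy scale/2
                     biases IVW; InSIDE still holds, so the Egger slope is
                     consistent and its intercept detects the bias.
``inside_violated``  alpha_j correlated with gamma_j, breaking InSIDE and
                     biasing the Egger slope.

Default conditions emulate a GWAS with genome-wide significant instruments
(instrument F-statistics in the hundreds): gamma ~ U(0.1, 0.3),
se_exposure = 0.005, se_outcome = 0.05.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Callable, Sequence

import numpy as np

from .data import SummaryDataset, VariantAssociation
from .errors import EstimationError
from .estimators import get_estimator

__all__ = [
    "SimulationConfig",
    "TruthRecord",
    "OperatingCharacteristics",
    "simulate_dataset",
    "operating_characteristics",
    "replicate_seed",
]

_PLEIOTROPY_KINDS = ("none", "balanced", "directional", "inside_violated")


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for one synthetic two-sample MR dataset.

    Parameters
    ----------
    J
        Number of independent variants.
    theta
        True causal effect (outcome units per exposure unit).
    gamma_range
        (low, high) for the uniform draw of true instrument strengths;
        low > 0, so instruments are positively oriented by construction.
    se_exposure, se_outcome
        Sampling SDs of the observed associations; a scalar or per-variant
        sequence of length J.
    invalid_fraction
        Fraction of variants given a pleiotropic direct effect (the first
        ceil(J * fraction) by index; forced to 0 when pleiotropy == "none").
    pleiotropy
        "none", "balanced", "directional" or "inside_violated".
    pleiotropy_scale
        Scale of the direct effects (SD for balanced, upper bound for
        directional).
    inside_correlation
        For "inside_violated": sign/strength of the coupling between
        direct effects and centered instrument strengths.
    seed
        Seed for the dataset's random draws.
    """

    J: int = 50
    theta: float = 0.0
    gamma_range: tuple[float, float] = (0.1, 0.3)
    se_exposure: float | Sequence[float] = 0.005
    se_outcome: float | Sequence[float] = 0.05
    invalid_fraction: float = 0.0
    pleiotropy: str = "none"
    pleiotropy_scale: float = 0.1
    inside_correlation: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.J < 2:
            raise EstimationError("J must be >= 2")
        low, high = self.gamma_range
        if not (0 < low <= high):
            raise EstimationError("gamma_range must satisfy 0 < low <= high")
        if self.pleiotropy not in _PLEIOTROPY_KINDS:
            raise EstimationError(
                f"unknown pleiotropy kind {self.pleiotropy!r}; choose from {_PLEIOTROPY_KINDS}"
            )
        if self.pleiotropy_scale < 0:
            raise EstimationError("pleiotropy_scale must be >= 0")
        if not 0 <= self.invalid_fraction <= 1:
            raise EstimationError("invalid_fraction must be in [0, 1]")
        if not -1 <= self.inside_correlation <= 1:
            raise EstimationError("inside_correlation must be in [-1, 1]")
        for name in ("se_exposure", "se_outcome"):
            se = np.atleast_1d(np.asarray(getattr(self, name), dtype=float))
            if se.size not in (1, self.J) or not (se > 0).all():
                raise EstimationError(f"{name} must be > 0, scalar or length J")
        if self.pleiotropy == "none":
            object.__setattr__(self, "invalid_fraction", 0.0)


@dataclass(frozen=True)
class TruthRecord:
    """Ground truth behind one simulated dataset."""

    theta: float
    gamma: np.ndarray
    alpha: np.ndarray
    valid: np.ndarray  # boolean per variant

    @property
    def n_invalid(self) -> int:
        return int((~self.valid).sum())


@dataclass(frozen=True)
class OperatingCharacteristics:
    """Monte Carlo summary of one estimator under one configuration."""

    method: str
    n_sims: int
    rejection_rate: float
    mean_estimate: float
    bias: float
    rmse: float
    mc_se: float  # binomial MC standard error of the rejection rate
    mean_se: float
    n_failed: int = 0


def _broadcast(se, j: int) -> np.ndarray:
    arr = np.atleast_1d(np.asarray(se, dtype=float))
    return np.full(j, arr[0]) if arr.size == 1 else arr


def simulate_dataset(
    config: SimulationConfig, seed: int | None = None
) -> tuple[SummaryDataset, TruthRecord]:
    """Draw one synthetic dataset under ``config`` (``seed`` overrides
    ``config.seed``); returns the dataset and its truth record."""
    rng = np.random.default_rng(config.seed if seed is None else seed)
    j = config.J
    gamma = rng.uniform(*config.gamma_range, size=j)
    alpha = np.zeros(j)
    n_invalid = math.ceil(j * config.invalid_fraction) if config.pleiotropy != "none" else 0
    valid = np.ones(j, dtype=bool)
    valid[:n_invalid] = False
    if n_invalid:
        scale = config.pleiotropy_scale
        if config.pleiotropy == "balanced":
            alpha[:n_invalid] = rng.normal(0.0, scale, size=n_invalid)
        elif config.pleiotropy == "directional":
            alpha[:n_invalid] = rng.uniform(0.0, scale, size=n_invalid)
        elif config.pleiotropy == "inside_violated":
            centered = gamma[:n_invalid] - gamma.mean()
            alpha[:n_invalid] = (
                config.inside_correlation * centered * scale
                + rng.normal(0.0, scale / 2, size=n_invalid)
            )
    big_gamma = config.theta * gamma + alpha
    se_x = _broadcast(config.se_exposure, j)
    se_y = _broadcast(config.se_outcome, j)
    bx = rng.normal(gamma, se_x)
    by = rng.normal(big_gamma, se_y)  # independent draw: two-sample structure
    variants = tuple(
        VariantAssociation(
            variant_id=f"snp{i + 1:04d}",
            beta_exposure=float(bx[i]), se_exposure=float(se_x[i]),
            beta_outcome=float(by[i]), se_outcome=float(se_y[i]),
        )
        for i in range(j)
    )
    data = SummaryDataset(
        variants=variants,
        exposure_label="simulated exposure",
        outcome_label="simulated outcome",
        oriented=bool((bx > 0).all()),
    )
    return data, TruthRecord(theta=config.theta, gamma=gamma, alpha=alpha, valid=valid)


def replicate_seed(master_seed: int, index: int) -> int:
    """Deterministic per-replicate seed: replicate ``index`` of master seed
    ``master_seed`` can be regenerated in isolation."""
    return int(np.random.SeedSequence(master_seed, spawn_key=(index,)).generate_state(1)[0])


def operating_characteristics(
    config: SimulationConfig,
    method: str | Callable,
    n_sims: int,
    alpha: float = 0.05,
    seed: int | None = None,
    p_value_of: Callable | None = None,
    **method_kwargs,
) -> OperatingCharacteristics:
    """Monte Carlo rejection rate, bias and RMSE of an estimator.

    Each replicate simulates a fresh dataset (per-replicate seeds derived
    from ``seed`` via :func:`replicate_seed`), orients it, applies the
    estimator, and tests the two-sided p-value against ``alpha``.
    ``p_value_of`` can replace the estimate's own p-value with another
    test's (e.g. the Egger intercept test).  Failed replicates are counted
    and excluded from the averages.
    """
    from .data import orient_to_exposure

    if n_sims < 1:
        raise EstimationError("n_sims must be >= 1")
    if not 0 < alpha < 1:
        raise EstimationError("alpha must be in (0, 1)")
    master = config.seed if seed is None else seed
    estimator = get_estimator(method, **method_kwargs)
    betas, pvals, ses = [], [], []
    n_failed = 0
    for i in range(n_sims):
        rep_seed = replicate_seed(master, i)
        data, _ = simulate_dataset(config, seed=rep_seed)
        try:
            data = orient_to_exposure(data)
            est = estimator(data, seed=replicate_seed(master, n_sims + i))
        except EstimationError:
            n_failed += 1
            continue
        betas.append(est.beta)
        ses.append(est.se)
        pvals.append(p_value_of(est) if p_value_of is not None else est.p_value)
    if not betas:
        raise EstimationError("every simulation replicate failed")
    betas = np.array(betas)
    pvals = np.array(pvals)
    n_ok = len(betas)
    rejection = float((pvals < alpha).mean())
    name = method if isinstance(method, str) else getattr(method, "__name__", "custom")
    return OperatingCharacteristics(
        method=name,
        n_sims=n_sims,
        rejection_rate=rejection,
        mean_estimate=float(betas.mean()),
        bias=float(betas.mean() - config.theta),
        rmse=float(np.sqrt(((betas - config.theta) ** 2).mean())),
        mc_se=float(math.sqrt(rejection * (1 - rejection) / n_ok)),
        mean_se=float(np.mean(ses)),
        n_failed=n_failed,
    )
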