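"""End-to-end sensitivity analysis: run every applicable method on a
dataset and collect the results in a self-describing report.

The pipeline is: orientation -> per-variant ratio estimates -> IVW (fixed
and multiplicative random-effects) -> Egger (both models) -> simple and
weighted medians -> Cochran's Q / I-squared -> directional-pleiotropy
test -> optional leave-one-out.  Methods whose preconditions a dataset
cannot meet (e.g. Egger with J = 2) are recorded as skipped with the
reason, not silently dropped.  Given a seed, the JSON serialization is
byte-identical across runs.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from typing import Any

import numpy as np

from . import __version__
from .data import SummaryDataset, orient_to_exposure, read_summary_table
from .errors import EstimationError, MRDataError
from .estimators import (
    MREstimate,
    ivw,
    egger,
    ratio_estimates,
    simple_median,
    to_odds_ratio,
    weighted_median,
)
from .heterogeneity import cochran_q, directional_pleiotropy_test
from .robustness import leave_one_out

__all__ = ["AnalysisReport", "analyze"]


@dataclass(frozen=True)
class AnalysisReport:
    """All results of one analysis run, traceable to method/model/seed."""

    exposure: str
    outcome: str
    n_variants: int
    estimates: tuple[MREstimate, ...]
    skipped: tuple[tuple[str, str], ...]  # (method, reason)
    heterogeneity: dict[str, Any] | None
    pleiotropy: dict[str, Any] | None
    odds_ratios: dict[str, Any]
    leave_one_out: dict[str, Any] | None
    seed: int
    alpha: float
    version: str = __version__

    def to_dict(self) -> dict[str, Any]:
        def clean(obj):
            if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
                return clean(dataclasses.asdict(obj))
            if isinstance(obj, dict):
                return {k: clean(v) for k, v in obj.items()}
            if isinstance(obj, (list, tuple)):
                return [clean(v) for v in obj]
            if isinstance(obj, (np.floating, np.integer)):
                return obj.item()
            return obj

        d = clean(dataclasses.asdict(self))
        for est, alpha in zip(d["estimates"], [self.alpha] * len(d["estimates"])):
            est["significant"] = est["p_value"] < alpha
        return d

    def to_json(self, indent: int = 2) -> str:
        return json.dumps(self.to_dict(), indent=indent, sort_keys=True)

    def estimate(self, method: str, model: str | None = None) -> MREstimate:
        for est in self.estimates:
            if est.method == method and (model is None or est.model == model):
                return est
        raise KeyError(f"no estimate for method={method!r} model={model!r}")


def analyze(
    data: SummaryDataset | str,
    *,
    seed: int = 0,
    n_boot: int = 1000,
    alpha: float = 0.05,
    exposure_sd: float | None = None,
    with_leave_one_out: bool = False,
    drop_null_instruments: bool = False,
    **read_kwargs,
) -> AnalysisReport:
    """Run the full sensitivity-analysis battery on a dataset (or a file path).

    ``exposure_sd`` (or the dataset's own ``exposure_sd``) converts
    log-odds estimates to odds ratios per SD of the exposure.
    ``drop_null_instruments`` removes variants with beta_exposure == 0
    (with a warning) instead of erroring.
    """
    import logging

    log = logging.getLogger(__name__)
    if isinstance(data, (str,)) or hasattr(data, "__fspath__"):
        data = read_summary_table(data, **read_kwargs)
    if drop_null_instruments:
        null = [v.variant_id for v in data.variants if v.beta_exposure == 0.0]
        if null:
            log.warning("dropping %d null instrument(s): %s", len(null), ", ".join(null))
            data = data.drop(null)
    data = orient_to_exposure(data)
    j = len(data)
    sd = exposure_sd if exposure_sd is not None else data.exposure_sd

    estimates: list[MREstimate] = []
    skipped: list[tuple[str, str]] = []

    def run(label, fn):
        try:
            estimates.append(fn())
        except EstimationError as exc:
            skipped.append((label, f"not computed: {exc}"))

    run("ivw/fixed", lambda: ivw(data, "fixed"))
    run("ivw/multiplicative_random", lambda: ivw(data, "multiplicative_random"))
    run("egger/fixed", lambda: egger(data, "fixed"))
    run("egger/multiplicative_random", lambda: egger(data, "multiplicative_random"))
    run("simple_median", lambda: simple_median(data, n_boot=n_boot, seed=seed))
    run("weighted_median", lambda: weighted_median(data, n_boot=n_boot, seed=seed + 1))

    heterogeneity = None
    if j >= 2:
        het = cochran_q(data)
        heterogeneity = {
            "Q": het.Q, "df": het.df, "p_value": het.p_value,
            "i_squared": het.i_squared,
            "i_squared_pct": 100.0 * het.i_squared,
            "contributions": dict(het.contributions),
        }
    else:
        skipped.append(("heterogeneity", "not computed: insufficient variants"))

    pleiotropy = None
    try:
        test = directional_pleiotropy_test(data)
        pleiotropy = dataclasses.asdict(test)
    except EstimationError as exc:
        skipped.append(("directional_pleiotropy_test", f"not computed: {exc}"))

    odds_ratios: dict[str, Any] = {}
    if sd is not None and data.outcome_scale == "log_odds":
        for est in estimates:
            orr = to_odds_ratio(est, sd)
            key = est.method if est.model == "not_applicable" else f"{est.method}/{est.model}"
            odds_ratios[key] = dataclasses.asdict(orr)

    loo = None
    if with_leave_one_out and j >= 3:
        summary = leave_one_out(data, method="ivw")
        loo = {
            "n_estimates": len(summary.estimates),
            "fraction_positive": summary.fraction_positive,
            "fraction_negative": summary.fraction_negative,
            "extremes": list(summary.extremes),
            "betas": {
                ",".join(sorted(s.omitted_ids)): s.estimate.beta
                for s in summary.estimates if not s.failed
            },
        }

    return AnalysisReport(
        exposure=data.exposure_label,
        outcome=data.outcome_label,
        n_variants=j,
        estimates=tuple(estimates),
        skipped=tuple(skipped),
        heterogeneity=heterogeneity,
        pleiotropy=pleiotropy,
        odds_ratios=odds_ratios,
        leave_one_out=loo,
        seed=seed,
        alpha=alpha,
    )
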