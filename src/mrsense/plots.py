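"""Diagnostic displays: ratio scatter plot, funnel plot, ordered subset plot.

Each builder returns a :class:`PlotData` holding every number that appears
in the figure; rendering is a thin matplotlib layer over it.  Tests assert
on PlotData, never on rendered images.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy import stats

from .data import SummaryDataset, as_arrays
from .estimators import MREstimate, ratio_estimates
from .errors import EstimationError
from .robustness import SubsetSummary

__all__ = ["PlotPoint", "ReferenceLine", "PlotData",
           "scatter_data", "funnel_data", "ordered_subsets_data", "render"]


@dataclass(frozen=True)
class PlotPoint:
    x: float
    y: float
    x_err: float = 0.0  # symmetric half-width; >= 0
    y_err: float = 0.0
    label: str = ""

    def __post_init__(self) -> None:
        if self.x_err < 0 or self.y_err < 0:
            raise EstimationError("error bars must be non-negative")


@dataclass(frozen=True)
class ReferenceLine:
    """orientation: 'vertical' | 'horizontal' at ``value``, or 'line' with
    value = (intercept, slope)."""

    orientation: str
    value: float | tuple[float, float]
    style: str = "solid"
    label: str = ""


@dataclass(frozen=True)
class PlotData:
    kind: str  # "scatter" | "funnel" | "ordered_subsets"
    points: tuple[PlotPoint, ...]
    reference_lines: tuple[ReferenceLine, ...] = ()
    x_label: str = ""
    y_label: str = ""


def _ci_mult(level: float) -> float:
    if not 0 < level < 1:
        raise EstimationError("ci level must be in (0, 1)")
    return float(stats.norm.ppf(0.5 + level / 2))


def scatter_data(
    data: SummaryDataset,
    fitted: Sequence[MREstimate] | None = None,
    ci_level: float = 0.95,
) -> PlotData:
    """Outcome associations against exposure associations, one point per
    variant with CI bars; under the causal null model the points lie on a
    straight line through the origin.

    Fitted estimates overlay as lines: through the origin with slope beta
    for IVW/medians, intercept + slope for Egger.
    """
    if not data.oriented:
        raise EstimationError("scatter_data requires an oriented dataset")
    m = _ci_mult(ci_level)
    arr = as_arrays(data)
    points = tuple(
        PlotPoint(x=float(bx), y=float(by), x_err=float(m * sx), y_err=float(m * sy), label=vid)
        for vid, bx, sx, by, sy in zip(arr.ids, arr.bx, arr.sx, arr.by, arr.sy)
    )
    lines = []
    for est in fitted or ():
        intercept = est.intercept if est.intercept is not None else 0.0
        lines.append(
            ReferenceLine(
                orientation="line", value=(float(intercept), float(est.beta)),
                style="dashed" if est.method == "egger" else "solid",
                label=f"{est.method} ({est.model})" if est.model != "not_applicable" else est.method,
            )
        )
    return PlotData(
        kind="scatter", points=points, reference_lines=tuple(lines),
        x_label=f"association with {data.exposure_label}",
        y_label=f"association with {data.outcome_label}",
    )


def funnel_data(
    data: SummaryDataset, ivw_estimate: MREstimate | None = None, ci_level: float = 0.95
) -> PlotData:
    """Instrument precision 1/se(theta_j) against the per-variant causal
    estimates theta_j, with horizontal CI bars.

    A symmetric funnel is expected without directional pleiotropy.
    Vertical reference lines: solid at the null, dashed at the IVW estimate.
    """
    m = _ci_mult(ci_level)
    ratios = ratio_estimates(data)
    points = tuple(
        PlotPoint(x=r.theta, y=1.0 / r.se, x_err=m * r.se, label=r.variant_id)
        for r in ratios
    )
    lines = [ReferenceLine("vertical", 0.0, style="solid", label="null")]
    if ivw_estimate is not None:
        lines.append(
            ReferenceLine("vertical", float(ivw_estimate.beta), style="dashed", label="ivw")
        )
    return PlotData(
        kind="funnel", points=points, reference_lines=tuple(lines),
        x_label="per-variant causal estimate", y_label="precision (1/SE)",
    )


def ordered_subsets_data(summary: SubsetSummary, ci_level: float = 0.95) -> PlotData:
    """Subset estimates ordered by signed value ascending, with CI bars and
    a horizontal reference at the null."""
    ordered = summary.sorted_estimates()
    if not ordered:
        raise EstimationError("no successful subset estimates to plot")
    points = tuple(
        PlotPoint(
            x=float(rank), y=s.estimate.beta,
            y_err=float(s.estimate.beta - s.estimate.ci_low),
            label=",".join(sorted(s.omitted_ids)),
        )
        for rank, s in enumerate(ordered, start=1)
    )
    return PlotData(
        kind="ordered_subsets", points=points,
        reference_lines=(ReferenceLine("horizontal", 0.0, style="solid", label="null"),),
        x_label="rank", y_label="causal estimate",
    )


def render(plot: PlotData, path: str | Path) -> None:
    """Render a PlotData to SVG or PNG (by file extension).  Styling is
    deliberately minimal; every number shown comes from the PlotData."""
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 4.5))
    xs = [p.x for p in plot.points]
    ys = [p.y for p in plot.points]
    xerr = [p.x_err for p in plot.points]
    yerr = [p.y_err for p in plot.points]
    ax.errorbar(xs, ys, xerr=xerr if any(xerr) else None,
                yerr=yerr if any(yerr) else None,
                fmt="o", ms=4, lw=1, capsize=2, color="k", ecolor="0.6")
    xlim = ax.get_xlim()
    for line in plot.reference_lines:
        ls = {"solid": "-", "dashed": "--"}.get(line.style, "-")
        if line.orientation == "vertical":
            ax.axvline(line.value, ls=ls, color="0.3", label=line.label or None)
        elif line.orientation == "horizontal":
            ax.axhline(line.value, ls=ls, color="0.3", label=line.label or None)
        else:
            intercept, slope = line.value
            grid = np.linspace(min(0.0, xlim[0]), xlim[1], 50)
            ax.plot(grid, intercept + slope * grid, ls=ls, lw=1, label=line.label or None)
    ax.set_xlabel(plot.x_label)
    ax.set_ylabel(plot.y_label)
    if any(l.label for l in plot.reference_lines):
        ax.legend(frameon=False, fontsize=8)
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)
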