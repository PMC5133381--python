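"""Data model, validation, orientation and file I/O for two-sample summarized MR data.

The atomic record is one genetic variant's pair of association estimates:
(beta_exposure, se_exposure) from the exposure GWAS and
(beta_outcome, se_outcome) from the outcome GWAS, with sampling errors
independent between the two (the two-sample setting).  A
:class:`SummaryDataset` is an ordered collection of such records plus
metadata about the exposure and outcome scales.

All estimators in this package require an *oriented* dataset: effect alleles
chosen so that every association with the exposure is non-negative.
:func:`orient_to_exposure` performs that sign convention; allele
harmonization between the two GWAS (effect-allele matching, palindromic
variants) is assumed done upstream.
"""

from __future__ import annotations

import csv
import math
from collections import namedtuple
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

from .errors import OrientationError, SchemaError, ValidationError

__all__ = [
    "VariantAssociation",
    "SummaryDataset",
    "read_summary_table",
    "write_summary_table",
    "orient_to_exposure",
    "CANONICAL_COLUMNS",
]

#: Canonical column names for the tabular interchange format.
CANONICAL_COLUMNS = (
    "variant",
    "beta_exposure",
    "se_exposure",
    "beta_outcome",
    "se_outcome",
)


@dataclass(frozen=True)
class VariantAssociation:
    """One variant's summarized associations with the exposure and the outcome.

    Parameters
    ----------
    variant_id
        Unique identifier (typically an rsID).
    beta_exposure, se_exposure
        Per-allele association with the exposure and its standard error.
    beta_outcome, se_outcome
        Per-allele association with the outcome (log odds ratio for a binary
        outcome) and its standard error.
    covariate_betas
        Optional per-allele associations with additional exposures, used by
        the multivariable estimator.
    alleles
        Optional (effect, other) allele pair carried on the record; never
        used in computation (harmonization is assumed done upstream).
    """

    variant_id: str
    beta_exposure: float
    se_exposure: float
    beta_outcome: float
    se_outcome: float
    covariate_betas: tuple[float, ...] | None = None
    alleles: tuple[str, str] | None = None

    def __post_init__(self) -> None:
        for name in ("beta_exposure", "beta_outcome"):
            if not math.isfinite(getattr(self, name)):
                raise ValidationError(f"{self.variant_id}: {name} is not finite")
        for name in ("se_exposure", "se_outcome"):
            value = getattr(self, name)
            if not (math.isfinite(value) and value > 0):
                raise ValidationError(
                    f"{self.variant_id}: {name} must be finite and > 0, got {value!r}"
                )
        if self.covariate_betas is not None:
            object.__setattr__(self, "covariate_betas", tuple(float(b) for b in self.covariate_betas))
            if not all(math.isfinite(b) for b in self.covariate_betas):
                raise ValidationError(f"{self.variant_id}: covariate beta is not finite")


@dataclass(frozen=True)
class SummaryDataset:
    """Ordered collection of :class:`VariantAssociation` with study metadata.

    ``oriented`` records whether :func:`orient_to_exposure` has been applied;
    estimators check the flag rather than re-deriving it.  ``exposure_sd``
    is the per-unit-to-per-SD scaling factor used when converting log-odds
    estimates to odds ratios per SD of the exposure.
    """

    variants: tuple[VariantAssociation, ...]
    exposure_label: str = "exposure"
    outcome_label: str = "outcome"
    outcome_scale: str = "linear"  # "linear" | "log_odds"
    oriented: bool = False
    exposure_sd: float | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "variants", tuple(self.variants))
        if len(self.variants) < 1:
            raise ValidationError("dataset must contain at least one variant")
        if self.outcome_scale not in ("linear", "log_odds"):
            raise ValidationError(f"unknown outcome_scale {self.outcome_scale!r}")
        ids = [v.variant_id for v in self.variants]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise ValidationError(f"duplicate variant_id(s): {', '.join(dupes)}")
        if self.exposure_sd is not None and not self.exposure_sd > 0:
            raise ValidationError("exposure_sd must be > 0")
        k = {len(v.covariate_betas) if v.covariate_betas else 0 for v in self.variants}
        if len(k) > 1:
            raise ValidationError("covariate_betas must have the same length for every variant")
        if self.oriented and any(v.beta_exposure < 0 for v in self.variants):
            raise ValidationError("oriented dataset contains a negative beta_exposure")

    def __len__(self) -> int:
        return len(self.variants)

    def __iter__(self):
        return iter(self.variants)

    @property
    def variant_ids(self) -> tuple[str, ...]:
        return tuple(v.variant_id for v in self.variants)

    @property
    def n_exposures(self) -> int:
        """Number of exposure columns (1 + covariates), for multivariable use."""
        cov = self.variants[0].covariate_betas
        return 1 + (len(cov) if cov else 0)

    def subset(self, keep_ids: Sequence[str]) -> "SummaryDataset":
        """Dataset restricted to ``keep_ids``, preserving original order."""
        keep = set(keep_ids)
        missing = keep - set(self.variant_ids)
        if missing:
            raise KeyError(f"unknown variant id(s): {sorted(missing)}")
        return replace(self, variants=tuple(v for v in self.variants if v.variant_id in keep))

    def drop(self, omit_ids: Sequence[str]) -> "SummaryDataset":
        """Dataset with ``omit_ids`` removed, preserving original order."""
        omit = set(omit_ids)
        return replace(self, variants=tuple(v for v in self.variants if v.variant_id not in omit))


#: Plain numpy view of a dataset, used internally by the estimators.
ArrayView = namedtuple("ArrayView", "ids bx sx by sy covariates")


def as_arrays(data: SummaryDataset) -> ArrayView:
    """Return the dataset's numeric columns as numpy arrays (row order preserved)."""
    import numpy as np

    bx = np.array([v.beta_exposure for v in data.variants], dtype=float)
    sx = np.array([v.se_exposure for v in data.variants], dtype=float)
    by = np.array([v.beta_outcome for v in data.variants], dtype=float)
    sy = np.array([v.se_outcome for v in data.variants], dtype=float)
    if data.n_exposures > 1:
        cov = np.array([v.covariate_betas for v in data.variants], dtype=float)
    else:
        cov = None
    return ArrayView(list(data.variant_ids), bx, sx, by, sy, cov)


def _sniff_delimiter(path: Path) -> str:
    with open(path, newline="") as fh:
        header = fh.readline()
    return "\t" if header.count("\t") >= header.count(",") and "\t" in header else ","


def _parse_float(text: str, *, row: int, column: str) -> float:
    try:
        return float(text)
    except (TypeError, ValueError):
        raise ValidationError(f"row {row}: column {column!r} is not numeric: {text!r}") from None


def read_summary_table(
    path: str | Path,
    column_map: Mapping[str, str] | None = None,
    *,
    delimiter: str | None = None,
    exposure_label: str = "exposure",
    outcome_label: str = "outcome",
    outcome_scale: str = "linear",
    exposure_sd: float | None = None,
) -> SummaryDataset:
    """Read a delimiter-separated summary-statistics table into a :class:`SummaryDataset`.

    The canonical header is ``variant, beta_exposure, se_exposure,
    beta_outcome, se_outcome`` with optional additional exposure pairs
    ``beta_exposure2, se_exposure2, ...`` for multivariable analysis.
    ``column_map`` maps canonical names to the file's actual headers, e.g.
    ``{"variant": "snp", "beta_exposure": "bx", ...}``.  The delimiter is
    auto-detected between comma and tab unless given.  Scientific notation
    is accepted.  Row order is preserved; the returned dataset is
    un-oriented.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    delim = delimiter or _sniff_delimiter(path)
    column_map = dict(column_map or {})

    with open(path, newline="") as fh:
        reader = csv.DictReader(fh, delimiter=delim)
        header = reader.fieldnames or []

        def col(name: str) -> str:
            return column_map.get(name, name)

        for name in CANONICAL_COLUMNS:
            if col(name) not in header:
                raise SchemaError(f"missing required column {col(name)!r}")
        # Additional exposure columns for multivariable analysis.  Their SEs
        # are not used by any estimator (weights come from se_outcome), so
        # se_exposure2... columns are accepted but ignored.
        extra_pairs = []
        k = 2
        while col(f"beta_exposure{k}") in header:
            extra_pairs.append(col(f"beta_exposure{k}"))
            k += 1
        allele_cols = [c for c in (col("effect_allele"), col("other_allele")) if c in header]

        variants = []
        for i, row in enumerate(reader, start=1):
            covs = tuple(
                _parse_float(row[c], row=i, column=c) for c in extra_pairs
            ) or None
            alleles = tuple(row[c] for c in allele_cols) if len(allele_cols) == 2 else None
            try:
                variants.append(
                    VariantAssociation(
                        variant_id=row[col("variant")],
                        beta_exposure=_parse_float(row[col("beta_exposure")], row=i, column=col("beta_exposure")),
                        se_exposure=_parse_float(row[col("se_exposure")], row=i, column=col("se_exposure")),
                        beta_outcome=_parse_float(row[col("beta_outcome")], row=i, column=col("beta_outcome")),
                        se_outcome=_parse_float(row[col("se_outcome")], row=i, column=col("se_outcome")),
                        covariate_betas=covs,
                        alleles=alleles,  # echoed, never interpreted
                    )
                )
            except ValidationError as exc:
                raise ValidationError(f"row {i}: {exc}") from None

    return SummaryDataset(
        variants=tuple(variants),
        exposure_label=exposure_label,
        outcome_label=outcome_label,
        outcome_scale=outcome_scale,
        exposure_sd=exposure_sd,
    )


def write_summary_table(data: SummaryDataset, path: str | Path, *, delimiter: str = ",") -> None:
    """Write a dataset in the canonical tabular format (round-trips with the reader)."""
    path = Path(path)
    n_cov = data.n_exposures - 1
    header = list(CANONICAL_COLUMNS) + [f"beta_exposure{k}" for k in range(2, n_cov + 2)]
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter=delimiter)
        writer.writerow(header)
        for v in data.variants:
            row = [
                v.variant_id,
                repr(v.beta_exposure),
                repr(v.se_exposure),
                repr(v.beta_outcome),
                repr(v.se_outcome),
            ]
            if v.covariate_betas:
                row += [repr(b) for b in v.covariate_betas]
            writer.writerow(row)


def orient_to_exposure(data: SummaryDataset) -> SummaryDataset:
    """Orient every variant so its association with the exposure is positive.

    For each variant with ``beta_exposure < 0`` the signs of
    ``beta_exposure``, ``beta_outcome`` and every covariate beta are flipped
    (equivalent to switching the effect allele); standard errors are
    unchanged.  Idempotent.  A variant with ``beta_exposure == 0`` has no
    defined orientation (and an undefined ratio estimate), so it is an error.
    """
    null = [v.variant_id for v in data.variants if v.beta_exposure == 0.0]
    if null:
        raise OrientationError(
            "orientation undefined for variant(s) with beta_exposure == 0: "
            + ", ".join(null)
        )
    if data.oriented and all(v.beta_exposure >= 0 for v in data.variants):
        return data
    flipped = []
    for v in data.variants:
        if v.beta_exposure < 0:
            alleles = (v.alleles[1], v.alleles[0]) if v.alleles else None
            v = replace(
                v,
                beta_exposure=-v.beta_exposure,
                beta_outcome=-v.beta_outcome,
                covariate_betas=tuple(-b for b in v.covariate_betas) if v.covariate_betas else None,
                alleles=alleles,
            )
        flipped.append(v)
    return replace(data, variants=tuple(flipped), oriented=True)
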