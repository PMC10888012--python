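"""Folding free-energy (ΔΔG) bookkeeping.

All ΔΔG values inside the pipeline follow the convention ΔΔG = ΔG_wt − ΔG_mut:
negative values destabilize the protein, positive values stabilize it.
Predictors that emit the opposite sign are normalized at ingestion.  This
module also provides predictor-ensemble averaging and the symmetric
stabilizing/destabilizing census at a magnitude cutoff (values inside the
(−cutoff, +cutoff) band count as neither).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .variant_model import ValidationError, VariantRecord

__all__ = [
    "SignConvention",
    "PAPER_CONVENTION",
    "StabilityCensus",
    "MissingPredictorError",
    "normalize_sign",
    "ensemble_average",
    "stability_census",
    "fraction_destabilizing",
    "absolute_transform",
]


@dataclass(frozen=True)
class SignConvention:
    """Declares which sign a ΔΔG source uses for destabilization."""

    name: str
    negative_is_destabilizing: bool


#: The convention used throughout this package: negative = destabilizing.
PAPER_CONVENTION = SignConvention("ddg_wt_minus_mut", negative_is_destabilizing=True)


@dataclass(frozen=True)
class StabilityCensus:
    cutoff: float
    n_stabilizing: int
    n_destabilizing: int


class MissingPredictorError(ValidationError):
    """A requested predictor value is absent from a record."""


def normalize_sign(value: float, convention: SignConvention) -> float:
    """Map a ΔΔG from its source convention to negative-destabilizing."""
    if not math.isfinite(value):
        raise ValidationError(f"non-finite ΔΔG {value!r}")
    return value if convention.negative_is_destabilizing else -value


def ensemble_average(record: VariantRecord, predictors: Sequence[str]) -> float:
    """Arithmetic mean of the record's normalized ΔΔG over named predictors."""
    if not predictors:
        raise ValidationError("predictor list is empty")
    values = []
    for name in predictors:
        if name not in record.ddg:
            raise MissingPredictorError(
                f"record {record.protein_id} {record.wt}{record.position}{record.mut} "
                f"lacks predictor {name!r}"
            )
        values.append(record.ddg[name])
    return float(np.mean(values))


def stability_census(ddg_values: Iterable[float], cutoff: float) -> StabilityCensus:
    """Count stabilizing (> +cutoff) and destabilizing (< −cutoff) values."""
    if cutoff < 0:
        raise ValidationError("census cutoff is a magnitude and must be >= 0")
    values = np.asarray(list(ddg_values), dtype=float)
    return StabilityCensus(
        cutoff=cutoff,
        n_stabilizing=int(np.sum(values > cutoff)),
        n_destabilizing=int(np.sum(values < -cutoff)),
    )


def fraction_destabilizing(
    records: Iterable[VariantRecord],
    predictors: Sequence[str],
    threshold: float = 0.0,
) -> float:
    """Fraction of records whose ensemble ΔΔG falls below −threshold.

    With the default threshold 0 this is the fraction of records with any
    loss of stability.
    """
    values = [ensemble_average(r, predictors) for r in records]
    if not values:
        raise ValidationError("fraction undefined on an empty record set")
    return float(np.mean(np.asarray(values) < -threshold))


def absolute_transform(ddg_values: Iterable[float]) -> np.ndarray:
    """Elementwise |ΔΔG|, for use as an alternative direction-blind score."""
    return np.abs(np.asarray(list(ddg_values), dtype=float))
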