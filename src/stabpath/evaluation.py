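"""Cutoff-sweep evaluation of pathogenicity scores.

Scores follow the stability convention: *lower* values are more pathogenic
(a more negative ΔΔG destabilizes more; a lower RSA is more buried), so a
record is called pathogenic when its score falls at or below the decision
cutoff.  Direction-reversed scores (e.g. |ΔΔG|) are handled by an explicit
``direction`` switch.

Provides the confusion-matrix metrics (TPR, FPR, FNR, accuracy, MCC), the
ROC curve with trapezoid AUC (ties grouped into single sweep steps, making
the trapezoid area identical to the concordance-pair AUC with ties scored
half), the MCC threshold scan used to pick operating cutoffs, and the
balanced-resampling protocol that reports mean ± sd of the rates over
repeated equal-class subsamples.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Iterable, Sequence

import numpy as np
import pandas as pd

from .variant_model import ValidationError

__all__ = [
    "ScoredLabel",
    "ConfusionCounts",
    "RocCurve",
    "ThresholdScan",
    "ResamplingSummary",
    "MethodSpec",
    "confusion_at_cutoff",
    "metrics",
    "roc_curve",
    "mcc_scan",
    "make_grid",
    "balanced_resampling_eval",
    "compare_methods",
]


@dataclass(frozen=True)
class ScoredLabel:
    score: float
    label: str  # "benign" | "pathogenic"

    def __post_init__(self) -> None:
        if not math.isfinite(self.score):
            raise ValidationError("score must be finite")
        if self.label not in ("benign", "pathogenic"):
            raise ValidationError(f"unknown binary label {self.label!r}")


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    tn: int
    fp: int
    fn: int

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn


@dataclass(frozen=True)
class RocCurve:
    points: tuple  # ordered (cutoff, tpr, fpr)
    auc: float


@dataclass(frozen=True)
class ThresholdScan:
    grid: np.ndarray
    mcc_at: np.ndarray
    optimal_cutoff: float
    optimal_mcc: float


@dataclass(frozen=True)
class ResamplingSummary:
    n_reps: int
    sample_n_per_class: int
    tpr_mean: float
    tpr_sd: float
    fpr_mean: float
    fpr_sd: float
    fnr_mean: float
    fnr_sd: float
    accuracy_mean: float
    accuracy_sd: float


def _as_arrays(data: Iterable[ScoredLabel]) -> tuple[np.ndarray, np.ndarray]:
    data = list(data)
    if not data:
        raise ValidationError("no scored records")
    scores = np.array([d.score for d in data], dtype=float)
    y = np.array([d.label == "pathogenic" for d in data], dtype=bool)
    return scores, y


def _predict(scores: np.ndarray, cutoff: float, direction: str) -> np.ndarray:
    if direction == "le":
        return scores <= cutoff
    if direction == "ge":
        return scores >= cutoff
    raise ValidationError(f"direction must be 'le' or 'ge', got {direction!r}")


def confusion_at_cutoff(
    data: Iterable[ScoredLabel], cutoff: float, direction: str = "le"
) -> ConfusionCounts:
    """Tally the confusion matrix at a fixed cutoff.

    With the default direction a record is predicted pathogenic when its
    score is at or below the cutoff.
    """
    scores, y = _as_arrays(data)
    pred = _predict(scores, cutoff, direction)
    return ConfusionCounts(
        tp=int(np.sum(pred & y)),
        tn=int(np.sum(~pred & ~y)),
        fp=int(np.sum(pred & ~y)),
        fn=int(np.sum(~pred & y)),
    )


def metrics(c: ConfusionCounts) -> dict[str, float]:
    """TPR, FPR, FNR, accuracy and MCC from a confusion matrix.

    MCC uses the convention that a zero denominator factor yields MCC = 0.
    Rates are undefined (error) when the corresponding class is absent.
    """
    tp, tn, fp, fn = c.tp, c.tn, c.fp, c.fn
    n_pos, n_neg = tp + fn, tn + fp
    if n_pos == 0 or n_neg == 0:
        raise ValidationError("both classes must be present for rate metrics")
    denom2 = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    mcc = 0.0 if denom2 == 0 else (tp * tn - fp * fn) / math.sqrt(denom2)
    return {
        "tpr": tp / n_pos,
        "fpr": fp / n_neg,
        "fnr": fn / n_pos,
        "accuracy": (tp + tn) / c.total,
        "mcc": mcc,
    }


def roc_curve(data: Iterable[ScoredLabel], direction: str = "le") -> RocCurve:
    """ROC curve swept over all distinct score values.

    Equal scores collapse into one sweep step, so the trapezoid area equals
    the concordance-pair AUC (ties counted half).  Requires both classes.
    """
    scores, y = _as_arrays(data)
    n_pos, n_neg = int(y.sum()), int((~y).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValidationError("ROC requires both classes")
    if direction == "ge":
        scores = -scores
    order = np.argsort(scores, kind="stable")
    s, yy = scores[order], y[order]
    # cumulative counts at each distinct score (predicted pathogenic: <= s)
    points = [(-np.inf, 0.0, 0.0)]
    tp = fp = 0
    i = 0
    n = len(s)
    while i < n:
        j = i
        while j < n and s[j] == s[i]:
            j += 1
        tp += int(yy[i:j].sum())
        fp += (j - i) - int(yy[i:j].sum())
        points.append((float(s[i]), tp / n_pos, fp / n_neg))
        i = j
    pts = np.array([(p[2], p[1]) for p in points])  # (fpr, tpr)
    auc = float(np.trapezoid(pts[:, 1], pts[:, 0]))
    return RocCurve(points=tuple(points), auc=auc)


def make_grid(min_value: float, max_value: float, step: float) -> np.ndarray:
    """Inclusive evenly spaced cutoff grid, robust to floating-point step."""
    if step <= 0 or max_value < min_value:
        raise ValidationError("invalid grid specification")
    n = int(round((max_value - min_value) / step))
    grid = min_value + step * np.arange(n + 1)
    return np.round(grid, 10)


def mcc_scan(
    data: Iterable[ScoredLabel],
    grid_spec: dict | Sequence[float],
    direction: str = "le",
) -> ThresholdScan:
    """MCC at every grid cutoff; the optimum is the argmax.

    Ties on MCC are broken toward the cutoff of smallest magnitude, then the
    smaller value.
    """
    data = list(data)
    if isinstance(grid_spec, dict):
        grid = make_grid(grid_spec["min"], grid_spec["max"], grid_spec["step"])
    else:
        grid = np.asarray(list(grid_spec), dtype=float)
    if grid.size == 0:
        raise ValidationError("empty cutoff grid")
    mccs = np.array(
        [metrics(confusion_at_cutoff(data, c, direction))["mcc"] for c in grid]
    )
    best = max(
        range(len(grid)),
        key=lambda i: (mccs[i], -abs(grid[i]), -grid[i]),
    )
    return ThresholdScan(
        grid=grid,
        mcc_at=mccs,
        optimal_cutoff=float(grid[best]),
        optimal_mcc=float(mccs[best]),
    )


DDG_GRID = {"min": -5.0, "max": 5.0, "step": 0.1}
RSA_GRID = {"min": 0.0, "max": 1.0, "step": 0.01}


def balanced_resampling_eval(
    data: Iterable[ScoredLabel],
    cutoff: float,
    n_reps: int = 100,
    seed: int | np.random.Generator = 0,
    direction: str = "le",
) -> ResamplingSummary:
    """Balanced-subsample evaluation at a fixed cutoff.

    N = floor(0.5 * min(class sizes)); each repetition draws N benign and N
    pathogenic records without replacement, and the rates are averaged over
    repetitions (sd with ddof=1).
    """
    scores, y = _as_arrays(data)
    rng = np.random.default_rng(seed) if isinstance(seed, int) else seed
    idx_pos = np.flatnonzero(y)
    idx_neg = np.flatnonzero(~y)
    n_each = min(idx_pos.size, idx_neg.size) // 2
    if n_each == 0:
        raise ValidationError("classes too small for balanced resampling")
    if min(idx_pos.size, idx_neg.size) < 2:
        raise ValidationError("need at least 2 records per class")
    rows = []
    pred = _predict(scores, cutoff, direction)
    for _ in range(n_reps):
        take = np.concatenate(
            [
                rng.choice(idx_pos, size=n_each, replace=False),
                rng.choice(idx_neg, size=n_each, replace=False),
            ]
        )
        p, t = pred[take], y[take]
        c = ConfusionCounts(
            tp=int(np.sum(p & t)),
            tn=int(np.sum(~p & ~t)),
            fp=int(np.sum(p & ~t)),
            fn=int(np.sum(~p & t)),
        )
        rows.append(metrics(c))
    frame = pd.DataFrame(rows)
    sd = frame.std(ddof=1) if n_reps > 1 else frame.iloc[0] * 0.0
    mean = frame.mean()
    return ResamplingSummary(
        n_reps=n_reps,
        sample_n_per_class=n_each,
        tpr_mean=float(mean["tpr"]),
        tpr_sd=float(sd["tpr"]),
        fpr_mean=float(mean["fpr"]),
        fpr_sd=float(sd["fpr"]),
        fnr_mean=float(mean["fnr"]),
        fnr_sd=float(sd["fnr"]),
        accuracy_mean=float(mean["accuracy"]),
        accuracy_sd=float(sd["accuracy"]),
    )


@dataclass(frozen=True)
class MethodSpec:
    """One scored method to benchmark.

    ``scorer`` maps the dataset (list of records or a DataFrame) to a float
    array aligned with it; ``cutoff`` is a number or "mcc-opt" to take the
    optimum of an MCC scan over ``grid``.  External binary classifiers are
    represented by a scorer returning 0/1 calls with cutoff 0.5 and
    direction "ge".
    """

    name: str
    scorer: Callable
    direction: str = "le"
    cutoff: float | str = "mcc-opt"
    grid: dict = field(default_factory=lambda: dict(DDG_GRID))


def compare_methods(
    dataset,
    method_specs: Sequence[MethodSpec],
    labels: Sequence[str] | None = None,
    n_reps: int = 100,
    seed: int = 0,
) -> pd.DataFrame:
    """Benchmark several methods with the balanced-resampling protocol.

    All methods are evaluated on the same drawn sample in each repetition
    (paired sampling), so between-method differences are not inflated by
    sampling noise.  Returns one row per method with the resolved cutoff and
    mean ± sd of TPR/FPR/FNR/accuracy.
    """
    if labels is None:
        labels = [r.label for r in dataset]
    y = np.array([l == "pathogenic" for l in labels], dtype=bool)
    if y.sum() == 0 or (~y).sum() == 0:
        raise ValidationError("both classes required")
    resolved = []
    for spec in method_specs:
        scores = np.asarray(spec.scorer(dataset), dtype=float)
        if scores.shape[0] != y.shape[0]:
            raise ValidationError(f"scorer {spec.name!r} misaligned with dataset")
        data = [
            ScoredLabel(s, "pathogenic" if t else "benign")
            for s, t in zip(scores, y)
        ]
        if spec.cutoff == "mcc-opt":
            cutoff = mcc_scan(data, spec.grid, spec.direction).optimal_cutoff
        else:
            cutoff = float(spec.cutoff)
        resolved.append((spec, data, cutoff))
    rows = []
    for spec, data, cutoff in resolved:
        summary = balanced_resampling_eval(
            data,
            cutoff,
            n_reps=n_reps,
            seed=np.random.default_rng(seed),  # same stream -> same draws per method
            direction=spec.direction,
        )
        rows.append(
            {
                "method": spec.name,
                "cutoff": cutoff,
                "avg_tpr": summary.tpr_mean,
                "sd_tpr": summary.tpr_sd,
                "avg_fpr": summary.fpr_mean,
                "sd_fpr": summary.fpr_sd,
                "avg_fnr": summary.fnr_mean,
                "sd_fnr": summary.fnr_sd,
                "avg_accuracy": summary.accuracy_mean,
                "sd_accuracy": summary.accuracy_sd,
            }
        )
    return pd.DataFrame(rows)
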