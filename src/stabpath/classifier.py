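"""Logistic pathogenicity model on (ΔΔG, RSA) features.

The model is an L2-penalized binomial regression: with standardized features
x and P(pathogenic) = sigmoid(b0 + x·w), the fit maximizes

    sum_i [ y_i z_i − log(1 + e^{z_i}) ] − ||w||² / (2c)

with the intercept unpenalized; c is the inverse regularization strength.
The optimum is found by damped Newton iterations on this three-parameter
concave objective, to an infinity-norm gradient below 1e−10 — tight enough
that the fit is bit-deterministic given its inputs.

The training protocol mirrors the standard benchmark recipe: downsample to
equal class sizes, split 80/20 stratified, select c by repeated stratified
5-fold cross-validation on held-out AUC, refit on the full training split at
the selected c, and report AUC and MCC (probability cutoff 0.5) on both
splits.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .evaluation import (
    ConfusionCounts,
    ScoredLabel,
    metrics,
    roc_curve,
)
from .stability_metrics import MissingPredictorError, ensemble_average
from .variant_model import ValidationError, VariantRecord

__all__ = [
    "LogisticModel",
    "CvReport",
    "FeatureSpec",
    "ConvergenceError",
    "balance_classes",
    "split_train_test",
    "fit_logistic",
    "predict_proba",
    "cv_select_c",
    "train_full_protocol",
    "extract_features",
    "DEFAULT_C_GRID",
]

DEFAULT_C_GRID = (0.001, 0.01, 0.1, 1.0, 10.0, 100.0, 1000.0)


class ConvergenceError(RuntimeError):
    pass


@dataclass(frozen=True)
class LogisticModel:
    intercept: float
    coef: tuple[float, ...]  # per standardized feature
    c_value: float
    feature_names: tuple[str, ...]
    feature_means: tuple[float, ...]
    feature_scales: tuple[float, ...]

    @property
    def coef_ddg(self) -> float:
        return self.coef[self.feature_names.index("ddg")]

    @property
    def coef_rsa(self) -> float:
        return self.coef[self.feature_names.index("rsa")]

    def to_dict(self) -> dict:
        return {
            "intercept": self.intercept,
            "coef": list(self.coef),
            "c_value": self.c_value,
            "feature_names": list(self.feature_names),
            "feature_means": list(self.feature_means),
            "feature_scales": list(self.feature_scales),
        }


@dataclass(frozen=True)
class CvReport:
    c_grid: tuple[float, ...]
    mean_auc: tuple[float, ...]
    selected_c: float


@dataclass(frozen=True)
class FeatureSpec:
    """Which predictor ensemble (and optionally RSA) feeds the model."""

    name: str
    predictors: tuple[str, ...]
    include_rsa: bool = True

    @property
    def feature_names(self) -> tuple[str, ...]:
        return ("ddg", "rsa") if self.include_rsa else ("ddg",)


def extract_features(
    records: Sequence[VariantRecord], spec: FeatureSpec
) -> tuple[np.ndarray, np.ndarray, int]:
    """(features, labels, n_skipped) for records with complete data.

    Records missing a requested predictor or RSA are skipped (counted),
    never imputed.
    """
    rows, labels, skipped = [], [], 0
    for rec in records:
        try:
            ddg = ensemble_average(rec, spec.predictors)
        except MissingPredictorError:
            skipped += 1
            continue
        if spec.include_rsa:
            if rec.rsa is None:
                skipped += 1
                continue
            rows.append((ddg, rec.rsa))
        else:
            rows.append((ddg,))
        labels.append(rec.label == "pathogenic")
    if not rows:
        raise ValidationError("no records with complete features")
    return np.asarray(rows, float), np.asarray(labels, bool), skipped


def balance_classes(
    records: Sequence, labels: Sequence[str] | None = None, seed: int = 0
):
    """Downsample the majority class without replacement to the minority size.

    Works on any indexable sequence; labels default to each record's
    ``.label``.  Returns the balanced subsequence (original order preserved).
    """
    records = list(records)
    if labels is None:
        labels = [r.label for r in records]
    y = np.array([l == "pathogenic" for l in labels], dtype=bool)
    idx_pos, idx_neg = np.flatnonzero(y), np.flatnonzero(~y)
    if idx_pos.size == 0 or idx_neg.size == 0:
        raise ValidationError("both classes required for balancing")
    rng = np.random.default_rng(seed)
    n = min(idx_pos.size, idx_neg.size)
    keep = np.concatenate(
        [
            rng.choice(idx_pos, size=n, replace=False),
            rng.choice(idx_neg, size=n, replace=False),
        ]
    )
    keep.sort()
    return [records[i] for i in keep]


def split_train_test(
    records: Sequence, fraction: float = 0.8, seed: int = 0,
    labels: Sequence[str] | None = None,
):
    """Stratified train/test split; per-class sizes within 1 of the exact split."""
    records = list(records)
    if len(records) < 5:
        raise ValidationError("need at least 5 records to split")
    if not (0.0 < fraction < 1.0):
        raise ValidationError("train fraction must be in (0, 1)")
    if labels is None:
        labels = [r.label for r in records]
    y = np.array([l == "pathogenic" for l in labels], dtype=bool)
    rng = np.random.default_rng(seed)
    train_idx: list[int] = []
    for cls_idx in (np.flatnonzero(y), np.flatnonzero(~y)):
        perm = rng.permutation(cls_idx)
        k = int(round(fraction * cls_idx.size))
        train_idx.extend(perm[:k])
    train_set = set(train_idx)
    train = [records[i] for i in range(len(records)) if i in train_set]
    test = [records[i] for i in range(len(records)) if i not in train_set]
    if not test or not train:
        raise ValidationError("split produced an empty subset")
    return train, test


def _sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


def _neg_penalized_loglik(beta, X1, y, c):
    z = X1 @ beta
    # log(1+e^z) computed stably
    ll = float(y @ z - np.sum(np.logaddexp(0.0, z)))
    return -(ll - beta[1:] @ beta[1:] / (2.0 * c))


def fit_logistic(
    features: np.ndarray,
    labels: np.ndarray,
    c: float = 1.0,
    *,
    standardize: bool = True,
    feature_names: Sequence[str] | None = None,
    tol: float = 1e-10,
    max_iter: int = 200,
) -> LogisticModel:
    """Fit the penalized logistic model by damped Newton iterations.

    Converges to infinity-norm gradient <= ``tol`` of the penalized
    log-likelihood; raises ConvergenceError otherwise.
    """
    X = np.asarray(features, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    y = np.asarray(labels).astype(float)
    if c <= 0:
        raise ValidationError("c must be positive")
    if not np.all(np.isfinite(X)):
        raise ValidationError("features must be finite")
    if y.sum() < 2 or (1 - y).sum() < 2:
        raise ValidationError("need at least 2 records per class")
    if feature_names is None:
        feature_names = [f"x{i}" for i in range(X.shape[1])]

    if standardize:
        means = X.mean(axis=0)
        scales = X.std(axis=0)
        scales[scales == 0] = 1.0
    else:
        means = np.zeros(X.shape[1])
        scales = np.ones(X.shape[1])
    Xs = (X - means) / scales
    X1 = np.hstack([np.ones((Xs.shape[0], 1)), Xs])

    beta = np.zeros(X1.shape[1])
    penalty_diag = np.concatenate([[0.0], np.full(X.shape[1], 1.0 / c)])
    obj = _neg_penalized_loglik(beta, X1, y, c)
    for _ in range(max_iter):
        p = _sigmoid(X1 @ beta)
        grad = X1.T @ (p - y) + penalty_diag * beta  # gradient of the negative
        if np.max(np.abs(grad)) <= tol:
            break
        w = p * (1.0 - p)
        H = (X1 * w[:, None]).T @ X1 + np.diag(penalty_diag)
        step = np.linalg.solve(H, grad)
        # damped Newton: halve until the objective stops increasing (tiny
        # relative slack so rounding noise near the optimum cannot stall the
        # quadratic convergence phase)
        slack = 1e-12 * (1.0 + abs(obj))
        t = 1.0
        while t > 1e-12:
            cand = beta - t * step
            cand_obj = _neg_penalized_loglik(cand, X1, y, c)
            if cand_obj <= obj + slack:
                break
            t /= 2.0
        beta, obj = cand, min(cand_obj, obj)
    else:
        raise ConvergenceError(
            f"Newton did not reach gradient norm {tol:g}; final "
            f"{np.max(np.abs(grad)):g}"
        )
    return LogisticModel(
        intercept=float(beta[0]),
        coef=tuple(float(b) for b in beta[1:]),
        c_value=float(c),
        feature_names=tuple(feature_names),
        feature_means=tuple(float(m) for m in means),
        feature_scales=tuple(float(s) for s in scales),
    )


def predict_proba(model: LogisticModel, features: np.ndarray) -> np.ndarray:
    """P(pathogenic) for feature rows (raw units; standardization is stored)."""
    X = np.asarray(features, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    if X.shape[1] != len(model.coef):
        raise ValidationError(
            f"expected {len(model.coef)} features, got {X.shape[1]}"
        )
    Xs = (X - np.asarray(model.feature_means)) / np.asarray(model.feature_scales)
    return _sigmoid(model.intercept + Xs @ np.asarray(model.coef))


def _stratified_folds(y: np.ndarray, k: int, rng: np.random.Generator):
    """Index lists for k stratified folds."""
    folds: list[list[int]] = [[] for _ in range(k)]
    for cls_idx in (np.flatnonzero(y), np.flatnonzero(~y)):
        perm = rng.permutation(cls_idx)
        for i, idx in enumerate(perm):
            folds[i % k].append(int(idx))
    return [np.array(sorted(f)) for f in folds]


def _auc_from_proba(p: np.ndarray, y: np.ndarray) -> float:
    data = [
        ScoredLabel(float(pi), "pathogenic" if yi else "benign")
        for pi, yi in zip(p, y)
    ]
    return roc_curve(data, direction="ge").auc


def cv_select_c(
    features: np.ndarray,
    labels: np.ndarray,
    c_grid: Sequence[float] = DEFAULT_C_GRID,
    k: int = 5,
    reps: int = 100,
    seed: int = 0,
) -> CvReport:
    """Select c by repeated stratified k-fold cross-validated held-out AUC.

    The mean is taken over k folds × ``reps`` repartitions; ties on the mean
    AUC resolve to the smaller c (stronger regularization).  A degenerate
    fold (single class) triggers a repartition under a fresh sub-seed.
    """
    X = np.asarray(features, float)
    y = np.asarray(labels).astype(bool)
    if len(c_grid) == 0:
        raise ValidationError("empty c grid")
    ss = np.random.SeedSequence(seed)
    sums = np.zeros(len(c_grid))
    count = 0
    for rep_seed in ss.spawn(reps):
        rng = np.random.default_rng(rep_seed)
        for _ in range(20):
            folds = _stratified_folds(y, k, rng)
            if all(0 < y[f].sum() < len(f) for f in folds):
                break
        else:
            raise ValidationError("could not build stratified folds")
        for fold in folds:
            mask = np.ones(len(y), dtype=bool)
            mask[fold] = False
            for ci, c in enumerate(c_grid):
                model = fit_logistic(X[mask], y[mask], c)
                p = predict_proba(model, X[fold])
                sums[ci] += _auc_from_proba(p, y[fold])
            count += 1
    mean_auc = sums / count
    best = max(range(len(c_grid)), key=lambda i: (mean_auc[i], -c_grid[i]))
    return CvReport(
        c_grid=tuple(float(c) for c in c_grid),
        mean_auc=tuple(float(a) for a in mean_auc),
        selected_c=float(c_grid[best]),
    )


def _split_metrics(model: LogisticModel, X: np.ndarray, y: np.ndarray) -> dict:
    p = predict_proba(model, X)
    pred = p >= 0.5
    c = ConfusionCounts(
        tp=int(np.sum(pred & y)),
        tn=int(np.sum(~pred & ~y)),
        fp=int(np.sum(pred & ~y)),
        fn=int(np.sum(~pred & y)),
    )
    return {"auc": _auc_from_proba(p, y), "mcc": metrics(c)["mcc"]}


def train_full_protocol(
    records: Sequence[VariantRecord],
    feature_spec: FeatureSpec,
    c_grid: Sequence[float] = DEFAULT_C_GRID,
    seed: int = 0,
    cv_reps: int = 100,
) -> tuple[LogisticModel, dict, dict, CvReport]:
    """Balance, split 80/20, select c by CV, refit, and report.

    Returns (model, train metrics, test metrics, cv report); metrics are AUC
    and MCC at probability cutoff 0.5.
    """
    X, y, _ = extract_features(records, feature_spec)
    rows = list(range(len(y)))
    lab = ["pathogenic" if t else "benign" for t in y]
    bal = balance_classes(rows, labels=lab, seed=seed)
    bal_lab = [lab[i] for i in bal]
    train_rows, test_rows = split_train_test(
        bal, fraction=0.8, seed=seed + 1, labels=bal_lab
    )
    Xtr, ytr = X[train_rows], y[train_rows]
    Xte, yte = X[test_rows], y[test_rows]
    report = cv_select_c(Xtr, ytr, c_grid, reps=cv_reps, seed=seed + 2)
    model = fit_logistic(
        Xtr, ytr, report.selected_c, feature_names=feature_spec.feature_names
    )
    return model, _split_metrics(model, Xtr, ytr), _split_metrics(model, Xte, yte), report
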