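"""Random-forest evaluation harness with ROC analysis.

Binary outcomes (12-month survival status, or immune-signature status
dichotomized at the cohort median) are predicted from the 52-feature table
with a random forest under stratified k-fold cross-validation. Class imbalance
is handled by class-proportional resampling inside each training fold, missing
features (tiny habitats, absent edge types) are imputed with training-fold
medians, and performance is summarized by the ROC curve of the pooled
out-of-fold probabilities: AUC (trapezoidal rule), the cutoff maximizing
sensitivity + specificity, and the accuracy

    ACC = (TP + TN) / (TP + FN + TN + FP)

at that cutoff. MAE is the mean absolute difference between the predicted
probability and the 0/1 label. Feature importances are Gini importances from a
forest refit on the full table.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.metrics import roc_curve
from sklearn.model_selection import StratifiedKFold

from .errors import (
    DegenerateLabelsError,
    ParameterError,
    StratificationError,
    UndefinedROCError,
)

__all__ = [
    "ClassifierReport",
    "dichotomize_labels",
    "crossvalidated_rf",
    "roc_report",
    "evaluate_features",
]


@dataclass
class ClassifierReport:
    """ROC summary of a cross-validated classifier."""

    auc: float
    tpr: float  # sensitivity at the optimal cutoff
    tnr: float  # specificity at the optimal cutoff
    acc: float
    mae: float
    cutoff: float  # probability threshold maximizing tpr + tnr
    optimal_point: tuple[float, float]  # (fpr, tpr) operating point
    roc_fpr: np.ndarray = field(repr=False, default=None)
    roc_tpr: np.ndarray = field(repr=False, default=None)
    feature_importances: pd.Series | None = field(repr=False, default=None)
    fold_assignments: np.ndarray | None = field(repr=False, default=None)
    seed: int | None = None

    def to_dict(self) -> dict:
        out = {
            "auc": self.auc,
            "tpr": self.tpr,
            "tnr": self.tnr,
            "acc": self.acc,
            "mae": self.mae,
            "cutoff": self.cutoff,
            "optimal_point": list(self.optimal_point),
            "seed": self.seed,
        }
        if self.feature_importances is not None:
            out["feature_importances"] = self.feature_importances.to_dict()
        if self.fold_assignments is not None:
            out["fold_assignments"] = self.fold_assignments.tolist()
        return out


def dichotomize_labels(values, rule: str = "median") -> np.ndarray:
    """Binary labels from per-subject scalars.

    ``"threshold-12-months"``: label 1 iff survival > 12 months.
    ``"median"``: label 1 iff score > cohort median, 0 iff <= median
    (a score exactly at the median goes to class 0).
    """
    values = np.asarray(values, dtype=float)
    if values.size < 2:
        raise ParameterError("need >= 2 subjects to dichotomize")
    if rule == "threshold-12-months":
        return (values > 12.0).astype(int)
    if rule == "median":
        if np.all(values == values[0]):
            raise DegenerateLabelsError("constant scores: median split undefined")
        return (values > np.median(values)).astype(int)
    raise ParameterError(f"unknown dichotomization rule: {rule!r}")


def _impute_median(train: np.ndarray, other: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Fill NaNs with per-column training medians (never from held-out data)."""
    import warnings

    with warnings.catch_warnings():
        # all-NaN columns are legal (habitat absent cohort-wide); filled with 0
        warnings.simplefilter("ignore", RuntimeWarning)
        med = np.nanmedian(train, axis=0)
    med = np.where(np.isfinite(med), med, 0.0)
    train = np.where(np.isnan(train), med, train)
    other = np.where(np.isnan(other), med, other)
    return train, other


def _balance_classes(
    X: np.ndarray, y: np.ndarray, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Class-proportional resampling: upsample minority class(es) with
    replacement until all classes match the majority count."""
    classes, counts = np.unique(y, return_counts=True)
    target = counts.max()
    keep = [np.arange(len(y))]
    for cls, cnt in zip(classes, counts):
        if cnt < target:
            idx = np.flatnonzero(y == cls)
            keep.append(rng.choice(idx, size=target - cnt, replace=True))
    sel = np.concatenate(keep)
    return X[sel], y[sel]


def crossvalidated_rf(
    table: pd.DataFrame,
    labels,
    n_trees: int = 10_000,
    k: int = 5,
    seed: int = 0,
) -> np.ndarray:
    """Out-of-fold class-1 probabilities under stratified k-fold CV.

    Within each training fold: median imputation of missing features, then
    class-proportional resampling to equal class counts, then a random forest
    with ``n_trees`` trees. Deterministic given ``seed``.
    """
    X = np.asarray(table, dtype=float)
    y = np.asarray(labels, dtype=int)
    if X.shape[0] != y.shape[0]:
        raise ParameterError("feature table and labels length mismatch")
    _, counts = np.unique(y, return_counts=True)
    if counts.size < 2 or counts.min() < k:
        raise StratificationError(
            f"each class needs >= {k} members for {k}-fold stratified CV"
        )
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=int(seed))
    probs = np.empty(len(y), dtype=float)
    for fold, (tr, te) in enumerate(skf.split(X, y)):
        fold_seed = int((seed + 7919 * (fold + 1)) % 2**31)
        Xtr, Xte = _impute_median(X[tr], X[te])
        Xtr, ytr = _balance_classes(Xtr, y[tr], np.random.default_rng(fold_seed))
        rf = RandomForestClassifier(
            n_estimators=n_trees, random_state=fold_seed, n_jobs=1
        )
        rf.fit(Xtr, ytr)
        probs[te] = rf.predict_proba(Xte)[:, list(rf.classes_).index(1)]
    return probs


def fold_assignments(labels, k: int = 5, seed: int = 0) -> np.ndarray:
    """Fold index per subject for the stratified split used by crossvalidated_rf."""
    y = np.asarray(labels, dtype=int)
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=int(seed))
    folds = np.empty(len(y), dtype=int)
    for fold, (_, te) in enumerate(skf.split(np.zeros((len(y), 1)), y)):
        folds[te] = fold
    return folds


def roc_report(
    probabilities,
    labels,
    feature_table: pd.DataFrame | None = None,
    n_trees: int = 1000,
    seed: int = 0,
) -> ClassifierReport:
    """ROC analysis of predicted probabilities against binary labels.

    The ROC curve is traced by a threshold sweep over the unique probability
    values; AUC is the trapezoidal area under it. The operating cutoff
    maximizes sensitivity + specificity (on ties, the smallest threshold
    wins), and accuracy is computed from the confusion matrix at that cutoff.
    If ``feature_table`` is given, Gini importances are computed from a random
    forest refit on the full (median-imputed) table.
    """
    p = np.asarray(probabilities, dtype=float)
    y = np.asarray(labels, dtype=int)
    if np.unique(y).size < 2:
        raise UndefinedROCError("both classes must be present for ROC analysis")
    fpr, tpr, _ = roc_curve(y, p)
    auc = float(np.trapezoid(tpr, fpr))
    n_pos = int((y == 1).sum())
    n_neg = int((y == 0).sum())
    best = (-np.inf, None)
    for c in np.unique(p):  # ascending: first maximum = smallest threshold
        pred = p >= c
        tp = int(np.sum(pred & (y == 1)))
        tn = int(np.sum(~pred & (y == 0)))
        sens = tp / n_pos
        spec = tn / n_neg
        if sens + spec > best[0]:
            best = (sens + spec, (float(c), sens, spec, tp, tn))
    cutoff, sens, spec, tp, tn = best[1]
    acc = (tp + tn) / len(y)
    mae = float(np.mean(np.abs(p - y)))
    importances = None
    if feature_table is not None:
        X = np.asarray(feature_table, dtype=float)
        X, _ = _impute_median(X, X)
        rf = RandomForestClassifier(
            n_estimators=n_trees, random_state=int(seed), n_jobs=1
        )
        rf.fit(X, y)
        importances = pd.Series(
            rf.feature_importances_, index=list(feature_table.columns)
        ).sort_values(ascending=False)
    return ClassifierReport(
        auc=auc,
        tpr=sens,
        tnr=spec,
        acc=float(acc),
        mae=mae,
        cutoff=cutoff,
        optimal_point=(1.0 - spec, sens),
        roc_fpr=fpr,
        roc_tpr=tpr,
        feature_importances=importances,
        seed=int(seed),
    )


def evaluate_features(
    table: pd.DataFrame,
    labels,
    n_trees: int = 10_000,
    k: int = 5,
    seed: int = 0,
) -> ClassifierReport:
    """Cross-validated RF + ROC report, end to end."""
    probs = crossvalidated_rf(table, labels, n_trees=n_trees, k=k, seed=seed)
    report = roc_report(probs, labels, feature_table=table, n_trees=min(n_trees, 1000), seed=seed)
    report.fold_assignments = fold_assignments(labels, k=k, seed=seed)
    return report
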