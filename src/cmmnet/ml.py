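"""Stratified splitting, multiclass metrics and the six-classifier benchmark.

The split and the confusion-matrix metrics are coded against their formula
contracts; model fitting, confusion matrices and ROC areas come from
scikit-learn.  XGBoost is optional — when unavailable the report carries an
explicit skipped entry instead of failing.
"""

from __future__ import annotations

import importlib
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.ensemble import GradientBoostingClassifier, RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import confusion_matrix as sk_confusion_matrix
from sklearn.metrics import roc_auc_score
from sklearn.neighbors import KNeighborsClassifier
from sklearn.svm import SVC

__all__ = [
    "stratified_split",
    "metrics_from_confusion",
    "run_benchmark",
    "feature_importance",
    "BenchmarkReport",
    "MODEL_FAMILIES",
]

MODEL_FAMILIES = (
    "RandomForest",
    "GradientBoosting",
    "SVM",
    "KNN",
    "LogisticRegression",
    "XGBoost",
)


def stratified_split(
    X: np.ndarray,
    y: Sequence,
    train_fraction: float = 0.7,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Per-class proportional split; returns (train_idx, test_idx).

    Within each class the train size is round(fraction * n_class), so class
    proportions in the train set match the full set within one record.
    Disjoint and exhaustive; fully seeded.  Refuses singleton classes.
    """
    if not 0.0 < train_fraction < 1.0:
        raise ValueError("train_fraction must lie in (0, 1)")
    y = np.asarray(y)
    if len(y) != len(X):
        raise ValueError("X and y must have equal length")
    rng = np.random.default_rng(seed)
    train_idx: list[int] = []
    test_idx: list[int] = []
    for cls in np.unique(y):
        idx = np.flatnonzero(y == cls)
        if len(idx) < 2:
            raise ValueError(f"class {cls!r} has a single member; cannot stratify")
        idx = rng.permutation(idx)
        n_train = int(round(train_fraction * len(idx)))
        n_train = min(max(n_train, 1), len(idx) - 1)  # both sides non-empty
        train_idx.extend(idx[:n_train])
        test_idx.extend(idx[n_train:])
    return np.sort(np.array(train_idx)), np.sort(np.array(test_idx))


def metrics_from_confusion(
    cm: np.ndarray,
    average: str = "macro",
    paper_literal: bool = False,
) -> dict[str, float]:
    """Accuracy, precision, recall and F1 from a K x K confusion matrix.

    Rows are true classes, columns predictions.  Per class (one-vs-rest):
    precision = TP/(TP+FP), recall = TP/(TP+FN), F1 = harmonic mean;
    aggregation is macro (default), weighted or micro.  Accuracy is
    trace/total; ``paper_literal=True`` instead evaluates the one-vs-rest
    quantity (TP+TN)/(TP+TN+FN) per class and macro-averages it (kept for
    auditability of the printed formula, which omits FP).
    """
    cm = np.asarray(cm, dtype=float)
    if cm.ndim != 2 or cm.shape[0] != cm.shape[1] or cm.size == 0:
        raise ValueError("confusion matrix must be square and non-empty")
    total = cm.sum()
    if total <= 0:
        raise ValueError("confusion matrix total must be > 0")
    k = cm.shape[0]
    tp = np.diag(cm)
    fp = cm.sum(axis=0) - tp
    fn = cm.sum(axis=1) - tp
    tn = total - tp - fp - fn

    with np.errstate(invalid="ignore", divide="ignore"):
        precision = np.where(tp + fp > 0, tp / (tp + fp), 0.0)
        recall = np.where(tp + fn > 0, tp / (tp + fn), 0.0)
        denom = precision + recall
        f1 = np.where(denom > 0, 2 * precision * recall / denom, 0.0)
    if (tp + fp == 0).any():
        warnings.warn("some classes absent from predictions; precision set to 0")

    if average == "macro":
        agg = lambda v: float(v.mean())
    elif average == "weighted":
        weights = cm.sum(axis=1) / total
        agg = lambda v: float((v * weights).sum())
    elif average == "micro":
        tp_s, fp_s, fn_s = tp.sum(), fp.sum(), fn.sum()
        p = tp_s / (tp_s + fp_s) if tp_s + fp_s else 0.0
        r = tp_s / (tp_s + fn_s) if tp_s + fn_s else 0.0
        f = 2 * p * r / (p + r) if p + r else 0.0
        return {
            "accuracy": float(tp.sum() / total),
            "precision": float(p),
            "recall": float(r),
            "f1": float(f),
        }
    else:
        raise ValueError(f"unknown average {average!r}")

    if paper_literal:
        accuracy = agg((tp + tn) / (tp + tn + fn))
    else:
        accuracy = float(tp.sum() / total)
    return {
        "accuracy": float(accuracy),
        "precision": agg(precision),
        "recall": agg(recall),
        "f1": agg(f1),
    }


def _default_models(seed: int) -> dict[str, object]:
    """Library-default hyperparameters, pinned here for reproducibility."""
    models: dict[str, object] = {
        "RandomForest": RandomForestClassifier(random_state=seed),
        "GradientBoosting": GradientBoostingClassifier(random_state=seed),
        "SVM": SVC(probability=True, random_state=seed),
        "KNN": KNeighborsClassifier(),
        "LogisticRegression": LogisticRegression(max_iter=2000),
    }
    return models


@dataclass
class BenchmarkReport:
    """Per-model metrics, confusion matrices, importances and skip notes."""

    metrics: pd.DataFrame
    confusion: dict[str, np.ndarray] = field(default_factory=dict)
    importances: list[tuple[str, float]] = field(default_factory=list)
    skipped: dict[str, str] = field(default_factory=dict)
    fitted: dict[str, object] = field(default_factory=dict)


def run_benchmark(
    X_train: np.ndarray,
    y_train: Sequence,
    X_test: np.ndarray,
    y_test: Sequence,
    feature_names: Sequence[str] | None = None,
    models: Sequence[str] = MODEL_FAMILIES,
    seed: int = 0,
    average: str = "macro",
) -> BenchmarkReport:
    """Train each family, score on the held-out split, collect the report.

    AUC-ROC is one-vs-rest, macro-averaged, from predicted class
    probabilities.  Nothing here refits scaling: callers must pass matrices
    already projected with training-set parameters.
    """
    y_train = np.asarray(y_train)
    y_test = np.asarray(y_test)
    classes = np.unique(np.concatenate([y_train, y_test]))
    available = _default_models(seed)

    rows = []
    report = BenchmarkReport(metrics=pd.DataFrame())
    for name in models:
        if name == "XGBoost":
            try:
                xgb = importlib.import_module("xgboost")
            except ImportError:
                report.skipped[name] = "optional dependency 'xgboost' not installed"
                continue
            model = xgb.XGBClassifier(random_state=seed, eval_metric="mlogloss")
        elif name in available:
            model = available[name]
        else:
            report.skipped[name] = "unknown model family"
            continue
        model.fit(X_train, y_train)
        y_pred = model.predict(X_test)
        cm = sk_confusion_matrix(y_test, y_pred, labels=classes)
        scores = metrics_from_confusion(cm, average=average)
        proba = model.predict_proba(X_test)
        if len(classes) == 2:
            auc = float(roc_auc_score(y_test, proba[:, 1]))
        else:
            auc = float(
                roc_auc_score(y_test, proba, multi_class="ovr", average="macro", labels=classes)
            )
        rows.append(
            {
                "model": name,
                "accuracy": scores["accuracy"],
                "precision": scores["precision"],
                "recall": scores["recall"],
                "f1": scores["f1"],
                "auc_roc": auc,
            }
        )
        report.confusion[name] = cm
        report.fitted[name] = model
    report.metrics = pd.DataFrame(rows)
    if "GradientBoosting" in report.fitted and feature_names is not None:
        report.importances = feature_importance(
            report.fitted["GradientBoosting"], feature_names
        )
    return report


def feature_importance(model, feature_names: Sequence[str]) -> list[tuple[str, float]]:
    """Impurity-gain importances, normalized to sum 1, descending."""
    importances = np.asarray(model.feature_importances_, dtype=float)
    if len(importances) != len(feature_names):
        raise ValueError("feature_names length must match the fitted model")
    total = importances.sum()
    if total > 0:
        importances = importances / total
    order = np.argsort(importances)[::-1]
    return [(feature_names[i], float(importances[i])) for i in order]
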