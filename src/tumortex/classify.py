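"""SVM and kNN classification with leave-one-out evaluation.

Label convention: +1 = malignant = the "positive" class for sensitivity
bookkeeping (a tumour case counted as TP when correctly flagged), −1 = benign.
The SVM is a soft-margin RBF machine; its kernel width is parameterised as
σ with K(x, z) = exp(−‖x−z‖²/2σ²), i.e. scikit-learn gamma = 1/(2σ²).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from sklearn.metrics import roc_curve as _sk_roc_curve
from sklearn.neighbors import KNeighborsClassifier
from sklearn.pipeline import make_pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC


@dataclass(frozen=True)
class SVMSettings:
    C: float = 1.0
    sigma: float = 1.0

    def __post_init__(self):
        if self.C <= 0 or self.sigma <= 0:
            raise ValueError("C and sigma must be positive")

    @property
    def gamma(self) -> float:
        return 1.0 / (2.0 * self.sigma**2)


def train_svm(X: np.ndarray, y: np.ndarray, settings: SVMSettings) -> SVC:
    """Fit a soft-margin RBF SVM; predictions are sign(decision score)."""
    y = np.asarray(y)
    if len(np.unique(y)) < 2:
        raise ValueError("training set contains a single class")
    clf = SVC(C=settings.C, kernel="rbf", gamma=settings.gamma)
    clf.fit(np.asarray(X, dtype=float), y)
    return clf


def confusion_metrics(predictions, labels) -> tuple[float, float, float]:
    """(sensitivity, specificity, accuracy) with +1 as positive.

    A zero denominator yields NaN for that metric rather than 0.
    """
    pred = np.asarray(predictions)
    lab = np.asarray(labels)
    tp = int(((pred == 1) & (lab == 1)).sum())
    tn = int(((pred == -1) & (lab == -1)).sum())
    fp = int(((pred == 1) & (lab == -1)).sum())
    fn = int(((pred == -1) & (lab == 1)).sum())
    sens = tp / (tp + fn) if tp + fn > 0 else math.nan
    spec = tn / (tn + fp) if tn + fp > 0 else math.nan
    acc = (tp + tn) / len(lab)
    return sens, spec, acc


def error_scores(predictions, labels) -> tuple[float, float]:
    """(rmse, mae) of the 0/1-encoded predicted classes against the labels."""
    pred = (np.asarray(predictions) > 0).astype(float)
    obs = (np.asarray(labels) > 0).astype(float)
    if pred.size == 0:
        raise ValueError("empty input")
    diff = pred - obs
    return float(np.sqrt((diff**2).mean())), float(np.abs(diff).mean())


def roc_points(scores, labels) -> tuple[np.ndarray, np.ndarray, float, tuple[float, float]]:
    """ROC sweep, trapezoidal AUC, and the max(TP−FP) operating point."""
    lab = np.asarray(labels)
    if len(np.unique(lab)) < 2:
        raise ValueError("ROC needs both classes")
    fpr, tpr, _ = _sk_roc_curve(lab, np.asarray(scores, dtype=float), pos_label=1)
    auc = float(np.trapezoid(tpr, fpr))
    k = int(np.argmax(tpr - fpr))
    return fpr, tpr, auc, (float(fpr[k]), float(tpr[k]))


@dataclass
class EvalReport:
    """Held-out evaluation summary of one classifier run."""

    tp: int
    tn: int
    fp: int
    fn: int
    sensitivity: float
    specificity: float
    accuracy: float
    rmse: float
    mae: float
    auc: float
    operating_point: tuple[float, float]
    predictions: np.ndarray
    scores: np.ndarray
    roc_fpr: np.ndarray = field(repr=False, default=None)
    roc_tpr: np.ndarray = field(repr=False, default=None)

    @property
    def n(self) -> int:
        return self.tp + self.tn + self.fp + self.fn

    def to_dict(self) -> dict:
        return {
            "tp": self.tp, "tn": self.tn, "fp": self.fp, "fn": self.fn,
            "sensitivity": self.sensitivity, "specificity": self.specificity,
            "accuracy": self.accuracy, "rmse": self.rmse, "mae": self.mae,
            "auc": self.auc, "operating_point": list(self.operating_point),
            "predictions": self.predictions.tolist(),
            "scores": self.scores.tolist(),
            "roc": {"fpr": self.roc_fpr.tolist(), "tpr": self.roc_tpr.tolist()},
        }


def _report_from(predictions, scores, labels) -> EvalReport:
    pred = np.asarray(predictions)
    lab = np.asarray(labels)
    tp = int(((pred == 1) & (lab == 1)).sum())
    tn = int(((pred == -1) & (lab == -1)).sum())
    fp = int(((pred == 1) & (lab == -1)).sum())
    fn = int(((pred == -1) & (lab == 1)).sum())
    sens, spec, acc = confusion_metrics(pred, lab)
    rmse, mae = error_scores(pred, lab)
    fpr, tpr, auc, op = roc_points(scores, lab)
    return EvalReport(
        tp=tp, tn=tn, fp=fp, fn=fn,
        sensitivity=sens, specificity=spec, accuracy=acc,
        rmse=rmse, mae=mae, auc=auc, operating_point=op,
        predictions=pred, scores=np.asarray(scores, dtype=float),
        roc_fpr=fpr, roc_tpr=tpr,
    )


def loo_evaluate(
    X: np.ndarray,
    y: np.ndarray,
    settings: SVMSettings | None = None,
    classifier: str = "svm",
    k: int = 5,
) -> EvalReport:
    """Leave-one-out evaluation: n fits, each scoring its held-out sample.

    Features are z-scored with each fold's training statistics before
    classification (the texture features span several orders of magnitude).
    A fold whose training split is single-class predicts the training
    majority class with a score at the class sign (documented fallback).
    With ``settings=None`` the SVM kernel width defaults to the data-driven
    scikit-learn ``gamma="scale"``, a sensible width when no tuned (C, σ)
    is available.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    n = len(y)
    if n < 2:
        raise ValueError("need at least two samples")
    gamma = settings.gamma if settings is not None else "scale"
    C = settings.C if settings is not None else 1.0
    preds = np.empty(n, dtype=int)
    scores = np.empty(n, dtype=float)
    for i in range(n):
        tr = np.arange(n) != i
        ytr = y[tr]
        if len(np.unique(ytr)) < 2:
            maj = 1 if (ytr == 1).sum() >= (ytr == -1).sum() else -1
            preds[i], scores[i] = maj, float(maj)
            continue
        if classifier == "svm":
            clf = make_pipeline(StandardScaler(), SVC(C=C, kernel="rbf", gamma=gamma))
            clf.fit(X[tr], ytr)
            s = float(clf.decision_function(X[i : i + 1])[0])
            preds[i] = 1 if s > 0 else -1
            scores[i] = s
        elif classifier == "knn":
            kk = min(k, len(ytr))
            clf = make_pipeline(StandardScaler(), KNeighborsClassifier(n_neighbors=kk))
            clf.fit(X[tr], ytr)
            proba = clf.predict_proba(X[i : i + 1])[0]
            classes = clf.classes_
            p_pos = float(proba[list(classes).index(1)]) if 1 in classes else 0.0
            scores[i] = 2 * p_pos - 1
            preds[i] = 1 if p_pos > 0.5 else -1
        else:
            raise ValueError(f"unknown classifier {classifier!r}")
    return _report_from(preds, scores, y)


def knn_baseline(X: np.ndarray, y: np.ndarray, k: int = 5) -> EvalReport:
    """Leave-one-out kNN (odd k: no ties on binary labels)."""
    if k % 2 == 0:
        raise ValueError("k must be odd")
    if k >= len(y):
        raise ValueError("k must be smaller than the sample count")
    return loo_evaluate(X, y, classifier="knn", k=k)


def compare_classifiers(errors_a, errors_b) -> tuple[float, float]:
    """Two-sided Wilcoxon signed-rank test on paired per-subject losses.

    Returns (statistic, p-value); identical error vectors give p = 1.
    """
    a = np.asarray(errors_a, dtype=float)
    b = np.asarray(errors_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("paired samples must have equal length")
    if a.size < 5:
        raise ValueError("need at least 5 pairs")
    diff = a - b
    if np.all(diff == 0):
        return 0.0, 1.0
    stat, p = stats.wilcoxon(a, b, zero_method="wilcox")
    return float(stat), float(p)
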