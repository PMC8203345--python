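"""Single-region SVM classification with leave-one-out cross-validation.

Each candidate region (a cluster's mean Fisher-z GFC) is evaluated alone:
for every held-out subject an RBF-kernel SVM is trained on the remaining
subjects and predicts the held-out label; sensitivity, specificity and
accuracy are derived from the pooled confusion counts (patients are the
positive class).

Hyperparameter handling:

* ``nested=True`` (default): per outer fold, (C, gamma) are chosen by an
  inner leave-one-out grid search on the training subjects only — an
  unbiased estimate.
* ``nested=False``: (C, gamma) are chosen by the *same* LOOCV whose
  accuracy is reported (optimistic; the report carries a leakage warning).

A single-point grid reduces both modes to plain fixed-hyperparameter
LOOCV.  Features are standardised with training-fold statistics only.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import product

import numpy as np
from sklearn.svm import SVC

DEFAULT_GRID = {"C": (0.1, 1.0, 10.0, 100.0), "gamma": (0.01, 0.1, 1.0, 10.0)}


@dataclass
class ClassifierReport:
    region: str
    true_labels: np.ndarray
    predicted_labels: np.ndarray
    tp: int
    tn: int
    fp: int
    fn: int
    sensitivity: float  # percent
    specificity: float  # percent
    accuracy: float  # percent
    kernel: str = "rbf"
    grid: dict = field(default_factory=dict)
    selected_params: list = field(default_factory=list)  # per outer fold
    nested: bool = True
    seed: int = 0
    warnings: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "region": self.region,
            "tp": self.tp, "tn": self.tn, "fp": self.fp, "fn": self.fn,
            "sensitivity_pct": self.sensitivity,
            "specificity_pct": self.specificity,
            "accuracy_pct": self.accuracy,
            "kernel": self.kernel,
            "grid": {k: list(v) for k, v in self.grid.items()},
            "nested": self.nested,
            "seed": self.seed,
            "warnings": self.warnings,
        }


def confusion_rates(tp: int, fn: int, tn: int, fp: int) -> tuple[float, float, float]:
    """(sensitivity, specificity, accuracy) as percentages, 2 decimals.

    sensitivity = tp/(tp+fn), specificity = tn/(tn+fp),
    accuracy = (tp+tn)/(tp+tn+fp+fn).
    """
    for name, v in (("tp", tp), ("fn", fn), ("tn", tn), ("fp", fp)):
        if v < 0:
            raise ValueError(f"{name} must be >= 0")
    if tp + fn < 1 or tn + fp < 1:
        raise ValueError("each class needs at least one subject")
    sens = 100.0 * tp / (tp + fn)
    spec = 100.0 * tn / (tn + fp)
    acc = 100.0 * (tp + tn) / (tp + tn + fp + fn)
    return round(sens, 2), round(spec, 2), round(acc, 2)


def _standardize(train: np.ndarray, test: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    mu = train.mean(axis=0)
    sd = train.std(axis=0)
    sd = np.where(sd < 1e-12, 1.0, sd)
    return (train - mu) / sd, (test - mu) / sd


def _loo_predictions(
    X: np.ndarray, y: np.ndarray, C: float, gamma: float, kernel: str
) -> np.ndarray:
    """Plain leave-one-out predictions at fixed hyperparameters."""
    n = len(y)
    pred = np.empty(n, dtype=y.dtype)
    for i in range(n):
        keep = np.ones(n, dtype=bool)
        keep[i] = False
        if len(np.unique(y[keep])) < 2:
            raise ValueError("single-class training fold")
        Xtr, Xte = _standardize(X[keep], X[i:i + 1])
        clf = SVC(C=C, gamma=gamma, kernel=kernel)
        clf.fit(Xtr, y[keep])
        pred[i] = clf.predict(Xte)[0]
    return pred


def loocv_svm(
    features: np.ndarray,
    labels: np.ndarray,
    region: str = "",
    kernel: str = "rbf",
    grid: dict | None = None,
    nested: bool = True,
    seed: int = 0,
) -> ClassifierReport:
    """Leave-one-out SVM evaluation of one feature set.

    ``labels`` are 1 for patients (positive class) and 0 for controls.
    """
    X = np.atleast_2d(np.asarray(features, dtype=float))
    if X.shape[0] == 1 and len(labels) > 1:
        X = X.T
    y = np.asarray(labels).astype(int)
    if not np.all(np.isfinite(X)):
        raise ValueError("features contain NaN or infinite values")
    if X.shape[0] != len(y):
        raise ValueError("features and labels disagree in length")
    counts = np.bincount(y, minlength=2)
    if counts[0] < 2 or counts[1] < 2:
        raise ValueError("need at least 2 subjects per class")

    grid = dict(DEFAULT_GRID) if grid is None else grid
    combos = list(product(grid["C"], grid["gamma"]))
    n = len(y)
    warnings: list[str] = []
    selected: list = []

    if nested or len(combos) == 1:
        pred = np.empty(n, dtype=int)
        for i in range(n):
            keep = np.ones(n, dtype=bool)
            keep[i] = False
            ytr = y[keep]
            if len(np.unique(ytr)) < 2:
                raise ValueError("single-class training fold")
            if len(combos) == 1:
                best = combos[0]
            else:
                # inner LOO grid search on the training subjects only
                best, best_acc = combos[0], -1.0
                for C, gamma in combos:
                    inner = _loo_predictions(X[keep], ytr, C, gamma, kernel)
                    acc = float((inner == ytr).mean())
                    if acc > best_acc:  # ties -> first (smallest C, gamma)
                        best, best_acc = (C, gamma), acc
            selected.append(best)
            Xtr, Xte = _standardize(X[keep], X[i:i + 1])
            clf = SVC(C=best[0], gamma=best[1], kernel=kernel)
            clf.fit(Xtr, ytr)
            pred[i] = clf.predict(Xte)[0]
        if len(combos) == 1:
            nested_used = True  # single point: nested and flat coincide
        else:
            nested_used = True
    else:
        # historical-practice mode: optimise (C, gamma) by the same LOOCV that
        # is reported — optimistic by selection, hence the warning.
        best, best_pred, best_acc = None, None, -1.0
        for C, gamma in combos:
            p = _loo_predictions(X, y, C, gamma, kernel)
            acc = float((p == y).mean())
            if acc > best_acc:
                best, best_pred, best_acc = (C, gamma), p, acc
        pred = best_pred
        selected = [best]
        nested_used = False
        warnings.append(
            "hyperparameters selected by the same LOOCV used for reporting; "
            "accuracy is optimistically biased"
        )

    tp = int(np.sum((pred == 1) & (y == 1)))
    fn = int(np.sum((pred == 0) & (y == 1)))
    tn = int(np.sum((pred == 0) & (y == 0)))
    fp = int(np.sum((pred == 1) & (y == 0)))
    sens, spec, acc = confusion_rates(tp, fn, tn, fp)
    return ClassifierReport(
        region=region,
        true_labels=y,
        predicted_labels=pred,
        tp=tp, tn=tn, fp=fp, fn=fn,
        sensitivity=sens, specificity=spec, accuracy=acc,
        kernel=kernel,
        grid=grid,
        selected_params=selected,
        nested=nested_used,
        seed=seed,
        warnings=warnings,
    )
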