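"""Cough/noise recognition with an SVM, and the evaluation-metric battery.

The recognizer is a scikit-learn-compatible estimator
(:class:`CoughClassifier`): z-score standardization fitted on the training
rows only, followed by an RBF-kernel support vector machine.  Labels are
the strings ``"Cough"`` (positive class) and ``"Noise"``.

Evaluation reports accuracy, sensitivity, specificity, Matthews
correlation, positive/negative predictive value, F1 and Cohen's kappa
from the confusion counts, with zero-denominator ratios returned as NaN
(a distinguished not-a-value) rather than a silent 0.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import isnan, sqrt
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.model_selection import StratifiedKFold
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC
from sklearn.utils.validation import check_is_fitted

POSITIVE_LABEL = "Cough"
NEGATIVE_LABEL = "Noise"


@dataclass(frozen=True)
class LabeledDataset:
    """Feature matrix plus Cough/Noise labels for training or evaluation."""

    features: np.ndarray
    labels: np.ndarray

    def __post_init__(self) -> None:
        features = np.asarray(self.features, dtype=np.float64)
        labels = np.asarray(self.labels)
        if features.ndim != 2:
            raise ValueError(f"features must be 2-D, got shape {features.shape}")
        if labels.shape != (features.shape[0],):
            raise ValueError("labels must have one entry per feature row")
        if not np.all(np.isfinite(features)):
            raise ValueError("features contain non-finite values")
        unknown = set(np.unique(labels)) - {POSITIVE_LABEL, NEGATIVE_LABEL}
        if unknown:
            raise ValueError(f"unknown labels: {sorted(unknown)}")
        object.__setattr__(self, "features", features)
        object.__setattr__(self, "labels", labels)

    def __len__(self) -> int:
        return self.features.shape[0]


@dataclass(frozen=True)
class ConfusionCounts:
    """Binary confusion counts with Cough as the positive class."""

    tp: int
    fn: int
    fp: int
    tn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fn, self.fp, self.tn) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.fn + self.fp + self.tn


@dataclass(frozen=True)
class MetricsReport:
    """Classification metrics; undefined (zero-denominator) entries are NaN."""

    acc: float
    sen: float
    spe: float
    mcc: float
    ppv: float
    npv: float
    f1: float
    kappa: float

    def as_dict(self) -> dict[str, float]:
        return {
            "acc": self.acc, "sen": self.sen, "spe": self.spe, "mcc": self.mcc,
            "ppv": self.ppv, "npv": self.npv, "f1": self.f1, "kappa": self.kappa,
        }


def _ratio(num: float, den: float) -> float:
    return num / den if den > 0 else float("nan")


def metrics_from_counts(c: ConfusionCounts) -> MetricsReport:
    """Closed-form metrics from the four confusion counts.

    ACC=(TP+TN)/all, SEN=TP/(TP+FN), SPE=TN/(TN+FP), PPV=TP/(TP+FP),
    NPV=TN/(TN+FN), F1 as the harmonic mean of PPV and SEN, MCC with the
    four-marginal denominator, and Cohen's kappa = (p_o - p_e)/(1 - p_e)
    with p_o = ACC and p_e from the confusion marginals.
    """
    tp, fn, fp, tn = float(c.tp), float(c.fn), float(c.fp), float(c.tn)
    n = tp + fn + fp + tn
    if n == 0:
        raise ValueError("cannot compute metrics of an empty evaluation")
    acc = (tp + tn) / n
    sen = _ratio(tp, tp + fn)
    spe = _ratio(tn, tn + fp)
    ppv = _ratio(tp, tp + fp)
    npv = _ratio(tn, tn + fn)
    mcc_den = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    mcc = (tp * tn - fp * fn) / sqrt(mcc_den) if mcc_den > 0 else float("nan")
    f1 = _ratio(2.0 * ppv * sen, ppv + sen) if not (isnan(ppv) or isnan(sen)) else float("nan")
    p_e = ((tp + fn) * (tp + fp) + (tn + fp) * (tn + fn)) / (n * n)
    kappa = (acc - p_e) / (1.0 - p_e) if p_e < 1.0 else float("nan")
    return MetricsReport(acc=acc, sen=sen, spe=spe, mcc=mcc, ppv=ppv, npv=npv,
                         f1=f1, kappa=kappa)


def evaluate(
    pred: Sequence[str], truth: Sequence[str]
) -> tuple[ConfusionCounts, MetricsReport]:
    """Tally a prediction against ground truth and compute all metrics."""
    pred = np.asarray(pred)
    truth = np.asarray(truth)
    if pred.shape != truth.shape or pred.ndim != 1 or pred.size == 0:
        raise ValueError(
            f"pred and truth must be equal-length non-empty 1-D sequences, "
            f"got {pred.shape} vs {truth.shape}"
        )
    p_pos = pred == POSITIVE_LABEL
    t_pos = truth == POSITIVE_LABEL
    counts = ConfusionCounts(
        tp=int(np.sum(p_pos & t_pos)),
        fn=int(np.sum(~p_pos & t_pos)),
        fp=int(np.sum(p_pos & ~t_pos)),
        tn=int(np.sum(~p_pos & ~t_pos)),
    )
    return counts, metrics_from_counts(counts)


class CoughClassifier(BaseEstimator, ClassifierMixin):
    """Standardize-then-SVM cough/noise recognizer.

    Parameters
    ----------
    C, gamma, kernel
        Passed to :class:`sklearn.svm.SVC` (defaults: RBF kernel, C=1,
        gamma='scale' i.e. 1/(d*var)).
    random_state
        Seed making training deterministic.

    Attributes (after :meth:`fit`)
    ------------------------------
    scaler_ : fitted per-column standardizer
    svc_ : fitted support vector machine
    classes_ : the two class labels
    n_features_in_ : training feature dimension
    """

    def __init__(self, C: float = 1.0, gamma: str | float = "scale",
                 kernel: str = "rbf", random_state: int = 0) -> None:
        self.C = C
        self.gamma = gamma
        self.kernel = kernel
        self.random_state = random_state

    def fit(self, X: np.ndarray, y: Sequence[str]) -> "CoughClassifier":
        X = np.asarray(X, dtype=np.float64)
        y = np.asarray(y)
        if X.ndim != 2 or X.shape[0] != y.shape[0]:
            raise ValueError("X must be 2-D with one label per row")
        if len(np.unique(y)) < 2:
            raise ValueError("training data must contain both classes")
        self.scaler_ = StandardScaler().fit(X)
        self.svc_ = SVC(C=self.C, gamma=self.gamma, kernel=self.kernel,
                        random_state=self.random_state)
        self.svc_.fit(self.scaler_.transform(X), y)
        self.classes_ = self.svc_.classes_
        self.n_features_in_ = X.shape[1]
        return self

    def predict(self, X: np.ndarray) -> np.ndarray:
        check_is_fitted(self, "svc_")
        X = np.asarray(X, dtype=np.float64)
        if X.size == 0:
            return np.asarray([], dtype=self.classes_.dtype)
        if X.ndim != 2 or X.shape[1] != self.n_features_in_:
            raise ValueError(
                f"feature dimension mismatch: model was trained on "
                f"{self.n_features_in_} columns, input has "
                f"{X.shape[1] if X.ndim == 2 else X.shape}"
            )
        return self.svc_.predict(self.scaler_.transform(X))


def train_classifier(
    data: LabeledDataset, seed: int = 0, **kernel_config
) -> CoughClassifier:
    """Convenience wrapper: fit a :class:`CoughClassifier` on a dataset."""
    return CoughClassifier(random_state=seed, **kernel_config).fit(
        data.features, data.labels
    )


def cross_validated_metrics(
    data: LabeledDataset, n_splits: int = 5, seed: int = 0, **kernel_config
) -> tuple[ConfusionCounts, MetricsReport]:
    """Pooled stratified k-fold cross-validation of the classifier.

    Out-of-fold predictions from every fold are pooled into one confusion
    matrix, so each segment is scored exactly once by a model that never
    saw it; standardization is refitted inside each training fold.
    """
    skf = StratifiedKFold(n_splits=n_splits, shuffle=True, random_state=seed)
    pred = np.empty(len(data), dtype=object)
    for train_idx, test_idx in skf.split(data.features, data.labels):
        model = CoughClassifier(random_state=seed, **kernel_config).fit(
            data.features[train_idx], data.labels[train_idx]
        )
        pred[test_idx] = model.predict(data.features[test_idx])
    return evaluate(pred.astype(str), data.labels)


def compare_feature_combinations(
    datasets: Mapping[str, LabeledDataset], n_splits: int = 5, seed: int = 0
) -> pd.DataFrame:
    """Cross-validated metrics for several feature combinations of the
    same segments; one row per combination, metric columns in percent
    (kappa as a plain value).
    """
    lengths = {len(d) for d in datasets.values()}
    if len(lengths) > 1:
        raise ValueError(f"combinations have mismatched row counts: {sorted(lengths)}")
    rows = {}
    for name, data in datasets.items():
        _, report = cross_validated_metrics(data, n_splits=n_splits, seed=seed)
        rows[name] = {
            "ACC (%)": 100 * report.acc, "SEN (%)": 100 * report.sen,
            "SPE (%)": 100 * report.spe, "MCC (%)": 100 * report.mcc,
            "PPV (%)": 100 * report.ppv, "NPV (%)": 100 * report.npv,
            "F1 (%)": 100 * report.f1, "Kappa": report.kappa,
        }
    return pd.DataFrame.from_dict(rows, orient="index")
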