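"""Evaluation protocol: stratified 70:30 holdout, 10-fold CV, a
ten-classifier zoo and seven reported measures.

The zoo mirrors the presets those classifier names conventionally denote
in GUI learner toolboxes: four SVMs (linear, quadratic, cubic, medium
Gaussian), three KNNs (cosine k=10, coarse k=100, distance-weighted
k=10), and three ensembles (random-subspace discriminant, boosted trees,
random-subspace KNN).  All hyperparameters are overridable per config.

Metrics are computed from the (fold-pooled) confusion matrix: macro
recall and precision in percent, FNR = 100 - macro recall, accuracy =
trace/total, F1 as the harmonic mean of macro precision and recall, and
macro one-vs-rest AUC from decision scores when the classifier provides
them (a confusion-derived fallback is used otherwise).  Wall time per
classifier is reported but never asserted.
"""

from __future__ import annotations

import time
import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.base import clone
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
from sklearn.ensemble import AdaBoostClassifier, BaggingClassifier
from sklearn.metrics import confusion_matrix, roc_auc_score
from sklearn.model_selection import StratifiedKFold, train_test_split
from sklearn.neighbors import KNeighborsClassifier
from sklearn.pipeline import make_pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier

from .matrix import FeatureMatrix

__all__ = [
    "ClassifierConfig",
    "EvaluationReport",
    "ZOO_NAMES",
    "make_classifier",
    "split_holdout",
    "cross_validate",
    "compute_metrics",
    "run_zoo",
]

ZOO_NAMES = (
    "LSVM",
    "QSVM",
    "CSVM",
    "MGSVM",
    "CosineKNN",
    "CoarseKNN",
    "WKNN",
    "ESKNN",
    "EBT",
    "ESD",
)


@dataclass
class ClassifierConfig:
    """A named zoo member plus any preset overrides."""

    name: str
    params: dict = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.name not in ZOO_NAMES:
            raise ValueError(f"unknown classifier {self.name!r}; pick from {ZOO_NAMES}")


@dataclass
class MetricRow:
    """One classifier's pooled confusion matrix and metric suite."""

    name: str
    confusion: np.ndarray
    recall_pct: float
    precision_pct: float
    fnr_pct: float
    auc: float
    accuracy_pct: float
    f1_pct: float
    time_sec: float

    def as_dict(self) -> dict:
        return {
            "name": self.name,
            "confusion": self.confusion.tolist(),
            "recall_pct": self.recall_pct,
            "precision_pct": self.precision_pct,
            "fnr_pct": self.fnr_pct,
            "auc": self.auc,
            "accuracy_pct": self.accuracy_pct,
            "f1_pct": self.f1_pct,
            "time_sec": self.time_sec,
        }


@dataclass
class EvaluationReport:
    """Zoo results under a named protocol; best row flagged by accuracy."""

    protocol: str
    rows: list[MetricRow] = field(default_factory=list)

    @property
    def best(self) -> MetricRow:
        return max(self.rows, key=lambda r: r.accuracy_pct)

    def as_dict(self) -> dict:
        return {
            "protocol": self.protocol,
            "best": self.best.name,
            "rows": [r.as_dict() for r in self.rows],
        }


def make_classifier(cfg: ClassifierConfig, n_train: int | None = None):
    """Instantiate a zoo member with its conventional preset."""
    name, seed = cfg.name, cfg.seed
    if name == "LSVM":
        est = SVC(kernel="linear", random_state=seed)
    elif name == "QSVM":
        est = SVC(kernel="poly", degree=2, coef0=1.0, random_state=seed)
    elif name == "CSVM":
        est = SVC(kernel="poly", degree=3, coef0=1.0, random_state=seed)
    elif name == "MGSVM":
        est = SVC(kernel="rbf", gamma="scale", random_state=seed)
    elif name == "CosineKNN":
        est = KNeighborsClassifier(n_neighbors=10, metric="cosine")
    elif name == "CoarseKNN":
        est = KNeighborsClassifier(n_neighbors=100)
    elif name == "WKNN":
        est = KNeighborsClassifier(n_neighbors=10, weights="distance")
    elif name == "ESKNN":
        est = BaggingClassifier(
            KNeighborsClassifier(n_neighbors=5),
            n_estimators=30,
            max_features=0.5,
            bootstrap=False,
            random_state=seed,
        )
    elif name == "EBT":
        est = AdaBoostClassifier(
            DecisionTreeClassifier(max_depth=3, random_state=seed),
            n_estimators=30,
            random_state=seed,
        )
    else:  # ESD: random-subspace linear discriminant
        est = BaggingClassifier(
            LinearDiscriminantAnalysis(),
            n_estimators=30,
            max_features=0.5,
            bootstrap=False,
            random_state=seed,
        )
    est.set_params(**cfg.params)
    # coarse KNN cannot ask for more neighbors than training points
    if isinstance(est, KNeighborsClassifier) and n_train is not None:
        est.set_params(n_neighbors=min(est.n_neighbors, max(n_train - 1, 1)))
    if isinstance(est, SVC):
        return make_pipeline(StandardScaler(), est)
    return est


def split_holdout(fm: FeatureMatrix, ratio: float = 0.7, seed: int = 0):
    """Stratified holdout split into (train, test) FeatureMatrix pair."""
    if not 0 < ratio < 1:
        raise ValueError("ratio must lie strictly between 0 and 1")
    _, counts = np.unique(fm.labels, return_counts=True)
    if counts.min() < 2:
        raise ValueError("every class needs at least 2 samples to stratify")
    idx_tr, idx_te = train_test_split(
        np.arange(fm.n_samples),
        train_size=ratio,
        stratify=fm.labels,
        random_state=seed % (2**32),
    )
    def _take(idx):
        return FeatureMatrix(
            fm.values[idx], fm.labels[idx], list(fm.column_ids), fm.source_tag
        )
    return _take(np.sort(idx_tr)), _take(np.sort(idx_te))


def compute_metrics(confusion: np.ndarray) -> dict:
    """Metric suite from a square confusion matrix (rows = true class)."""
    cm = np.asarray(confusion, dtype=float)
    if cm.ndim != 2 or cm.shape[0] != cm.shape[1] or cm.size == 0:
        raise ValueError("confusion must be a non-empty square matrix")
    if (cm < 0).any():
        raise ValueError("confusion counts must be nonnegative")
    row_sums = cm.sum(axis=1)
    col_sums = cm.sum(axis=0)
    diag = np.diag(cm)
    with np.errstate(invalid="ignore", divide="ignore"):
        recall = np.where(row_sums > 0, diag / row_sums, 0.0)
        precision = np.where(col_sums > 0, diag / col_sums, 0.0)
    macro_recall = 100.0 * recall.mean()
    macro_precision = 100.0 * precision.mean()
    accuracy = 100.0 * diag.sum() / cm.sum()
    denom = macro_precision + macro_recall
    f1 = 2.0 * macro_precision * macro_recall / denom if denom > 0 else 0.0
    return {
        "recall_pct": macro_recall,
        "precision_pct": macro_precision,
        "fnr_pct": 100.0 - macro_recall,
        "accuracy_pct": accuracy,
        "f1_pct": f1,
    }


def _auc_from_confusion(cm: np.ndarray) -> float:
    """Macro OVR AUC surrogate from per-class TPR/FPR points (trapezoid)."""
    cm = np.asarray(cm, dtype=float)
    total = cm.sum()
    aucs = []
    for c in range(cm.shape[0]):
        pos = cm[c].sum()
        neg = total - pos
        if pos == 0 or neg == 0:
            continue
        tpr = cm[c, c] / pos
        fpr = (cm[:, c].sum() - cm[c, c]) / neg
        aucs.append((1.0 + tpr - fpr) / 2.0)
    return float(np.mean(aucs)) if aucs else 0.5


def _scores_of(model, X) -> np.ndarray | None:
    if hasattr(model, "predict_proba"):
        try:
            return model.predict_proba(X)
        except Exception:
            return None
    if hasattr(model, "decision_function"):
        try:
            s = model.decision_function(X)
            return s if s.ndim == 2 else np.column_stack([-s, s])
        except Exception:
            return None
    return None


def _macro_auc(y_true_codes, scores, n_classes) -> float | None:
    if scores is None or scores.shape[1] != n_classes:
        return None
    present = np.unique(y_true_codes)
    if present.size < 2:
        return None
    try:
        if present.size < n_classes:
            scores = scores[:, present]
            remap = {c: i for i, c in enumerate(present)}
            y_true_codes = np.array([remap[c] for c in y_true_codes])
        if scores.shape[1] == 2:
            return float(roc_auc_score(y_true_codes, scores[:, 1]))
        return float(
            roc_auc_score(y_true_codes, scores, multi_class="ovr", average="macro")
        )
    except ValueError:
        return None


def cross_validate(
    fm: FeatureMatrix,
    cfg: ClassifierConfig,
    k: int = 10,
    seed: int = 0,
) -> MetricRow:
    """Stratified k-fold CV; metrics from the fold-pooled confusion matrix."""
    classes, y = np.unique(fm.labels, return_inverse=True)
    min_count = np.bincount(y).min()
    if min_count < k:
        warnings.warn(
            f"smallest class has {min_count} samples; reducing folds to {min_count}",
            stacklevel=2,
        )
        k = max(int(min_count), 2)
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed % (2**32))
    n_classes = classes.size
    cm = np.zeros((n_classes, n_classes), dtype=int)
    all_true, all_scores = [], []
    scores_ok = True
    t0 = time.perf_counter()
    for tr, te in skf.split(fm.values, y):
        model = make_classifier(cfg, n_train=len(tr))
        model.fit(fm.values[tr], y[tr])
        pred = model.predict(fm.values[te])
        cm += confusion_matrix(y[te], pred, labels=np.arange(n_classes))
        s = _scores_of(model, fm.values[te])
        if s is None or s.shape[1] != n_classes:
            scores_ok = False
        else:
            all_true.append(y[te])
            all_scores.append(s)
    elapsed = time.perf_counter() - t0
    auc = None
    if scores_ok and all_scores:
        auc = _macro_auc(np.concatenate(all_true), np.vstack(all_scores), n_classes)
    if auc is None:
        auc = _auc_from_confusion(cm)
    m = compute_metrics(cm)
    return MetricRow(
        name=cfg.name, confusion=cm, auc=auc, time_sec=elapsed, **m
    )


def _holdout_row(fm: FeatureMatrix, cfg: ClassifierConfig, ratio, seed) -> MetricRow:
    train, test = split_holdout(fm, ratio=ratio, seed=seed)
    classes = np.unique(fm.labels)
    code = {c: i for i, c in enumerate(classes)}
    y_tr = np.array([code[c] for c in train.labels])
    y_te = np.array([code[c] for c in test.labels])
    t0 = time.perf_counter()
    model = make_classifier(cfg, n_train=train.n_samples)
    model.fit(train.values, y_tr)
    pred = model.predict(test.values)
    elapsed = time.perf_counter() - t0
    cm = confusion_matrix(y_te, pred, labels=np.arange(classes.size))
    auc = _macro_auc(y_te, _scores_of(model, test.values), classes.size)
    if auc is None:
        auc = _auc_from_confusion(cm)
    return MetricRow(
        name=cfg.name, confusion=cm, auc=auc, time_sec=elapsed,
        **compute_metrics(cm),
    )


def run_zoo(
    fm: FeatureMatrix,
    zoo: list[ClassifierConfig] | None = None,
    protocol: str = "cv",
    k: int = 10,
    ratio: float = 0.7,
    seed: int = 0,
) -> EvaluationReport:
    """Evaluate a list of classifiers under one protocol; one row each."""
    if zoo is None:
        zoo = [ClassifierConfig(name=n, seed=seed) for n in ZOO_NAMES]
    if not zoo:
        raise ValueError("classifier zoo is empty")
    if len({c.name for c in zoo}) != len(zoo):
        raise ValueError("classifier names must be unique within a zoo run")
    if protocol not in ("cv", "holdout"):
        raise ValueError("protocol must be 'cv' or 'holdout'")
    report = EvaluationReport(protocol=protocol)
    for cfg in zoo:
        if protocol == "cv":
            report.rows.append(cross_validate(fm, cfg, k=k, seed=seed))
        else:
            report.rows.append(_holdout_row(fm, cfg, ratio, seed))
    return report
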