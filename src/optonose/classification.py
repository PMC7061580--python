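"""SVM-based VOC classification, one model per film thickness.

Each cycle is one sample.  The classifier is an RBF-kernel SVM (C=100,
gamma=0.1) evaluated by stratified 10-fold cross-validation; features are
z-scored using statistics computed on each fold's training rows only (the
RBF width presupposes commensurate feature scales).  Results are reported as
row-normalized confusion matrices plus pooled and fold-averaged accuracy and
macro precision.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.model_selection import StratifiedKFold
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .features import FEATURE_NAMES

__all__ = [
    "Dataset",
    "CVConfig",
    "CrossValResult",
    "ClassificationReport",
    "assemble_dataset",
    "crossval_predict",
    "confusion_matrix_normalized",
    "summarize_report",
]

logger = logging.getLogger(__name__)


@dataclass
class Dataset:
    """Feature matrix + labels for a single film thickness."""

    features: np.ndarray  # (n_cycles, n_features)
    labels: np.ndarray  # VOC label per row
    thickness_um: float
    groups: np.ndarray | None = None  # replicate id per row

    def __post_init__(self) -> None:
        self.features = np.asarray(self.features, dtype=float)
        self.labels = np.asarray(self.labels)
        if self.features.shape[0] != self.labels.shape[0]:
            raise ValueError("features and labels disagree on the number of rows")

    @property
    def n_samples(self) -> int:
        return self.features.shape[0]

    @property
    def classes(self) -> np.ndarray:
        return np.unique(self.labels)


@dataclass(frozen=True)
class CVConfig:
    n_folds: int = 10
    stratified: bool = True
    seed: int = 0
    C: float = 100.0
    gamma: float = 0.1
    standardize: bool = True
    group_by_replicate: bool = False

    def __post_init__(self) -> None:
        if self.n_folds < 2:
            raise ValueError("n_folds must be >= 2")
        if self.C <= 0 or self.gamma <= 0:
            raise ValueError("C and gamma must be positive")


@dataclass
class CrossValResult:
    """Out-of-fold predictions plus the per-fold bookkeeping tests rely on."""

    predictions: np.ndarray  # predicted label per row
    fold_of_row: np.ndarray  # test-fold index per row
    fold_train_means: list[np.ndarray] = field(default_factory=list)
    fold_train_stds: list[np.ndarray] = field(default_factory=list)

    def fold_accuracies(self, labels: np.ndarray) -> np.ndarray:
        accs = []
        for f in np.unique(self.fold_of_row):
            m = self.fold_of_row == f
            accs.append(float(np.mean(self.predictions[m] == labels[m])))
        return np.array(accs)


@dataclass
class ClassificationReport:
    confusion: np.ndarray  # row-normalized, rows = true VOC
    label_order: list[str]
    overall_accuracy: float
    mean_fold_accuracy: float
    per_voc_accuracy: dict[str, float]
    macro_precision: float
    thickness_um: float

    def to_dict(self) -> dict:
        return {
            "thickness_um": self.thickness_um,
            "overall_accuracy": self.overall_accuracy,
            "mean_fold_accuracy": self.mean_fold_accuracy,
            "macro_precision": self.macro_precision,
            "per_voc_accuracy": self.per_voc_accuracy,
        }


def assemble_dataset(feature_table: pd.DataFrame, thickness_um: float, n_folds: int = 10) -> Dataset:
    """Filter the pooled feature table down to one film thickness.

    The table must carry ``voc``, ``thickness_um``, ``replicate_id`` and the
    twelve feature columns.  Classes with fewer rows than ``n_folds`` cannot
    be stratified and raise an explicit error naming the class.
    """
    if feature_table.empty:
        raise ValueError("feature table is empty")
    sub = feature_table[feature_table["thickness_um"] == thickness_um]
    if sub.empty:
        available = sorted(feature_table["thickness_um"].unique())
        raise ValueError(f"no rows for thickness {thickness_um} um (available: {available})")
    counts = sub["voc"].value_counts()
    too_small = counts[counts < n_folds]
    if not too_small.empty:
        raise ValueError(
            f"class(es) with fewer than n_folds={n_folds} cycles: {sorted(too_small.index)}"
        )
    groups = sub["replicate_id"].to_numpy() if "replicate_id" in sub.columns else None
    return Dataset(
        features=sub[list(FEATURE_NAMES)].to_numpy(),
        labels=sub["voc"].to_numpy(),
        thickness_um=thickness_um,
        groups=groups,
    )


def _make_pipeline(cfg: CVConfig) -> Pipeline:
    steps = []
    if cfg.standardize:
        steps.append(("scale", StandardScaler()))
    steps.append(("svm", SVC(kernel="rbf", C=cfg.C, gamma=cfg.gamma)))
    return Pipeline(steps)


def crossval_predict(dataset: Dataset, cfg: CVConfig) -> CrossValResult:
    """Out-of-fold predictions: every cycle predicted exactly once by a model
    that never saw it in training.  Deterministic given ``cfg.seed``."""
    X, y = dataset.features, dataset.labels
    if len(dataset.classes) < 2:
        warnings.warn("single-class dataset: predictions are trivially that class")
        return CrossValResult(
            predictions=y.copy(),
            fold_of_row=np.zeros(len(y), dtype=int),
        )
    smallest = int(pd.Series(y).value_counts().min())
    if cfg.n_folds > smallest:
        raise ValueError(
            f"n_folds={cfg.n_folds} exceeds the smallest class count ({smallest})"
        )
    splitter = StratifiedKFold(n_splits=cfg.n_folds, shuffle=True, random_state=cfg.seed)
    predictions = np.empty(len(y), dtype=y.dtype)
    fold_of_row = np.empty(len(y), dtype=int)
    train_means, train_stds = [], []
    for f, (train, test) in enumerate(splitter.split(X, y)):
        pipe = _make_pipeline(cfg)
        pipe.fit(X[train], y[train])
        predictions[test] = pipe.predict(X[test])
        fold_of_row[test] = f
        if cfg.standardize:
            scaler: StandardScaler = pipe.named_steps["scale"]
            train_means.append(scaler.mean_.copy())
            train_stds.append(np.sqrt(scaler.var_))
    return CrossValResult(
        predictions=predictions,
        fold_of_row=fold_of_row,
        fold_train_means=train_means,
        fold_train_stds=train_stds,
    )


def confusion_matrix_normalized(
    true_labels: np.ndarray,
    predicted_labels: np.ndarray,
    label_order: list[str],
) -> np.ndarray:
    """Row-normalized confusion matrix: entry (i, j) = P(pred=j | true=i).

    Rows with zero support come back all-zero (and are logged), so every
    populated row sums to exactly 1.
    """
    true_labels = np.asarray(true_labels)
    predicted_labels = np.asarray(predicted_labels)
    if true_labels.shape != predicted_labels.shape:
        raise ValueError("label sequences must have equal length")
    index = {lab: i for i, lab in enumerate(label_order)}
    unknown = set(true_labels) | set(predicted_labels)
    unknown -= set(label_order)
    if unknown:
        raise ValueError(f"labels outside label_order: {sorted(unknown)}")
    counts = np.zeros((len(label_order), len(label_order)))
    for t, p in zip(true_labels, predicted_labels):
        counts[index[t], index[p]] += 1
    support = counts.sum(axis=1)
    out = np.zeros_like(counts)
    for i, s in enumerate(support):
        if s == 0:
            logger.warning("class %r has zero support; confusion row left all-zero", label_order[i])
        else:
            out[i] = counts[i] / s
    return out


def summarize_report(
    confusion: np.ndarray,
    true_labels: np.ndarray,
    result: CrossValResult,
    label_order: list[str],
    thickness_um: float,
) -> ClassificationReport:
    """Pooled accuracy, fold-mean accuracy, per-class recall, macro precision.

    Macro precision is the unweighted mean of column-wise precision; classes
    never predicted contribute 0 and are logged.
    """
    true_labels = np.asarray(true_labels)
    pred = result.predictions
    overall = float(np.mean(pred == true_labels))
    fold_mean = float(result.fold_accuracies(true_labels).mean())
    per_voc = {lab: float(confusion[i, i]) for i, lab in enumerate(label_order)}

    precisions = []
    for lab in label_order:
        predicted_mask = pred == lab
        if not predicted_mask.any():
            logger.warning("class %r never predicted; precision counted as 0", lab)
            precisions.append(0.0)
        else:
            precisions.append(float(np.mean(true_labels[predicted_mask] == lab)))
    return ClassificationReport(
        confusion=confusion,
        label_order=list(label_order),
        overall_accuracy=overall,
        mean_fold_accuracy=fold_mean,
        per_voc_accuracy=per_voc,
        macro_precision=float(np.mean(precisions)),
        thickness_um=thickness_um,
    )
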