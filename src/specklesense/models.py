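"""Classification back-ends and evaluation metrics.

Two back-ends classify a recording into one of the reference glucose levels:

* an SVM on fixed-length feature vectors built from the lock-in filtered
  displacement series (one row of 500 columns per video: 250 uniformly
  resampled points per displacement axis), with hyperparameters chosen by
  Gaussian-process Bayesian optimization of the mean 5-fold stratified
  cross-validation accuracy;
* a CNN→LSTM sequence model on stacks of normalized pixel-wise frame
  differences (see :mod:`specklesense.nn`).

Evaluation uses the standard one-vs-rest confusion-matrix metrics:
precision = TP/(TP+FP), recall = TP/(TP+FN), F1 = 2PR/(P+R), with the
zero-division convention that an undefined ratio counts as 0, and the
aggregate score is the unweighted (macro) mean of per-class F1.
"""

from __future__ import annotations

import json
import pickle
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.model_selection import StratifiedKFold, cross_val_score, train_test_split
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from . import bayesopt
from .exceptions import DegenerateInputError, InvalidInputError, InvalidParameterError
from .simulator import SpeckleVideo

__all__ = [
    "FeatureMatrix",
    "DifferenceSequence",
    "TrainConfig",
    "ClassifierReport",
    "frame_difference_stack",
    "build_ml_features",
    "GlucoseSVM",
    "SVMResults",
    "train_svm",
    "predict",
    "evaluate_classifier",
    "stratified_split",
]


@dataclass
class FeatureMatrix:
    """Sample-by-feature matrix with per-row glucose class labels."""

    X: np.ndarray  # (n_samples, n_features)
    labels: np.ndarray  # (n_samples,)

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=np.float64)
        self.labels = np.asarray(self.labels)
        if self.X.ndim != 2 or self.X.shape[0] != self.labels.shape[0]:
            raise InvalidInputError("X must be 2D with one label per row")

    @property
    def n_features(self) -> int:
        return self.X.shape[1]


@dataclass
class DifferenceSequence:
    """Normalized pixel-wise difference stack of one video (length frames−1)."""

    frames: np.ndarray  # (n_frames - 1, H, W), scaled to [0, 1]
    label: float

    def __post_init__(self) -> None:
        if not np.all(np.isfinite(self.frames)):
            raise InvalidInputError("difference frames must be finite")


@dataclass(frozen=True)
class TrainConfig:
    """Neural-network training hyperparameters."""

    learning_rate: float = 1e-4
    gradient_threshold: float = 2.0
    batch_size: int = 16
    shuffle_each_epoch: bool = True
    epochs: int = 100
    seed: int = 0
    train_fraction: float = 0.7

    def __post_init__(self) -> None:
        if not (0.0 < self.train_fraction < 1.0):
            raise InvalidParameterError("train_fraction must lie in (0, 1)")
        if self.learning_rate <= 0:
            raise InvalidParameterError("learning_rate must be > 0")


@dataclass
class ClassifierReport:
    """Confusion matrix plus the derived one-vs-rest metrics."""

    confusion: np.ndarray  # (K, K), rows = true class
    class_order: list
    accuracy: float
    per_class_precision: np.ndarray
    per_class_recall: np.ndarray
    per_class_f1: np.ndarray
    macro_f1: float
    metadata: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "class_order": [str(c) for c in self.class_order],
            "confusion": self.confusion.tolist(),
            "accuracy": self.accuracy,
            "per_class_precision": self.per_class_precision.tolist(),
            "per_class_recall": self.per_class_recall.tolist(),
            "per_class_f1": self.per_class_f1.tolist(),
            "macro_f1": self.macro_f1,
            "metadata": self.metadata,
        }

    def to_json(self, path: str | Path) -> Path:
        path = Path(path)
        path.write_text(json.dumps(self.to_dict(), indent=2))
        return path

    def per_class_table(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "class": self.class_order,
                "precision": self.per_class_precision,
                "recall": self.per_class_recall,
                "f1": self.per_class_f1,
                "support": self.confusion.sum(axis=1),
            }
        )

    def summary(self) -> str:
        lines = [
            f"samples: {int(self.confusion.sum())}  classes: {len(self.class_order)}",
            f"accuracy: {self.accuracy:.4f}  macro-F1: {self.macro_f1:.4f}",
            self.per_class_table().to_string(index=False),
        ]
        return "\n".join(lines)


def frame_difference_stack(video: SpeckleVideo | np.ndarray) -> DifferenceSequence:
    """Pixel-wise differences of consecutive frames, min-max scaled per video.

    The scaling floor is min(0, smallest difference) so an all-positive
    difference stack keeps its zero reference; a constant video yields an
    all-zero stack.
    """
    if isinstance(video, SpeckleVideo):
        frames = video.frames
        label = video.label
    else:
        frames = np.asarray(video)
        label = float("nan")
    if frames.ndim != 3 or frames.shape[0] < 2:
        raise InvalidInputError("video must hold at least 2 frames")
    diffs = np.diff(frames.astype(np.float64), axis=0)
    lo = min(float(diffs.min()), 0.0)
    hi = float(diffs.max())
    if hi == lo:
        scaled = np.zeros_like(diffs)
    else:
        scaled = (diffs - lo) / (hi - lo)
    return DifferenceSequence(frames=scaled, label=label)


def build_ml_features(
    lockin_x: np.ndarray,
    lockin_y: np.ndarray,
    target_length: int = 500,
    scale: str = "none",
) -> np.ndarray:
    """Fixed-length feature row from the two displacement channels.

    Each channel is resampled to target_length/2 points by uniform linear
    interpolation (endpoints preserved) and the channels are concatenated.
    ``scale="zscore"`` additionally standardizes the row to zero mean / unit
    variance, which makes the feature scale-invariant; the default ``"none"``
    keeps the physical amplitude, which carries the glucose information, and
    leaves standardization to the training pipeline (fit on training data).
    """
    x = np.asarray(lockin_x, dtype=np.float64)
    y = np.asarray(lockin_y, dtype=np.float64)
    if x.shape != y.shape or x.ndim != 1:
        raise InvalidInputError("channels must be 1D with equal lengths")
    if target_length % 2 != 0 or target_length < 2:
        raise InvalidParameterError("target_length must be a positive even number")
    half = target_length // 2

    def resample(channel: np.ndarray) -> np.ndarray:
        if channel.size == half:
            return channel.copy()
        src = np.linspace(0.0, 1.0, channel.size)
        dst = np.linspace(0.0, 1.0, half)
        return np.interp(dst, src, channel)

    row = np.concatenate([resample(x), resample(y)])
    if scale == "zscore":
        if x.std() == 0.0 or y.std() == 0.0:
            raise DegenerateInputError("constant channel cannot be z-scored")
        row = (row - row.mean()) / row.std()
    elif scale != "none":
        raise InvalidParameterError(f"unknown scale option: {scale!r}")
    return row


def stratified_split(
    labels: np.ndarray, train_fraction: float = 0.7, seed: int = 0
) -> tuple[np.ndarray, np.ndarray]:
    """Video-level stratified train/test split preserving class proportions."""
    labels = np.asarray(labels)
    idx = np.arange(labels.shape[0])
    train_idx, test_idx = train_test_split(
        idx,
        train_size=train_fraction,
        stratify=labels,
        random_state=seed,
        shuffle=True,
    )
    return np.sort(train_idx), np.sort(test_idx)


@dataclass
class SVMResults:
    """Fitted SVM with the cross-validation record of its hyperparameter search."""

    pipeline: Pipeline
    best_params: dict
    cv_accuracy: float
    fold_accuracies: np.ndarray
    search_history: pd.DataFrame
    seed: int

    def predict(self, X: np.ndarray) -> np.ndarray:
        return predict(self, X)

    def summary(self) -> str:
        p = self.best_params
        lines = [
            "Support-vector classifier (Bayesian-optimized, 5-fold stratified CV)",
            f"kernel: {p['kernel']}  C: {p['C']:.4g}"
            + (f"  gamma: {p['gamma']:.4g}" if p["kernel"] == "rbf" else ""),
            f"mean CV accuracy: {self.cv_accuracy:.4f}",
            "fold accuracies: "
            + ", ".join(f"{a:.3f}" for a in self.fold_accuracies),
            f"search evaluations: {len(self.search_history)}  seed: {self.seed}",
        ]
        return "\n".join(lines)

    def save(self, path: str | Path) -> Path:
        path = Path(path)
        with open(path, "wb") as fh:
            pickle.dump(self, fh)
        return path

    @staticmethod
    def load(path: str | Path) -> "SVMResults":
        with open(path, "rb") as fh:
            return pickle.load(fh)


class GlucoseSVM:
    """SVM glucose-level classifier on lock-in feature rows.

    Construct from a :class:`FeatureMatrix` (or raw arrays) and call
    :meth:`fit`; the returned :class:`SVMResults` carries the refit model,
    the chosen hyperparameters and the cross-validation diagnostics.
    """

    def __init__(
        self,
        features: FeatureMatrix | np.ndarray,
        labels=None,
        standardize: bool = False,
    ):
        self.standardize = bool(standardize)
        if isinstance(features, FeatureMatrix):
            self.X = features.X
            self.y = features.labels
        else:
            self.X = np.asarray(features, dtype=np.float64)
            self.y = np.asarray(labels)
        classes, counts = np.unique(self.y, return_counts=True)
        if classes.size < 2:
            raise InvalidInputError("need at least 2 classes")
        if counts.min() < 5:
            raise InvalidInputError(
                "every class needs >= 5 samples for 5-fold stratified CV"
            )
        self.classes_ = classes

    def _make_pipeline(self, kernel: str, C: float, gamma: float | None) -> Pipeline:
        # Feature rows share a physical scale (pixels), and the glucose cue
        # lives in the overall amplitude; per-column standardization would
        # whiten the signal-free dimensions up to the signal's level, so the
        # default pipeline feeds the SVC directly.
        svc = SVC(kernel=kernel, C=C, gamma=gamma if gamma is not None else "scale")
        steps = [("scale", StandardScaler())] if self.standardize else []
        return Pipeline(steps + [("svc", svc)])

    def _cv_accuracy(self, kernel: str, C: float, gamma: float | None, seed: int) -> float:
        pipe = self._make_pipeline(kernel, C, gamma)
        cv = StratifiedKFold(n_splits=5, shuffle=True, random_state=seed)
        scores = cross_val_score(pipe, self.X, self.y, cv=cv)
        return float(scores.mean())

    def fit(self, opt_budget: int = 20, seed: int = 0) -> SVMResults:
        """Bayesian hyperparameter search, then refit on all data.

        Search space: kernel ∈ {rbf, linear}; C ∈ [1e-2, 1e3] (log);
        rbf width gamma ∈ [1e-4, 1e1] (log). The objective is the mean
        5-fold stratified CV accuracy; the budget is split 2:1 between the
        rbf and linear branches. Deterministic for a fixed seed.
        """
        history: list[dict] = []

        def make_objective(kernel: str):
            def objective(x: np.ndarray) -> float:
                C = float(x[0])
                gamma = float(x[1]) if kernel == "rbf" else None
                acc = self._cv_accuracy(kernel, C, gamma, seed)
                history.append(
                    {"kernel": kernel, "C": C, "gamma": gamma, "cv_accuracy": acc}
                )
                return -acc

            return objective

        c_dim = bayesopt.Dimension(1e-2, 1e3, log=True)
        g_dim = bayesopt.Dimension(1e-4, 1e1, log=True)
        budget_rbf = max(4, int(round(opt_budget * 2 / 3)))
        budget_lin = max(3, opt_budget - budget_rbf)

        res_rbf = bayesopt.minimize(
            make_objective("rbf"), [c_dim, g_dim], n_calls=budget_rbf, seed=seed
        )
        res_lin = bayesopt.minimize(
            make_objective("linear"), [c_dim], n_calls=budget_lin, seed=seed + 1
        )

        if res_rbf.best_value <= res_lin.best_value:
            best = {
                "kernel": "rbf",
                "C": float(res_rbf.best_x[0]),
                "gamma": float(res_rbf.best_x[1]),
            }
            cv_acc = -res_rbf.best_value
        else:
            best = {"kernel": "linear", "C": float(res_lin.best_x[0]), "gamma": None}
            cv_acc = -res_lin.best_value

        pipe = self._make_pipeline(best["kernel"], best["C"], best["gamma"])

        cv = StratifiedKFold(n_splits=5, shuffle=True, random_state=seed)
        folds = cross_val_score(pipe, self.X, self.y, cv=cv)
        pipe.fit(self.X, self.y)

        return SVMResults(
            pipeline=pipe,
            best_params=best,
            cv_accuracy=cv_acc,
            fold_accuracies=np.asarray(folds),
            search_history=pd.DataFrame(history),
            seed=seed,
        )


def train_svm(
    features: FeatureMatrix, opt_budget: int = 20, seed: int = 0
) -> SVMResults:
    """Functional wrapper: ``GlucoseSVM(features).fit(opt_budget, seed)``."""
    return GlucoseSVM(features).fit(opt_budget=opt_budget, seed=seed)


def predict(model, inputs: np.ndarray) -> np.ndarray:
    """One label per input row/sequence, from the model's training label set."""
    if isinstance(model, SVMResults):
        estimator = model.pipeline
    else:
        estimator = model
    inputs = np.asarray(inputs)
    if inputs.shape[0] == 0:
        return np.empty((0,), dtype=object)
    if hasattr(estimator, "n_features_in_") and inputs.ndim == 2:
        if inputs.shape[1] != estimator.n_features_in_:
            raise InvalidInputError(
                f"input has {inputs.shape[1]} features, model expects "
                f"{estimator.n_features_in_}"
            )
    return estimator.predict(inputs)


def evaluate_classifier(
    true_labels: Sequence, predicted_labels: Sequence, class_order: Sequence
) -> ClassifierReport:
    """Confusion matrix and one-vs-rest precision / recall / F1 per class.

    Rows of the confusion matrix are true classes in ``class_order``.
    Undefined ratios (empty denominator) are reported as 0; the aggregate
    macro-F1 is the unweighted mean of the per-class F1 scores.
    """
    true_labels = np.asarray(true_labels)
    predicted_labels = np.asarray(predicted_labels)
    if true_labels.shape != predicted_labels.shape:
        raise InvalidInputError("true and predicted label lengths differ")
    class_order = list(class_order)
    index = {c: i for i, c in enumerate(class_order)}
    for lab in np.concatenate([true_labels, predicted_labels]):
        if lab not in index:
            raise InvalidInputError(f"label {lab!r} not in class_order")

    k = len(class_order)
    confusion = np.zeros((k, k), dtype=int)
    for t, p in zip(true_labels, predicted_labels):
        confusion[index[t], index[p]] += 1

    tp = np.diag(confusion).astype(float)
    fp = confusion.sum(axis=0) - tp
    fn = confusion.sum(axis=1) - tp
    with np.errstate(divide="ignore", invalid="ignore"):
        precision = np.where(tp + fp > 0, tp / (tp + fp), 0.0)
        recall = np.where(tp + fn > 0, tp / (tp + fn), 0.0)
        f1 = np.where(
            precision + recall > 0,
            2.0 * precision * recall / (precision + recall),
            0.0,
        )
    total = confusion.sum()
    accuracy = float(tp.sum() / total) if total else 0.0

    return ClassifierReport(
        confusion=confusion,
        class_order=class_order,
        accuracy=accuracy,
        per_class_precision=precision,
        per_class_recall=recall,
        per_class_f1=f1,
        macro_f1=float(f1.mean()),
        metadata={"averaging": "macro", "zero_division": 0},
    )
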