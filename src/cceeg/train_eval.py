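"""Training and evaluation battery for the C-c CNN.

Training uses Adam (learning rate 1e-4), categorical cross-entropy, batch
size 64 and a fixed epoch budget, all seed-deterministic.  Evaluation
reports accuracy, macro-averaged precision/recall/F1, a 9x9 confusion
matrix, and the micro-averaged multiclass ROC/AUC obtained by one-hot
encoding the labels and flattening label and probability matrices row-wise
into a single binary-vs-score pair.  Cross-validation is stratified
ten-fold by default, preserving the balanced class design.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
from sklearn.metrics import (
    accuracy_score,
    auc,
    confusion_matrix,
    precision_recall_fscore_support,
    roc_curve,
)
from sklearn.model_selection import StratifiedKFold

from cceeg import nn
from cceeg.ccnn_model import ArchitectureSpec, ModelHandle, build_model, forward_probabilities

__all__ = [
    "TrainConfig",
    "TrainingCurves",
    "EvalReport",
    "stratified_kfold",
    "train",
    "multiclass_roc_micro",
    "evaluate",
    "cross_validate",
]


@dataclass(frozen=True)
class TrainConfig:
    """Optimizer and cross-validation settings."""

    optimizer: str = "adam"
    learning_rate: float = 1e-4
    batch_size: int = 64
    epochs: int = 500
    loss: str = "categorical_cross_entropy"
    seed: int = 0
    k_folds: int = 10

    def __post_init__(self) -> None:
        if self.optimizer != "adam":
            raise ValueError("only the adam optimizer is supported")
        if self.loss != "categorical_cross_entropy":
            raise ValueError("only categorical cross-entropy is supported")
        if self.learning_rate < 0:
            raise ValueError("learning rate must be nonnegative")
        if self.batch_size < 1 or self.epochs < 1:
            raise ValueError("batch_size and epochs must be >= 1")
        if self.k_folds < 2:
            raise ValueError("k_folds must be >= 2")


@dataclass
class TrainingCurves:
    """Per-epoch loss and training accuracy, plus optional gradient norms."""

    loss: list[float] = field(default_factory=list)
    accuracy: list[float] = field(default_factory=list)
    grad_norms: dict[str, list[float]] = field(default_factory=dict)

    def to_csv(self, path: str | Path) -> None:
        import pandas as pd

        frame = pd.DataFrame({"epoch": np.arange(1, len(self.loss) + 1),
                              "loss": self.loss, "accuracy": self.accuracy})
        for name, series in self.grad_norms.items():
            frame[f"grad_norm_{name}"] = series
        frame.to_csv(path, index=False)


@dataclass
class EvalReport:
    """Metric battery for one evaluation (or aggregated over folds)."""

    accuracy: float
    precision: float
    recall: float
    f1: float
    auc: float
    confusion: np.ndarray
    roc_fpr: np.ndarray
    roc_tpr: np.ndarray
    n_samples: int
    averaging: str = "macro (precision/recall/F1), micro one-hot flattening (ROC/AUC)"
    fold_metrics: list[dict] = field(default_factory=list)
    accuracy_sd: float = 0.0

    def to_dict(self) -> dict:
        return {
            "accuracy": self.accuracy,
            "precision": self.precision,
            "recall": self.recall,
            "f1": self.f1,
            "auc": self.auc,
            "accuracy_sd": self.accuracy_sd,
            "n_samples": self.n_samples,
            "averaging": self.averaging,
            "confusion": self.confusion.tolist(),
            "fold_metrics": self.fold_metrics,
        }

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2))


def stratified_kfold(labels: Sequence[int], k: int, seed: int) -> list[np.ndarray]:
    """k disjoint, class-balanced test-index folds partitioning the data."""
    labels = np.asarray(labels)
    counts = np.bincount(labels)
    short = np.nonzero((counts > 0) & (counts < k))[0]
    if short.size:
        raise ValueError(
            f"class {int(short[0])} has only {int(counts[short[0]])} members "
            f"(< k = {k})"
        )
    splitter = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    return [test for _, test in splitter.split(np.zeros(labels.size), labels)]


def _one_hot(labels: np.ndarray, n_classes: int) -> np.ndarray:
    if labels.min() < 0 or labels.max() >= n_classes:
        raise ValueError(f"label outside 0-{n_classes - 1}")
    out = np.zeros((labels.size, n_classes))
    out[np.arange(labels.size), labels] = 1.0
    return out


def train(
    model: ModelHandle,
    train_epochs: np.ndarray,
    labels: Sequence[int],
    config: TrainConfig,
    grad_probe: dict[str, nn.Layer] | None = None,
) -> TrainingCurves:
    """Train in place; per-epoch loss/accuracy curves are always recorded.

    ``grad_probe`` maps names to layers whose parameter-gradient norms are
    logged once per epoch (averaged over that epoch's batches), used by the
    layer-depth experiment to probe whether appended layers learn at all.
    """
    x = np.asarray(train_epochs, dtype=np.float64)
    y = np.asarray(labels)
    onehot = _one_hot(y, model.spec.n_classes)
    rng = np.random.default_rng(config.seed)
    model.network.dropout_rng = np.random.default_rng(config.seed + 1)
    optimizer = nn.Adam(model.network.params(), lr=config.learning_rate)
    curves = TrainingCurves(grad_norms={name: [] for name in (grad_probe or {})})
    n = x.shape[0]
    for _epoch in range(config.epochs):
        order = rng.permutation(n)
        epoch_loss, epoch_correct = 0.0, 0
        probe_sums = {name: 0.0 for name in (grad_probe or {})}
        n_batches = 0
        for start in range(0, n, config.batch_size):
            idx = order[start : start + config.batch_size]
            optimizer.zero_grad()
            logits = model.network.forward_logits(x[idx], training=True)
            loss, dlogits = nn.softmax_cross_entropy(logits, onehot[idx])
            if not np.isfinite(loss):
                raise FloatingPointError(
                    f"training diverged: non-finite loss at epoch {_epoch + 1}"
                )
            model.network.backward(dlogits)
            for name, layer in (grad_probe or {}).items():
                probe_sums[name] += float(
                    np.sqrt(sum(np.sum(p.grad**2) for p in layer.params()))
                )
            optimizer.step()
            epoch_loss += loss * idx.size
            epoch_correct += int((logits.argmax(axis=1) == y[idx]).sum())
            n_batches += 1
        curves.loss.append(epoch_loss / n)
        curves.accuracy.append(epoch_correct / n)
        for name in probe_sums:
            curves.grad_norms[name].append(probe_sums[name] / n_batches)
    return curves


def multiclass_roc_micro(
    prob_matrix: np.ndarray, labels: Sequence[int]
) -> tuple[np.ndarray, np.ndarray, float]:
    """Micro-averaged multiclass ROC by one-hot flattening.

    Labels are one-hot encoded; the label and probability matrices are
    flattened row-wise into one binary-truth / score column pair, and a
    standard ROC (trapezoidal AUC) is computed on it.
    """
    probs = np.asarray(prob_matrix, dtype=np.float64)
    labels = np.asarray(labels)
    onehot = _one_hot(labels, probs.shape[1])
    fpr, tpr, _ = roc_curve(onehot.ravel(), probs.ravel())
    return fpr, tpr, float(auc(fpr, tpr))


def evaluate(model: ModelHandle, test_epochs, labels: Sequence[int]) -> EvalReport:
    """Metric battery on a test set; see module docstring for definitions."""
    labels = np.asarray(labels)
    if labels.size == 0:
        raise ValueError("empty test set")
    probs = forward_probabilities(model, test_epochs)
    return evaluate_probabilities(probs, labels, n_classes=model.spec.n_classes)


def evaluate_probabilities(
    probs: np.ndarray, labels: np.ndarray, n_classes: int = 9
) -> EvalReport:
    """Metrics from an already-computed probability matrix."""
    labels = np.asarray(labels)
    preds = probs.argmax(axis=1)
    acc = accuracy_score(labels, preds)
    prec, rec, f1, _ = precision_recall_fscore_support(
        labels, preds, average="macro", labels=np.arange(n_classes), zero_division=0
    )
    conf = confusion_matrix(labels, preds, labels=np.arange(n_classes))
    fpr, tpr, auc_micro = multiclass_roc_micro(probs, labels)
    return EvalReport(
        accuracy=float(acc),
        precision=float(prec),
        recall=float(rec),
        f1=float(f1),
        auc=auc_micro,
        confusion=conf,
        roc_fpr=fpr,
        roc_tpr=tpr,
        n_samples=int(labels.size),
    )


def cross_validate(
    spec: ArchitectureSpec,
    signals: np.ndarray,
    labels: Sequence[int],
    config: TrainConfig,
) -> EvalReport:
    """Stratified k-fold CV: fresh model per fold, aggregated report.

    The aggregate confusion matrix sums fold matrices (every sample is
    tested exactly once); scalar metrics are means over folds with the
    across-fold accuracy standard deviation reported alongside.
    """
    signals = np.asarray(signals, dtype=np.float64)
    labels = np.asarray(labels)
    folds = stratified_kfold(labels, config.k_folds, config.seed)
    all_idx = np.arange(labels.size)
    fold_reports: list[EvalReport] = []
    conf_total = np.zeros((spec.n_classes, spec.n_classes), dtype=int)
    for fold_no, test_idx in enumerate(folds):
        train_idx = np.setdiff1d(all_idx, test_idx)
        model = build_model(
            spec, signals.shape[1], signals.shape[2], seed=config.seed + fold_no
        )
        train(model, signals[train_idx], labels[train_idx],
              dataclasses.replace(config, seed=config.seed + fold_no))
        report = evaluate(model, signals[test_idx], labels[test_idx])
        fold_reports.append(report)
        conf_total += report.confusion
    accs = np.array([r.accuracy for r in fold_reports])
    probs_dummy_fpr = fold_reports[-1].roc_fpr
    probs_dummy_tpr = fold_reports[-1].roc_tpr
    return EvalReport(
        accuracy=float(accs.mean()),
        precision=float(np.mean([r.precision for r in fold_reports])),
        recall=float(np.mean([r.recall for r in fold_reports])),
        f1=float(np.mean([r.f1 for r in fold_reports])),
        auc=float(np.mean([r.auc for r in fold_reports])),
        confusion=conf_total,
        roc_fpr=probs_dummy_fpr,
        roc_tpr=probs_dummy_tpr,
        n_samples=int(labels.size),
        fold_metrics=[
            {"fold": i, "accuracy": r.accuracy, "precision": r.precision,
             "recall": r.recall, "f1": r.f1, "auc": r.auc}
            for i, r in enumerate(fold_reports)
        ],
        accuracy_sd=float(accs.std(ddof=0)),
    )
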