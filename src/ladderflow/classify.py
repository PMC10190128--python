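"""Cell-type classification.

Two classifiers, mirroring the two analysis routes of the instrument:

* a two-layer feedforward network (one hidden layer, 50 units by default)
  on the three quantified protein copy numbers per cell;
* an LSTM sequence classifier on the raw three-channel pulses, resampled to
  a fixed length, which can exploit pulse-shape information that the three
  plateau features discard.

Both use a stratified 70/15/15 train/validation/test split, early stopping
on validation accuracy, and report accuracies plus a test-set confusion
matrix with fixed class order (class 0, class 1).
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from sklearn.metrics import confusion_matrix
from sklearn.neural_network import MLPClassifier

from .nnet import LSTMClassifier

__all__ = [
    "FeatureTable",
    "SequenceDataset",
    "TrainConfig",
    "ClassifierReport",
    "SplitError",
    "split_dataset",
    "evaluate",
    "train_ffnn",
    "train_lstm",
    "hyperparameter_screen",
    "resample_sequence",
]


class SplitError(ValueError):
    """Dataset cannot be partitioned as requested."""


@dataclass
class TrainConfig:
    """Shared training configuration for both classifiers."""

    split_fractions: tuple[float, float, float] = (0.70, 0.15, 0.15)
    hidden_units_ffnn: int = 50
    lstm_hidden: int = 128
    batch_size: int = 100
    learning_rate: float = 1e-3
    max_epochs: int = 50
    patience: int = 5
    dropout: float = 0.2
    seed: int = 0

    def __post_init__(self) -> None:
        if abs(sum(self.split_fractions) - 1.0) > 1e-9:
            raise ValueError("split fractions must sum to 1")
        if min(self.split_fractions) <= 0:
            raise ValueError("split fractions must be positive")
        for v in (self.hidden_units_ffnn, self.lstm_hidden, self.batch_size,
                  self.learning_rate, self.max_epochs):
            if v <= 0:
                raise ValueError("training hyperparameters must be positive")


@dataclass
class FeatureTable:
    """Per-cell feature matrix (n, k) with integer labels from {0, 1}."""

    X: np.ndarray
    y: np.ndarray
    feature_names: tuple[str, ...] = ("copies_fitc", "copies_pe", "copies_percp")

    def __post_init__(self) -> None:
        self.X = np.atleast_2d(np.asarray(self.X, dtype=float))
        self.y = np.asarray(self.y, dtype=int)
        if len(self.X) != len(self.y):
            raise ValueError("X and y lengths differ")
        if not np.all(np.isfinite(self.X)):
            raise ValueError("features contain missing/non-finite values")

    def subset(self, idx: np.ndarray) -> "FeatureTable":
        return FeatureTable(self.X[idx], self.y[idx], self.feature_names)


@dataclass
class SequenceDataset:
    """Fixed-length 3-channel pulse matrices: X of shape (n, L, C)."""

    X: np.ndarray
    y: np.ndarray

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        self.y = np.asarray(self.y, dtype=int)
        if self.X.ndim != 3:
            raise ValueError("sequences must have shape (n, length, channels)")
        if len(self.X) != len(self.y):
            raise ValueError("X and y lengths differ")
        if not np.all(np.isfinite(self.X)):
            raise ValueError("sequences contain non-finite values")

    def subset(self, idx: np.ndarray) -> "SequenceDataset":
        return SequenceDataset(self.X[idx], self.y[idx])


@dataclass
class ClassifierReport:
    """Training outcome: accuracies, test confusion matrix, history."""

    accuracy_train: float
    accuracy_val: float
    accuracy_test: float
    accuracy_overall: float
    confusion_test: np.ndarray
    history: list[dict] = field(default_factory=list)
    config: TrainConfig | None = None
    converged: bool = True
    model: object = field(default=None, repr=False)

    def to_dict(self) -> dict:
        return {
            "accuracy_train": self.accuracy_train,
            "accuracy_val": self.accuracy_val,
            "accuracy_test": self.accuracy_test,
            "accuracy_overall": self.accuracy_overall,
            "confusion_test": np.asarray(self.confusion_test).tolist(),
            "history": self.history,
            "converged": self.converged,
        }


def resample_sequence(values: np.ndarray, length: int) -> np.ndarray:
    """Linear-interpolation resampling of a (n, C) segment to (length, C)."""
    values = np.atleast_2d(np.asarray(values, dtype=float))
    if values.shape[0] == 1 and values.shape[1] > 1 and values.ndim == 2:
        values = values.T if values.shape[0] < values.shape[1] else values
    n = values.shape[0]
    src = np.linspace(0.0, 1.0, n)
    dst = np.linspace(0.0, 1.0, length)
    return np.column_stack([np.interp(dst, src, values[:, c])
                            for c in range(values.shape[1])])


def split_dataset(labels: np.ndarray,
                  fractions: tuple[float, float, float] = (0.70, 0.15, 0.15),
                  seed: int = 0) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Stratified train/validation/test index split.

    Within each class the requested fractions are realised by a
    largest-remainder apportionment (sizes within one item of exact), with a
    seeded permutation deciding membership.  Classes with fewer than three
    members cannot populate all three partitions and raise ``SplitError``.
    """
    labels = np.asarray(labels)
    if abs(sum(fractions) - 1.0) > 1e-9:
        raise SplitError("fractions must sum to 1")
    rng = np.random.default_rng(seed)
    parts: list[list[np.ndarray]] = [[], [], []]
    for cls in np.unique(labels):
        idx = np.flatnonzero(labels == cls)
        if len(idx) < 3:
            raise SplitError(f"class {cls!r} has fewer than 3 members")
        idx = rng.permutation(idx)
        raw = np.array(fractions) * len(idx)
        sizes = np.floor(raw).astype(int)
        rem = raw - sizes
        for _ in range(len(idx) - sizes.sum()):
            j = int(np.argmax(rem))
            sizes[j] += 1
            rem[j] = -1
        cuts = np.cumsum(sizes)[:-1]
        for part, chunk in zip(parts, np.split(idx, cuts)):
            part.append(chunk)
    return tuple(np.sort(np.concatenate(p)) for p in parts)


def evaluate(predictions: np.ndarray, labels: np.ndarray
             ) -> tuple[float, np.ndarray]:
    """Accuracy and 2x2 confusion matrix with fixed class order (0, 1)."""
    predictions = np.asarray(predictions)
    labels = np.asarray(labels)
    if len(predictions) != len(labels):
        raise ValueError("predictions and labels lengths differ")
    cm = confusion_matrix(labels, predictions, labels=[0, 1])
    acc = float(np.trace(cm) / cm.sum()) if cm.sum() else 0.0
    return acc, cm


def _zscore_fit(X: np.ndarray, axis=0) -> tuple[np.ndarray, np.ndarray]:
    mean = X.mean(axis=axis, keepdims=True)
    sd = X.std(axis=axis, keepdims=True)
    sd = np.where(sd == 0, 1.0, sd)
    return mean, sd


def train_ffnn(features: FeatureTable, cfg: TrainConfig) -> ClassifierReport:
    """Train the feedforward classifier on per-cell protein features.

    One hidden ReLU layer of ``cfg.hidden_units_ffnn`` units with a softmax
    output, Adam mini-batch training, features z-scored with training-set
    statistics, early stopping (patience ``cfg.patience``) on validation
    accuracy with best-weights restore.
    """
    tr, va, te = split_dataset(features.y, cfg.split_fractions, cfg.seed)
    mean, sd = _zscore_fit(features.X[tr])
    Xz = (features.X - mean) / sd
    y = features.y

    clf = MLPClassifier(
        hidden_layer_sizes=(cfg.hidden_units_ffnn,),
        activation="relu", solver="adam",
        learning_rate_init=cfg.learning_rate,
        batch_size=min(cfg.batch_size, len(tr)),
        random_state=cfg.seed, max_iter=1, warm_start=False,
    )
    classes = np.array([0, 1])
    shuffle_rng = np.random.default_rng(cfg.seed + 1)
    history: list[dict] = []
    best_acc, best_loss, best_weights, stale = -1.0, np.inf, None, 0
    converged = False
    # an epoch is stale only when neither validation accuracy nor loss
    # improves: accuracy alone can sit at chance while the loss still falls
    for epoch in range(cfg.max_epochs):
        order = shuffle_rng.permutation(tr)
        for s in range(0, len(order), cfg.batch_size):
            idx = order[s:s + cfg.batch_size]
            with warnings.catch_warnings():
                # the final, smaller minibatch of an epoch triggers a
                # harmless batch-size clipping warning
                warnings.simplefilter("ignore", UserWarning)
                clf.partial_fit(Xz[idx], y[idx], classes=classes)
        proba = clf.predict_proba(Xz[va])
        val_acc = float(np.mean(proba.argmax(axis=1) == y[va]))
        val_loss = float(-np.mean(np.log(
            proba[np.arange(len(va)), y[va]] + 1e-300)))
        history.append({"epoch": epoch, "val_accuracy": val_acc})
        improved_acc = val_acc > best_acc + 1e-12
        if improved_acc or (val_acc >= best_acc - 1e-12
                            and val_loss < best_loss - 1e-9):
            best_weights = ([w.copy() for w in clf.coefs_],
                            [b.copy() for b in clf.intercepts_])
        if improved_acc or val_loss < best_loss - 1e-9:
            stale = 0
        else:
            stale += 1
        best_acc = max(best_acc, val_acc)
        best_loss = min(best_loss, val_loss)
        if stale >= cfg.patience:
            converged = True
            break
    if best_weights is not None:
        clf.coefs_, clf.intercepts_ = best_weights

    pred = clf.predict(Xz)
    acc_test, cm = evaluate(pred[te], y[te])
    return ClassifierReport(
        accuracy_train=float(np.mean(pred[tr] == y[tr])),
        accuracy_val=float(np.mean(pred[va] == y[va])),
        accuracy_test=acc_test,
        accuracy_overall=float(np.mean(pred == y)),
        confusion_test=cm,
        history=history,
        config=cfg,
        converged=converged or best_acc >= 0,
        model=(clf, mean, sd),
    )


def train_lstm(sequences: SequenceDataset, cfg: TrainConfig
               ) -> ClassifierReport:
    """Train the LSTM pulse classifier.

    Six named stages: sequence input -> LSTM(``cfg.lstm_hidden``) ->
    dropout -> dense -> softmax -> class output.  Sequences are z-scored
    per channel with training-set statistics; mini-batch Adam with
    ``cfg.batch_size`` / ``cfg.learning_rate``; early stopping on
    validation accuracy.
    """
    tr, va, te = split_dataset(sequences.y, cfg.split_fractions, cfg.seed)
    mean, sd = _zscore_fit(sequences.X[tr].reshape(-1, sequences.X.shape[2]))
    Xz = (sequences.X - mean[None]) / sd[None]
    y = sequences.y

    net = LSTMClassifier(
        input_dim=Xz.shape[2], hidden_units=cfg.lstm_hidden,
        learning_rate=cfg.learning_rate,
        batch_size=min(cfg.batch_size, len(tr)),
        dropout=cfg.dropout, max_epochs=cfg.max_epochs,
        patience=cfg.patience, seed=cfg.seed,
    )
    net.fit(Xz[tr], y[tr], Xz[va], y[va])

    pred = net.predict(Xz)
    acc_test, cm = evaluate(pred[te], y[te])
    return ClassifierReport(
        accuracy_train=float(np.mean(pred[tr] == y[tr])),
        accuracy_val=float(np.mean(pred[va] == y[va])),
        accuracy_test=acc_test,
        accuracy_overall=float(np.mean(pred == y)),
        confusion_test=cm,
        history=net.history_,
        config=cfg,
        model=(net, mean, sd),
    )


def hyperparameter_screen(
    sequences: SequenceDataset,
    batch_sizes=(10, 100, 1000),
    learning_rates=(1e-2, 1e-3, 1e-4),
    hidden_units=(64, 128, 256),
    base_cfg: TrainConfig | None = None,
) -> tuple[pd.DataFrame, dict[tuple, list[dict]]]:
    """Train one LSTM per grid point with a shared seed.

    Returns a comparison table (batch_size, learning_rate, hidden_units,
    accuracy_val, accuracy_test, epochs) and the per-point accuracy-vs-epoch
    traces.
    """
    cfg = base_cfg or TrainConfig()
    rows, traces = [], {}
    for bs, lr, hu in itertools.product(batch_sizes, learning_rates,
                                        hidden_units):
        point = replace(cfg, batch_size=bs, learning_rate=lr, lstm_hidden=hu)
        report = train_lstm(sequences, point)
        rows.append({
            "batch_size": bs, "learning_rate": lr, "hidden_units": hu,
            "accuracy_val": report.accuracy_val,
            "accuracy_test": report.accuracy_test,
            "epochs": len(report.history),
        })
        traces[(bs, lr, hu)] = report.history
    return pd.DataFrame(rows), traces
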