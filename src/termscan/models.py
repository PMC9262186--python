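"""The two CNN classifiers, training with early stopping, the
pretrain-then-finetune procedure, evaluation metrics and model comparison.

Both topologies share one head: convolution (30 filters, kernel 10, ReLU,
valid padding) -> max-pool (5) -> dropout (0.2) -> flatten -> dense 360
(ReLU) -> dense 30 (sigmoid) -> 1 output (sigmoid), trained with Adamax on
binary cross-entropy. The one-hot CNN convolves along the sequence (L x 4
input); the matrix CNN uses a 10 x 10 kernel and 5 x 5 pooling on the
L x L pairing matrix, all other parameters identical.

Training monitors test-set accuracy and stops when it no longer improves
(configurable patience), restoring the best-epoch weights. Pre-training
runs the same loop on inverse-folded structure data first and carries the
weights into the main training.
"""

from __future__ import annotations

import itertools
import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
from scipy.stats import norm
from sklearn.metrics import average_precision_score, precision_recall_curve

from . import _nn
from .encoders import batch_one_hot, batch_pairing_matrix
from .structure import PretrainingSet

__all__ = [
    "ModelConfig",
    "TermModel",
    "TrainingHistory",
    "EvalMetrics",
    "build_model",
    "train",
    "pretrain_finetune",
    "evaluate",
    "compare_models",
]

TOPOLOGIES = ("onehot_cnn", "matrix_cnn")


@dataclass(frozen=True)
class ModelConfig:
    topology: str = "matrix_cnn"
    input_length: int = 75
    conv_filters: int = 30
    kernel_size: int = 10
    pool_size: int = 5
    dropout_rate: float = 0.2
    dense1_units: int = 360
    dense2_units: int = 30
    optimizer: str = "adamax"
    learning_rate: float = 2e-3
    loss: str = "binary_crossentropy"
    batch_size: int = 32
    max_epochs: int = 200
    patience: int = 5

    def validate(self) -> None:
        if self.topology not in TOPOLOGIES:
            raise ValueError(f"unknown topology {self.topology!r}")
        if self.input_length < self.kernel_size:
            raise ValueError(
                f"input_length {self.input_length} < kernel_size "
                f"{self.kernel_size}"
            )
        for name in ("conv_filters", "dense1_units", "dense2_units"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


@dataclass
class TrainingHistory:
    train_acc: list[float] = field(default_factory=list)
    test_acc: list[float] = field(default_factory=list)
    best_epoch: int = 0
    stop_epoch: int = 0

    def to_rows(self) -> list[dict]:
        return [
            {"epoch": e + 1, "train_acc": ta, "test_acc": va}
            for e, (ta, va) in enumerate(zip(self.train_acc, self.test_acc))
        ]


class TermModel:
    """A built (possibly trained) classifier: maps sequences to scores in
    [0, 1] (sigmoid output)."""

    def __init__(self, config: ModelConfig, net: _nn.Sequential):
        self.config = config
        self.net = net

    def encode(self, seqs: list[str]) -> np.ndarray:
        if self.config.topology == "onehot_cnn":
            return batch_one_hot(seqs)
        return batch_pairing_matrix(seqs)

    def predict_scores(
        self, inputs: list[str] | np.ndarray, batch_size: int = 256
    ) -> np.ndarray:
        """Model output in [0, 1] per input sequence (or encoded tensor)."""
        scores = []
        n = len(inputs)
        for lo in range(0, n, batch_size):
            chunk = inputs[lo : lo + batch_size]
            x = self.encode(list(chunk)) if isinstance(chunk[0], str) else np.asarray(chunk)
            z = self.net.forward(x.astype(np.float32), training=False)
            scores.append(_nn.sigmoid(z[:, 0]))
        return np.concatenate(scores) if scores else np.empty(0)

    __call__ = predict_scores

    def count_params(self) -> int:
        return self.net.count_params()

    def save(self, path: str | Path) -> None:
        """Native .npz weight checkpoint plus a JSON config sidecar."""
        path = Path(path)
        np.savez(path.with_suffix(".npz"), *self.net.get_weights())
        with open(path.with_suffix(".json"), "w") as fh:
            json.dump(asdict(self.config), fh, indent=2)

    @classmethod
    def load(cls, path: str | Path) -> "TermModel":
        path = Path(path)
        with open(path.with_suffix(".json")) as fh:
            config = ModelConfig(**json.load(fh))
        model = build_model(config, seed=0)
        with np.load(path.with_suffix(".npz")) as npz:
            model.net.set_weights([npz[k] for k in npz.files])
        return model


def build_model(config: ModelConfig, seed: int | None = None) -> TermModel:
    """Instantiate an untrained model with Glorot-uniform initial weights."""
    config.validate()
    rng = np.random.default_rng(seed)
    L, F, K, P = (
        config.input_length,
        config.conv_filters,
        config.kernel_size,
        config.pool_size,
    )
    if config.topology == "onehot_cnn":
        conv_out = L - K + 1
        flat = (conv_out // P) * F
        layers = [
            _nn.Conv1D(4, F, K, rng, input_grad=False),
            _nn.MaxPool1D(P),
            _nn.Dropout(config.dropout_rate),
            _nn.Flatten(),
        ]
    else:
        conv_out = L - K + 1
        flat = (conv_out // P) ** 2 * F
        layers = [
            _nn.Conv2D(1, F, K, rng, input_grad=False),
            _nn.MaxPool2D(P),
            _nn.Dropout(config.dropout_rate),
            _nn.Flatten(),
        ]
    layers += [
        _nn.Dense(flat, config.dense1_units, "relu", rng),
        _nn.Dense(config.dense1_units, config.dense2_units, "sigmoid", rng),
        # final sigmoid applied in predict_scores; kept as logits for a
        # numerically stable cross-entropy gradient
        _nn.Dense(config.dense2_units, 1, "linear", rng),
    ]
    return TermModel(config, _nn.Sequential(layers))


def _as_xy(data, model: TermModel) -> tuple[np.ndarray, np.ndarray]:
    if hasattr(data, "sequences"):
        seqs, y = data.sequences(), data.labels()
    else:
        seqs, y = data
    if len(seqs) == 0:
        raise ValueError("empty dataset")
    x = seqs if isinstance(seqs, np.ndarray) else model.encode(list(seqs))
    return x.astype(np.float32), np.asarray(y, dtype=np.float32)


def train(
    model: TermModel,
    train_data,
    test_data,
    seed: int | None = None,
    epochs: int | None = None,
    patience: int | None = None,
    batch_size: int | None = None,
) -> TrainingHistory:
    """Mini-batch Adamax training with early stopping on test accuracy.

    ``train_data``/``test_data`` are (sequences, labels) pairs or
    LabeledDataset objects. Training stops once test accuracy has not
    improved for ``patience`` consecutive epochs (default from config) and
    the best-epoch weights are restored. Deterministic for a fixed seed.
    """
    cfg = model.config
    epochs = cfg.max_epochs if epochs is None else epochs
    patience = cfg.patience if patience is None else patience
    batch_size = cfg.batch_size if batch_size is None else batch_size
    rng = np.random.default_rng(seed)

    x_train, y_train = _as_xy(train_data, model)
    x_test, y_test = _as_xy(test_data, model)

    opt = _nn.Adamax(model.net.parameters(), lr=cfg.learning_rate)
    history = TrainingHistory()
    best_acc, best_weights, since_best = -1.0, model.net.get_weights(), 0
    n = x_train.shape[0]
    for epoch in range(epochs):
        order = rng.permutation(n)
        correct = 0
        for lo in range(0, n, batch_size):
            idx = order[lo : lo + batch_size]
            xb, yb = x_train[idx], y_train[idx]
            z = model.net.forward(xb, training=True, rng=rng)[:, 0]
            p = _nn.sigmoid(z)
            correct += int(np.sum((p > 0.5) == (yb > 0.5)))
            dz = ((p - yb) / len(idx)).astype(np.float32)
            model.net.backward(dz[:, None])
            opt.step()
        train_acc = correct / n
        test_scores = model.predict_scores(x_test)
        test_acc = float(np.mean((test_scores > 0.5) == (y_test > 0.5)))
        history.train_acc.append(train_acc)
        history.test_acc.append(test_acc)
        if test_acc > best_acc:
            best_acc = test_acc
            best_weights = model.net.get_weights()
            history.best_epoch = epoch + 1
            since_best = 0
        else:
            if test_acc == best_acc:
                # tie: keep the latest (most-trained) weights at the best
                # accuracy, but do not extend the patience window
                best_weights = model.net.get_weights()
                history.best_epoch = epoch + 1
            since_best += 1
            if since_best >= patience:
                break
    history.stop_epoch = len(history.train_acc)
    model.net.set_weights(best_weights)
    return history


def pretrain_finetune(
    config: ModelConfig,
    pretraining_set: PretrainingSet | None,
    train_data,
    test_data,
    seed: int | None = None,
    max_restarts: int = 2,
    **train_kwargs,
) -> tuple[TermModel, TrainingHistory | None, TrainingHistory]:
    """Inverse-folding pre-training followed by main training.

    The model first learns to separate structure-only positives from random
    sequences (early stopping on the held-out pre-training partition); the
    resulting weights initialise the main training. With
    ``pretraining_set=None`` this is identical to plain ``train``.

    The small networks occasionally diverge into the class-prior basin
    (constant output at the majority-class rate) when the main training
    starts from a confidently-wrong state; if the best test accuracy never
    clears the majority-class fraction, the main training restarts from the
    initial (pre-trained) weights with a derived seed, up to
    ``max_restarts`` times. Fully deterministic for a fixed seed.
    """
    ss = np.random.SeedSequence(seed).spawn(3 + max_restarts)
    model = build_model(config, seed=ss[0])
    pre_history = None
    if pretraining_set is not None:
        pre_seqs, _ = pretraining_set.pretrain()
        if len(pre_seqs[0]) != config.input_length:
            raise ValueError(
                f"pre-training length {len(pre_seqs[0])} != model input "
                f"length {config.input_length}"
            )
        pre_history = train(
            model,
            pretraining_set.pretrain(),
            pretraining_set.earlystop(),
            seed=ss[1],
            **train_kwargs,
        )
    init_weights = model.net.get_weights()
    _, y_train = train_data if not hasattr(train_data, "labels") else (
        None, train_data.labels()
    )
    y_train = np.asarray(y_train, dtype=float)
    majority = max(y_train.mean(), 1.0 - y_train.mean())
    for attempt in range(1 + max_restarts):
        main_history = train(
            model, train_data, test_data, seed=ss[2 + attempt], **train_kwargs
        )
        if max(main_history.test_acc) > majority + 0.05:
            break
        if attempt < max_restarts:
            model.net.set_weights(init_weights)
    return model, pre_history, main_history


@dataclass
class EvalMetrics:
    precision: float
    recall: float
    specificity: float
    f1: float
    auprc: float
    pr_curve: tuple[np.ndarray, np.ndarray]  # (recall, precision) points
    threshold: float = 0.5


def evaluate(model, validation_data, threshold: float = 0.5) -> EvalMetrics:
    """Point metrics at the decision threshold plus the PR curve and AUPRC
    (average precision) on a validation set containing both classes.

    ``model`` is a TermModel or any callable mapping sequences to scores."""
    if hasattr(validation_data, "sequences"):
        seqs, y = validation_data.sequences(), validation_data.labels()
    else:
        seqs, y = validation_data
    y = np.asarray(y, dtype=float)
    if len(y) == 0 or len(np.unique(y)) < 2:
        raise ValueError("validation set must contain both classes")
    scores = np.asarray(model(list(seqs)) if callable(model) else model, dtype=float)
    pred = scores > threshold
    tp = int(np.sum(pred & (y == 1)))
    fp = int(np.sum(pred & (y == 0)))
    fn = int(np.sum(~pred & (y == 1)))
    tn = int(np.sum(~pred & (y == 0)))
    precision = tp / (tp + fp) if tp + fp else 0.0
    recall = tp / (tp + fn) if tp + fn else 0.0
    specificity = tn / (tn + fp) if tn + fp else 0.0
    f1 = (
        2 * precision * recall / (precision + recall)
        if precision + recall
        else 0.0
    )
    prec_pts, rec_pts, _ = precision_recall_curve(y, scores)
    auprc = float(average_precision_score(y, scores))
    return EvalMetrics(
        precision, recall, specificity, f1, auprc, (rec_pts, prec_pts), threshold
    )


def _ranks_with_ties(values: np.ndarray) -> np.ndarray:
    order = np.argsort(values, kind="mergesort")
    ranks = np.empty(len(values))
    i = 0
    while i < len(values):
        j = i
        while j + 1 < len(values) and values[order[j + 1]] == values[order[i]]:
            j += 1
        ranks[order[i : j + 1]] = (i + j) / 2.0 + 1.0
        i = j + 1
    return ranks


def compare_models(
    scores_a, scores_b, exact_limit: int = 12
) -> float:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney) p-value between two score
    samples, e.g. per-replicate AUPRC values of two model variants.

    Exact permutation enumeration of the rank-sum statistic for combined
    n <= ``exact_limit``; tie-corrected normal approximation (no continuity
    correction) otherwise.
    """
    a = np.asarray(scores_a, dtype=float)
    b = np.asarray(scores_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be non-empty")
    combined = np.concatenate([a, b])
    ranks = _ranks_with_ties(combined)
    w_obs = float(ranks[: a.size].sum())
    n, na = combined.size, a.size
    if n <= exact_limit:
        sums = np.array(
            [sum(c) for c in itertools.combinations(ranks, na)]
        )
        p_le = np.mean(sums <= w_obs + 1e-9)
        p_ge = np.mean(sums >= w_obs - 1e-9)
        return float(min(1.0, 2.0 * min(p_le, p_ge)))
    mu = na * (n + 1) / 2.0
    _, counts = np.unique(combined, return_counts=True)
    tie_term = float(np.sum(counts**3 - counts))
    nb = n - na
    sigma2 = na * nb / 12.0 * ((n + 1) - tie_term / (n * (n - 1)))
    if sigma2 <= 0:
        return 1.0
    z = (w_obs - mu) / math.sqrt(sigma2)
    return float(min(1.0, 2.0 * norm.sf(abs(z))))
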