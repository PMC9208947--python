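"""Model assembly, the supervised training loop, and evaluation metrics.

The assembled network is Inception block -> improved ECA -> row reduction ->
LSTM -> fully connected softmax.  Training minimizes categorical
cross-entropy with Adam at learning rate 0.001 (the reference setting; 200
epochs for the full-scale runs).  Evaluation tallies a one-vs-rest confusion
per class:

    Accuracy  = (TP + TN) / (TP + TN + FP + FN)
    Precision = TP / (TP + FP)
    Recall    = TP / (TP + FN)
    F1        = 2 * Precision * Recall / (Precision + Recall)

Headline precision/recall/F1 are macro averages over classes (weighted
averages are also reported); the headline accuracy is the overall fraction
correct, trace(confusion)/sum(confusion).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, asdict

import numpy as np

from ._nn import Adam, Dense, cross_entropy, softmax
from .channel_attention import ImprovedECA
from .inception_block import InceptionBlock, InceptionConfig
from .lstm_head import RowReduce, TemporalHead
from .preprocessing import SplitDataset, windows_to_arrays

logger = logging.getLogger(__name__)


@dataclass
class ModelConfig:
    """All architectural and training hyperparameters."""

    inception: InceptionConfig = field(default_factory=InceptionConfig)
    gamma: float = 2.0
    b: float = 1.0
    n_override: int | None = None
    channel_reduce: str = "gather"  # "gather" | "conv1x1"
    lstm_hidden: int = 64
    lstm_input: str = "channel_mean"  # "channel_mean" | "flatten"
    num_classes: int = 12
    window_length: int = 100
    stride: int | None = None
    split_ratio: float = 0.7
    lr: float = 1e-3
    epochs: int = 200
    batch_size: int = 64
    seed: int = 0

    def __post_init__(self) -> None:
        if self.num_classes < 2:
            raise ValueError("num_classes must be >= 2")
        for name in ("lstm_hidden", "window_length", "epochs", "batch_size"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be positive")
        if self.lr <= 0:
            raise ValueError("lr must be positive")

    @classmethod
    def table_reference(cls) -> "ModelConfig":
        """The full-scale reference layout: 384-channel Inception output,
        9 retained channels via a learned 1x1 reduction, LSTM [64, 18],
        12 classes, K=100."""
        return cls(n_override=9, channel_reduce="conv1x1", num_classes=12,
                   window_length=100)

    @classmethod
    def small(cls, num_classes: int = 3, window_length: int = 32) -> "ModelConfig":
        """Reduced-width configuration for fast CPU experiments on synthetic
        recordings (48-channel Inception output, 32-unit LSTM)."""
        return cls(inception=InceptionConfig.small(), lstm_hidden=32,
                   num_classes=num_classes, window_length=window_length,
                   stride=window_length // 2, epochs=20, batch_size=16)


class Network:
    """The assembled Inception-attention-LSTM classifier (NumPy, trainable)."""

    def __init__(self, config: ModelConfig, n_axes: int) -> None:
        self.config = config
        self.n_axes = n_axes
        rng = np.random.default_rng(config.seed)
        self.inception = InceptionBlock(config.inception, rng=rng)
        channels = self.inception.out_channels
        self.eca = ImprovedECA(channels, gamma=config.gamma, b=config.b,
                               n_override=config.n_override,
                               channel_reduce=config.channel_reduce, rng=rng)
        self.reduce = RowReduce(config.lstm_input)
        lstm_in = self.reduce.input_size(self.eca.n, n_axes)
        self.head = TemporalHead(lstm_in, config.lstm_hidden, rng=rng)
        self.fc = Dense(config.lstm_hidden, config.num_classes, rng=rng, name="fc")
        self.layers = [self.inception, self.eca, self.reduce, self.head, self.fc]
        self.params = [p for layer in self.layers for p in layer.params]
        self.trained = False

    def forward(self, X: np.ndarray) -> np.ndarray:
        """(B, K, D) windows -> (B, num_classes) logits."""
        X = np.asarray(X, dtype=float)
        if X.ndim != 3:
            raise ValueError("expected a (batch, K, D) array of windows")
        if X.shape[2] != self.n_axes:
            raise ValueError(f"network built for D={self.n_axes} axes, got {X.shape[2]}")
        h = X[:, None, :, :]  # (B, 1, K, D) single-channel images
        for layer in self.layers:
            h = layer.forward(h)
        return h

    def backward(self, dlogits: np.ndarray) -> None:
        d = dlogits
        for layer in reversed(self.layers):
            d = layer.backward(d)

    def predict_proba(self, X: np.ndarray, batch_size: int = 256) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        out = [softmax(self.forward(X[i : i + batch_size]))
               for i in range(0, X.shape[0], batch_size)]
        return np.concatenate(out, axis=0)

    def predict(self, X: np.ndarray) -> np.ndarray:
        return self.predict_proba(X).argmax(axis=1)

    def parameter_census(self) -> dict[str, int]:
        """Per-layer trainable-parameter counts for the assembled model."""
        census = dict(self.inception.parameter_census())
        census["channel_attention"] = int(self.eca.kernel.size)
        if self.eca.reduce_conv is not None:
            census["feature_extraction"] = self.eca.reduce_conv.n_parameters()
        else:
            census["feature_extraction"] = 0  # index gather, no weights
        census["lstm"] = self.head.n_parameters()
        census["fc"] = self.fc.n_parameters()
        return census

    def n_parameters(self) -> int:
        return sum(p.size for p in self.params)


def build_model(config: ModelConfig, n_axes: int = 18) -> Network:
    """Assemble the network for recordings with ``n_axes`` sensor channels."""
    try:
        return Network(config, n_axes)
    except ValueError as exc:
        raise ValueError(f"incompatible model configuration: {exc}") from exc


def train(
    model: Network,
    split: SplitDataset | tuple[np.ndarray, np.ndarray],
    config: ModelConfig | None = None,
    eval_data: tuple[np.ndarray, np.ndarray] | None = None,
) -> tuple[Network, list[dict]]:
    """Mini-batch Adam training; returns the model and a per-epoch history.

    ``split`` is either a :class:`SplitDataset` (its test part is used for the
    per-epoch accuracy log) or a plain ``(X, y)`` tuple.  Deterministic for a
    fixed config seed.  Raises on a non-finite loss.
    """
    config = config or model.config
    if isinstance(split, SplitDataset):
        X_train, y_train = windows_to_arrays(split.train)
        if eval_data is None and split.test:
            eval_data = windows_to_arrays(split.test)
    else:
        X_train, y_train = split
    X_train = np.asarray(X_train, dtype=float)
    y_train = np.asarray(y_train, dtype=int)
    if X_train.shape[0] == 0:
        raise ValueError("empty training set")
    if y_train.max() >= model.config.num_classes:
        raise ValueError("label outside the configured class range")
    rng = np.random.default_rng(config.seed + 1)
    opt = Adam(model.params, lr=config.lr)
    n = X_train.shape[0]
    history: list[dict] = []
    for epoch in range(config.epochs):
        order = rng.permutation(n)
        epoch_loss = 0.0
        for start in range(0, n, config.batch_size):
            idx = order[start : start + config.batch_size]
            opt.zero_grad()
            logits = model.forward(X_train[idx])
            loss, dlogits = cross_entropy(logits, y_train[idx])
            if not np.isfinite(loss):
                raise RuntimeError(
                    f"training diverged: non-finite loss at epoch {epoch}, "
                    f"batch starting {start} (lr={config.lr})"
                )
            model.backward(dlogits)
            opt.step()
            epoch_loss += loss * len(idx)
        record = {"epoch": epoch, "loss": epoch_loss / n}
        if eval_data is not None:
            y_hat = model.predict(eval_data[0])
            record["test_acc"] = float((y_hat == eval_data[1]).mean())
        history.append(record)
        logger.info("epoch %d: loss=%.4f%s", epoch, record["loss"],
                    f" test_acc={record['test_acc']:.3f}" if "test_acc" in record else "")
    model.trained = True
    return model, history


# --- metrics ----------------------------------------------------------------

@dataclass
class EvalReport:
    """Confusion matrix plus headline and per-class metrics."""

    confusion: np.ndarray  # (A, A) counts, rows = true, cols = predicted
    accuracy: float  # overall fraction correct (trace / sum)
    precision: float  # macro average
    recall: float  # macro average
    f1: float  # macro average
    per_class: dict[int, dict[str, float]]
    weighted: dict[str, float]
    label_map: dict[int, int] = field(default_factory=dict)

    def normalized_confusion(self) -> np.ndarray:
        """Row-normalized view (per-true-class recognition rates)."""
        totals = self.confusion.sum(axis=1, keepdims=True)
        with np.errstate(invalid="ignore", divide="ignore"):
            out = self.confusion / totals
        return np.nan_to_num(out)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["confusion"] = self.confusion.tolist()
        return d


def metrics_from_counts(tp: int, fp: int, fn: int, tn: int) -> dict[str, float]:
    """Accuracy/precision/recall/F1 from a binary one-vs-rest tally."""
    total = tp + fp + fn + tn
    acc = (tp + tn) / total if total else float("nan")
    prec = tp / (tp + fp) if (tp + fp) else 0.0
    rec = tp / (tp + fn) if (tp + fn) else 0.0
    f1 = 2 * prec * rec / (prec + rec) if (prec + rec) else 0.0
    return {"accuracy": acc, "precision": prec, "recall": rec, "f1": f1}


def confusion_counts(y_true: np.ndarray, y_pred: np.ndarray, n_classes: int) -> np.ndarray:
    cm = np.zeros((n_classes, n_classes), dtype=int)
    np.add.at(cm, (np.asarray(y_true, int), np.asarray(y_pred, int)), 1)
    return cm


def eval_report(y_true: np.ndarray, y_pred: np.ndarray,
                n_classes: int | None = None,
                label_map: dict[int, int] | None = None) -> EvalReport:
    """Build an :class:`EvalReport` from true/predicted dense labels.

    A class absent from both truth and prediction has undefined one-vs-rest
    metrics; it is excluded from the macro means with a warning.
    """
    y_true = np.asarray(y_true, dtype=int)
    y_pred = np.asarray(y_pred, dtype=int)
    if y_true.shape != y_pred.shape or y_true.size == 0:
        raise ValueError("y_true and y_pred must be equal-length, non-empty")
    if n_classes is None:
        n_classes = int(max(y_true.max(), y_pred.max())) + 1
    cm = confusion_counts(y_true, y_pred, n_classes)
    total = int(cm.sum())
    per_class: dict[int, dict[str, float]] = {}
    support = []
    for c in range(n_classes):
        tp = int(cm[c, c])
        fn = int(cm[c].sum() - tp)
        fp = int(cm[:, c].sum() - tp)
        tn = total - tp - fn - fp
        if tp + fn + fp == 0:
            warnings.warn(
                f"class {c} absent from both truth and prediction; "
                "excluded from macro averages", stacklevel=2)
            continue
        m = metrics_from_counts(tp, fp, fn, tn)
        m["support"] = float(tp + fn)
        per_class[c] = m
        support.append(tp + fn)
    macro = {k: float(np.mean([m[k] for m in per_class.values()]))
             for k in ("precision", "recall", "f1")}
    sup = np.array(support, dtype=float)
    wts = sup / sup.sum() if sup.sum() else sup
    weighted = {k: float(np.sum([m[k] for m in per_class.values()] * wts))
                for k in ("precision", "recall", "f1")}
    return EvalReport(
        confusion=cm,
        accuracy=float(np.trace(cm) / total),
        precision=macro["precision"], recall=macro["recall"], f1=macro["f1"],
        per_class=per_class, weighted=weighted, label_map=label_map or {},
    )


def evaluate(model: Network, windows, label_map: dict[int, int] | None = None) -> EvalReport:
    """Evaluate a model on a list of windows or an ``(X, y)`` pair."""
    if isinstance(windows, tuple):
        X, y = windows
    else:
        X, y = windows_to_arrays(windows)
    if len(y) == 0:
        raise ValueError("no windows to evaluate")
    y_pred = model.predict(X)
    return eval_report(y, y_pred, n_classes=model.config.num_classes, label_map=label_map)
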