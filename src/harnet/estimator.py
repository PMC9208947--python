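"""Scikit-learn estimator interface to the Inception-attention-LSTM network.

:class:`InceptionLSTMClassifier` wraps model assembly and the training loop
behind the standard ``fit`` / ``predict`` / ``predict_proba`` contract, so the
classifier composes with sklearn model selection (``cross_val_score``,
``GridSearchCV``) on window tensors of shape (n_windows, K, D).

Defaults are the reduced-width configuration suitable for CPU experiments;
``InceptionLSTMClassifier.reference()`` gives the full-scale layout
(384-channel Inception output, 9 retained channels, LSTM hidden size 64).
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.utils.validation import check_is_fitted

from .inception_block import InceptionConfig
from .training import ModelConfig, Network, build_model, train


class InceptionLSTMClassifier(ClassifierMixin, BaseEstimator):
    """Inception convolution -> improved ECA channel attention -> LSTM classifier.

    Parameters mirror :class:`~harnet.training.ModelConfig`; see there for
    semantics.  ``branch1``..``branch4`` are the Inception branch widths,
    ``n_override`` fixes the number of retained attention channels (otherwise
    adaptive), ``channel_reduce`` chooses top-N gathering vs a learned 1x1
    reduction, and ``lstm_input`` chooses channel-mean vs flatten row encoding.

    Examples
    --------
    >>> from harnet.datasets import make_windows
    >>> X, y = make_windows(seed=0)
    >>> clf = InceptionLSTMClassifier(epochs=5, seed=0).fit(X, y)
    >>> clf.predict(X[:3]).shape
    (3,)
    """

    def __init__(
        self,
        branch1: tuple = (8, 8),
        branch2: tuple = (8, 16, 16),
        branch3: tuple = (8, 16, 16),
        branch4: int = 8,
        gamma: float = 2.0,
        b: float = 1.0,
        n_override: int | None = None,
        channel_reduce: str = "gather",
        lstm_hidden: int = 32,
        lstm_input: str = "channel_mean",
        lr: float = 1e-3,
        epochs: int = 20,
        batch_size: int = 16,
        seed: int = 0,
    ) -> None:
        self.branch1 = branch1
        self.branch2 = branch2
        self.branch3 = branch3
        self.branch4 = branch4
        self.gamma = gamma
        self.b = b
        self.n_override = n_override
        self.channel_reduce = channel_reduce
        self.lstm_hidden = lstm_hidden
        self.lstm_input = lstm_input
        self.lr = lr
        self.epochs = epochs
        self.batch_size = batch_size
        self.seed = seed

    @classmethod
    def reference(cls, **overrides) -> "InceptionLSTMClassifier":
        """Full-scale layout: branches 64/128/128/64 (384 channels), 9 retained
        channels via a learned 1x1 reduction, LSTM hidden size 64."""
        kwargs = dict(branch1=(64, 64), branch2=(64, 128, 128), branch3=(64, 128, 128),
                      branch4=64, n_override=9, channel_reduce="conv1x1",
                      lstm_hidden=64, batch_size=64, epochs=200)
        kwargs.update(overrides)
        return cls(**kwargs)

    def _make_config(self, n_classes: int, window_length: int) -> ModelConfig:
        return ModelConfig(
            inception=InceptionConfig(branch1=tuple(self.branch1),
                                      branch2=tuple(self.branch2),
                                      branch3=tuple(self.branch3),
                                      branch4=int(self.branch4)),
            gamma=self.gamma, b=self.b, n_override=self.n_override,
            channel_reduce=self.channel_reduce, lstm_hidden=self.lstm_hidden,
            lstm_input=self.lstm_input, num_classes=n_classes,
            window_length=window_length, lr=self.lr, epochs=self.epochs,
            batch_size=self.batch_size, seed=self.seed,
        )

    def _validate_windows(self, X: np.ndarray, expect_shape: tuple | None = None) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if X.ndim != 3:
            raise ValueError(f"X must be (n_windows, K, D), got shape {X.shape}")
        if not np.isfinite(X).all():
            raise ValueError("X contains NaN or infinite values; interpolate first")
        if expect_shape is not None and X.shape[1:] != expect_shape:
            raise ValueError(f"windows of shape {X.shape[1:]} do not match fitted shape {expect_shape}")
        return X

    def fit(self, X: np.ndarray, y: np.ndarray,
            eval_set: tuple[np.ndarray, np.ndarray] | None = None) -> "InceptionLSTMClassifier":
        """Train on windows X (n, K, D) with integer or string labels y.

        ``eval_set`` optionally supplies held-out windows whose accuracy is
        logged per epoch into ``history_``.
        """
        X = self._validate_windows(X)
        y = np.asarray(y)
        if y.shape[0] != X.shape[0]:
            raise ValueError("X and y disagree on the number of windows")
        self.classes_, y_idx = np.unique(y, return_inverse=True)
        if len(self.classes_) < 2:
            raise ValueError("need at least 2 classes")
        self.window_shape_ = X.shape[1:]
        self.config_ = self._make_config(len(self.classes_), X.shape[1])
        self.model_: Network = build_model(self.config_, n_axes=X.shape[2])
        eval_data = None
        if eval_set is not None:
            Xe = self._validate_windows(eval_set[0], self.window_shape_)
            ye = np.searchsorted(self.classes_, np.asarray(eval_set[1]))
            eval_data = (Xe, ye)
        _, self.history_ = train(self.model_, (X, y_idx), self.config_, eval_data=eval_data)
        return self

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        check_is_fitted(self, "model_")
        X = self._validate_windows(X, self.window_shape_)
        return self.model_.predict_proba(X)

    def predict(self, X: np.ndarray) -> np.ndarray:
        check_is_fitted(self, "model_")
        return self.classes_[self.predict_proba(X).argmax(axis=1)]

    def parameter_census(self) -> dict[str, int]:
        """Per-layer trainable-parameter counts of the fitted network."""
        check_is_fitted(self, "model_")
        return self.model_.parameter_census()

    def __sklearn_tags__(self):
        tags = super().__sklearn_tags__()
        tags.input_tags.two_d_array = False
        tags.target_tags.required = True
        return tags
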