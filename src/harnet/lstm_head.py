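"""Temporal feature extraction and classification.

The attention-filtered feature map A' (W time rows x H sensor-axis columns x
N channels) is read row by row: each of the W rows becomes one LSTM time
step.  A row carries H x N values; by default they are reduced to a length-H
input vector by averaging over the N retained channels (so the LSTM input
size tracks the sensor-axis width, e.g. 18 for a 3-IMU acc+gyro layout), with
a flatten alternative that keeps all H*N values.  The final hidden state
feeds a fully connected softmax classifier.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ._nn import LSTM, Layer, _sigmoid, softmax


@dataclass
class LSTMState:
    """Hidden and cell vectors after a step; h = o * tanh(c) always holds."""

    h: np.ndarray
    c: np.ndarray


@dataclass
class GateParams:
    """Weights over the concatenated [h_{t-1}, x_t] for the four gates."""

    W_f: np.ndarray
    W_i: np.ndarray
    W_c: np.ndarray
    W_o: np.ndarray
    b_f: np.ndarray
    b_i: np.ndarray
    b_c: np.ndarray
    b_o: np.ndarray

    def __post_init__(self) -> None:
        shapes = {m.shape for m in (self.W_f, self.W_i, self.W_c, self.W_o)}
        if len(shapes) != 1:
            raise ValueError("all four gate matrices must share shape hidden x (hidden + input)")

    @property
    def hidden_size(self) -> int:
        return self.W_f.shape[0]

    @property
    def input_size(self) -> int:
        return self.W_f.shape[1] - self.W_f.shape[0]

    @classmethod
    def random(cls, input_size: int, hidden_size: int,
               rng: np.random.Generator | None = None,
               forget_bias: float = 1.0) -> "GateParams":
        rng = rng or np.random.default_rng(0)
        s = np.sqrt(1.0 / (hidden_size + input_size))
        shape = (hidden_size, hidden_size + input_size)
        return cls(
            W_f=rng.uniform(-s, s, shape), W_i=rng.uniform(-s, s, shape),
            W_c=rng.uniform(-s, s, shape), W_o=rng.uniform(-s, s, shape),
            b_f=np.full(hidden_size, forget_bias), b_i=np.zeros(hidden_size),
            b_c=np.zeros(hidden_size), b_o=np.zeros(hidden_size),
        )


def lstm_cell_step(state: LSTMState, x_t: np.ndarray, params: GateParams) -> LSTMState:
    """One LSTM cell update.

    f_t = sigma(W_f [h, x] + b_f);  i_t = sigma(W_i [h, x] + b_i);
    c~_t = tanh(W_c [h, x] + b_c);  c_t = f_t * c_{t-1} + i_t * c~_t;
    o_t = sigma(W_o [h, x] + b_o);  h_t = o_t * tanh(c_t).
    """
    x_t = np.asarray(x_t, dtype=float)
    if x_t.shape[-1] != params.input_size:
        raise ValueError(f"input size {x_t.shape[-1]} does not match gates ({params.input_size})")
    z = np.concatenate([state.h, x_t], axis=-1)
    f = _sigmoid(params.W_f @ z + params.b_f)
    i = _sigmoid(params.W_i @ z + params.b_i)
    g = np.tanh(params.W_c @ z + params.b_c)
    c = f * state.c + i * g
    o = _sigmoid(params.W_o @ z + params.b_o)
    return LSTMState(h=o * np.tanh(c), c=c)


def reduce_rows(feature_map: np.ndarray, mode: str = "channel_mean") -> np.ndarray:
    """Turn a (W, H, N) map into a (W, input_size) step sequence."""
    fm = np.asarray(feature_map, dtype=float)
    if fm.ndim != 3:
        raise ValueError("expected a W x H x N feature map")
    if mode == "channel_mean":
        return fm.mean(axis=2)
    if mode == "flatten":
        return fm.reshape(fm.shape[0], -1)
    raise ValueError("lstm_input mode must be 'channel_mean' or 'flatten'")


def temporal_forward(feature_map: np.ndarray, params: GateParams,
                     lstm_input: str = "channel_mean") -> np.ndarray:
    """Read the feature map line by line through the LSTM; return final h."""
    seq = reduce_rows(feature_map, lstm_input)
    state = LSTMState(h=np.zeros(params.hidden_size), c=np.zeros(params.hidden_size))
    for t in range(seq.shape[0]):
        state = lstm_cell_step(state, seq[t], params)
    return state.h


def classify(hidden: np.ndarray, weights: np.ndarray, bias: np.ndarray) -> np.ndarray:
    """Softmax class probabilities from the final hidden state."""
    logits = np.asarray(weights) @ np.asarray(hidden) + np.asarray(bias)
    return softmax(logits)


# --- batched layers used by the assembled network ---------------------------

class RowReduce(Layer):
    """(B, N, K, D) feature maps -> (B, K, input) step sequences."""

    def __init__(self, mode: str = "channel_mean") -> None:
        super().__init__()
        if mode not in ("channel_mean", "flatten"):
            raise ValueError("lstm_input mode must be 'channel_mean' or 'flatten'")
        self.mode = mode
        self._shape: tuple | None = None

    def input_size(self, n_channels: int, n_axes: int) -> int:
        return n_axes if self.mode == "channel_mean" else n_channels * n_axes

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._shape = x.shape
        if self.mode == "channel_mean":
            return x.mean(axis=1).copy()  # (B, K, D)
        B, N, K, D = x.shape
        return x.transpose(0, 2, 1, 3).reshape(B, K, N * D)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        B, N, K, D = self._shape
        if self.mode == "channel_mean":
            return np.broadcast_to(dout[:, None], self._shape) / N
        return dout.reshape(B, K, N, D).transpose(0, 2, 1, 3)


class TemporalHead(Layer):
    """LSTM over row sequences followed by nothing: exposes the final h."""

    def __init__(self, input_size: int, hidden_size: int,
                 rng: np.random.Generator | None = None) -> None:
        super().__init__()
        self.lstm = LSTM(input_size, hidden_size, rng=rng)
        self.params = list(self.lstm.params)

    def forward(self, x: np.ndarray) -> np.ndarray:
        return self.lstm.forward(x)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        return self.lstm.backward(dout)

    def gate_params(self) -> GateParams:
        l = self.lstm
        return GateParams(
            W_f=l.W_f.value, W_i=l.W_i.value, W_c=l.W_c.value, W_o=l.W_o.value,
            b_f=l.b_f.value, b_i=l.b_i.value, b_c=l.b_c.value, b_o=l.b_o.value,
        )
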