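"""Minimal NumPy neural-network layers with hand-written backpropagation.

All layers consume and produce NCHW batches (batch, channels, time, axes) or
(batch, time, features) for the recurrent layer.  Each layer caches what its
backward pass needs during forward; ``backward`` consumes the upstream
gradient and returns the input gradient while accumulating parameter
gradients in-place.  Training is plain mini-batch Adam.

Convolutions use "same" zero padding and stride 1 throughout: the parallel
branches of the spatial extractor must agree on spatial dimensions to be
concatenated, and the recurrent head reads one time row per step.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view


class Param:
    """A trainable array with its accumulated gradient."""

    __slots__ = ("value", "grad", "name")

    def __init__(self, value: np.ndarray, name: str = "") -> None:
        self.value = np.asarray(value, dtype=float)
        self.grad = np.zeros_like(self.value)
        self.name = name

    @property
    def size(self) -> int:
        return self.value.size


class Layer:
    params: list[Param]

    def __init__(self) -> None:
        self.params = []

    def forward(self, x: np.ndarray) -> np.ndarray:  # pragma: no cover - interface
        raise NotImplementedError

    def backward(self, dout: np.ndarray) -> np.ndarray:  # pragma: no cover - interface
        raise NotImplementedError

    def n_parameters(self) -> int:
        return sum(p.size for p in self.params)


def _sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


class Conv2d(Layer):
    """2-D convolution (cross-correlation), same zero padding, stride 1.

    Output pixel: s(i,j) = act( sum_{m,n} w[m,n] * x[i+m, j+n] + b ), i.e. the
    local-receptive-field map followed by a nonlinearity; ReLU by default.
    """

    def __init__(
        self,
        in_channels: int,
        out_channels: int,
        kh: int,
        kw: int,
        bias: bool = True,
        activation: str | None = "relu",
        rng: np.random.Generator | None = None,
        name: str = "conv",
    ) -> None:
        super().__init__()
        if min(in_channels, out_channels, kh, kw) < 1:
            raise ValueError("convolution dimensions must be positive")
        if kh % 2 == 0 or kw % 2 == 0:
            raise ValueError("same-padding convolution requires odd kernel sizes")
        rng = rng or np.random.default_rng(0)
        fan_in = in_channels * kh * kw
        w = rng.normal(0.0, np.sqrt(2.0 / fan_in), size=(out_channels, in_channels, kh, kw))
        self.w = Param(w, f"{name}.w")
        self.params = [self.w]
        self.b = None
        if bias:
            self.b = Param(np.zeros(out_channels), f"{name}.b")
            self.params.append(self.b)
        self.kh, self.kw = kh, kw
        self.in_channels, self.out_channels = in_channels, out_channels
        self.activation = activation
        self.name = name
        self._cache: tuple | None = None

    @property
    def shape_spec(self) -> tuple[int, int, int, int]:
        """(out, in, kh, kw) — the layer-table convention."""
        return (self.out_channels, self.in_channels, self.kh, self.kw)

    def forward(self, x: np.ndarray) -> np.ndarray:
        B, C, H, W = x.shape
        if C != self.in_channels:
            raise ValueError(f"{self.name}: expected {self.in_channels} input channels, got {C}")
        ph, pw = self.kh // 2, self.kw // 2
        xp = np.pad(x, ((0, 0), (0, 0), (ph, ph), (pw, pw)))
        cols = sliding_window_view(xp, (self.kh, self.kw), axis=(2, 3))  # B,C,H,W,kh,kw
        cols = cols.transpose(0, 2, 3, 1, 4, 5).reshape(B, H * W, C * self.kh * self.kw)
        wm = self.w.value.reshape(self.out_channels, -1)
        pre = cols @ wm.T
        if self.b is not None:
            pre = pre + self.b.value
        pre = pre.transpose(0, 2, 1).reshape(B, self.out_channels, H, W)
        out = np.maximum(pre, 0.0) if self.activation == "relu" else pre
        self._cache = (cols, pre, x.shape)
        return out

    def backward(self, dout: np.ndarray) -> np.ndarray:
        cols, pre, x_shape = self._cache
        B, C, H, W = x_shape
        if self.activation == "relu":
            dout = dout * (pre > 0)
        dflat = dout.reshape(B, self.out_channels, H * W).transpose(0, 2, 1)  # B,HW,out
        wm = self.w.value.reshape(self.out_channels, -1)
        self.w.grad += np.einsum("bpo,bpk->ok", dflat, cols).reshape(self.w.value.shape)
        if self.b is not None:
            self.b.grad += dflat.sum(axis=(0, 1))
        dcols = dflat @ wm  # B,HW,C*kh*kw
        dcols = dcols.reshape(B, H, W, C, self.kh, self.kw).transpose(0, 3, 1, 2, 4, 5)
        ph, pw = self.kh // 2, self.kw // 2
        dxp = np.zeros((B, C, H + 2 * ph, W + 2 * pw))
        for di in range(self.kh):
            for dj in range(self.kw):
                dxp[:, :, di : di + H, dj : dj + W] += dcols[..., di, dj]
        return dxp[:, :, ph : ph + H, pw : pw + W]


class MaxPool2d(Layer):
    """Max pooling with stride 1 and same padding (spatial dims preserved)."""

    def __init__(self, kh: int = 3, kw: int = 3) -> None:
        super().__init__()
        self.kh, self.kw = kh, kw
        self._cache: tuple | None = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        B, C, H, W = x.shape
        ph, pw = self.kh // 2, self.kw // 2
        xp = np.pad(x, ((0, 0), (0, 0), (ph, ph), (pw, pw)), constant_values=-np.inf)
        win = sliding_window_view(xp, (self.kh, self.kw), axis=(2, 3))  # B,C,H,W,kh,kw
        flat = win.reshape(B, C, H, W, self.kh * self.kw)
        idx = flat.argmax(axis=-1)
        out = np.take_along_axis(flat, idx[..., None], axis=-1)[..., 0]
        self._cache = (idx, x.shape)
        return out

    def backward(self, dout: np.ndarray) -> np.ndarray:
        idx, (B, C, H, W) = self._cache
        ph, pw = self.kh // 2, self.kw // 2
        dxp = np.zeros((B, C, H + 2 * ph, W + 2 * pw))
        di, dj = np.divmod(idx, self.kw)
        ii = np.arange(H)[None, None, :, None] + di
        jj = np.arange(W)[None, None, None, :] + dj
        bb = np.arange(B)[:, None, None, None]
        cc = np.arange(C)[None, :, None, None]
        np.add.at(dxp, (bb, cc, ii, jj), dout)
        return dxp[:, :, ph : ph + H, pw : pw + W]


class Dense(Layer):
    """Affine map y = W x + b (no activation; softmax lives in the loss)."""

    def __init__(
        self,
        in_features: int,
        out_features: int,
        rng: np.random.Generator | None = None,
        name: str = "fc",
    ) -> None:
        super().__init__()
        rng = rng or np.random.default_rng(0)
        s = np.sqrt(1.0 / in_features)
        self.w = Param(rng.uniform(-s, s, size=(out_features, in_features)), f"{name}.w")
        self.b = Param(np.zeros(out_features), f"{name}.b")
        self.params = [self.w, self.b]
        self._x: np.ndarray | None = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._x = x
        return x @ self.w.value.T + self.b.value

    def backward(self, dout: np.ndarray) -> np.ndarray:
        self.w.grad += dout.T @ self._x
        self.b.grad += dout.sum(axis=0)
        return dout @ self.w.value


class LSTM(Layer):
    """Single-layer unidirectional LSTM over (batch, time, features) input.

    Gate equations (forget f, input i, candidate c~, output o over the
    concatenated [h_{t-1}, x_t]):

        f_t = sigma(W_f [h, x] + b_f)        i_t = sigma(W_i [h, x] + b_i)
        c~_t = tanh(W_c [h, x] + b_c)        c_t = f_t * c_{t-1} + i_t * c~_t
        o_t = sigma(W_o [h, x] + b_o)        h_t = o_t * tanh(c_t)

    The final hidden state h_T is the layer output.  The forget-gate bias is
    initialized to 1 so early training does not erase the cell state.
    """

    def __init__(
        self,
        input_size: int,
        hidden_size: int,
        rng: np.random.Generator | None = None,
        forget_bias: float = 1.0,
        name: str = "lstm",
    ) -> None:
        super().__init__()
        rng = rng or np.random.default_rng(0)
        s = np.sqrt(1.0 / (hidden_size + input_size))
        shape = (hidden_size, hidden_size + input_size)

        def mat(tag: str) -> Param:
            return Param(rng.uniform(-s, s, size=shape), f"{name}.W_{tag}")

        self.W_f, self.W_i, self.W_c, self.W_o = mat("f"), mat("i"), mat("c"), mat("o")
        self.b_f = Param(np.full(hidden_size, forget_bias), f"{name}.b_f")
        self.b_i = Param(np.zeros(hidden_size), f"{name}.b_i")
        self.b_c = Param(np.zeros(hidden_size), f"{name}.b_c")
        self.b_o = Param(np.zeros(hidden_size), f"{name}.b_o")
        self.params = [self.W_f, self.W_i, self.W_c, self.W_o,
                       self.b_f, self.b_i, self.b_c, self.b_o]
        self.input_size = input_size
        self.hidden_size = hidden_size
        self._cache: list | None = None

    def step(self, h: np.ndarray, c: np.ndarray, x_t: np.ndarray) -> tuple:
        """One cell update; returns (h_t, c_t, gate cache)."""
        z = np.concatenate([h, x_t], axis=-1)
        f = _sigmoid(z @ self.W_f.value.T + self.b_f.value)
        i = _sigmoid(z @ self.W_i.value.T + self.b_i.value)
        g = np.tanh(z @ self.W_c.value.T + self.b_c.value)
        c_new = f * c + i * g
        o = _sigmoid(z @ self.W_o.value.T + self.b_o.value)
        h_new = o * np.tanh(c_new)
        return h_new, c_new, (z, f, i, g, o, c, c_new)

    def forward(self, x: np.ndarray) -> np.ndarray:
        B, T, F = x.shape
        if F != self.input_size:
            raise ValueError(f"lstm: expected input size {self.input_size}, got {F}")
        h = np.zeros((B, self.hidden_size))
        c = np.zeros((B, self.hidden_size))
        cache = []
        for t in range(T):
            h, c, step_cache = self.step(h, c, x[:, t, :])
            cache.append(step_cache)
        self._cache = cache
        self._x_shape = x.shape
        return h

    def backward(self, dh: np.ndarray) -> np.ndarray:
        B, T, F = self._x_shape
        dx = np.zeros((B, T, F))
        dc = np.zeros_like(dh)
        H = self.hidden_size
        for t in reversed(range(T)):
            z, f, i, g, o, c_prev, c_new = self._cache[t]
            tanh_c = np.tanh(c_new)
            do = dh * tanh_c
            dc = dc + dh * o * (1.0 - tanh_c**2)
            df = dc * c_prev
            di = dc * g
            dg = dc * i
            dzf = df * f * (1.0 - f)
            dzi = di * i * (1.0 - i)
            dzg = dg * (1.0 - g**2)
            dzo = do * o * (1.0 - o)
            self.W_f.grad += dzf.T @ z
            self.W_i.grad += dzi.T @ z
            self.W_c.grad += dzg.T @ z
            self.W_o.grad += dzo.T @ z
            self.b_f.grad += dzf.sum(axis=0)
            self.b_i.grad += dzi.sum(axis=0)
            self.b_c.grad += dzg.sum(axis=0)
            self.b_o.grad += dzo.sum(axis=0)
            dz = (dzf @ self.W_f.value + dzi @ self.W_i.value
                  + dzg @ self.W_c.value + dzo @ self.W_o.value)
            dh = dz[:, :H]
            dx[:, t, :] = dz[:, H:]
            dc = dc * f
        return dx


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


def cross_entropy(logits: np.ndarray, y: np.ndarray) -> tuple[float, np.ndarray]:
    """Mean categorical cross-entropy and its gradient w.r.t. the logits."""
    p = softmax(logits)
    n = logits.shape[0]
    loss = -np.log(np.clip(p[np.arange(n), y], 1e-12, None)).mean()
    grad = p.copy()
    grad[np.arange(n), y] -= 1.0
    return float(loss), grad / n


class Adam:
    """Adam optimizer over a flat list of :class:`Param`."""

    def __init__(self, params: list[Param], lr: float = 1e-3,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8) -> None:
        self.params = params
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p.value) for p in params]
        self.v = [np.zeros_like(p.value) for p in params]
        self.t = 0

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad[...] = 0.0

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for p, m, v in zip(self.params, self.m, self.v):
            m[...] = b1 * m + (1 - b1) * p.grad
            v[...] = b2 * v + (1 - b2) * p.grad**2
            mhat = m / (1 - b1**self.t)
            vhat = v / (1 - b2**self.t)
            p.value -= self.lr * mhat / (np.sqrt(vhat) + self.eps)
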