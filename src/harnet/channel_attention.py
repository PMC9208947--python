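"""Efficient channel attention (ECA) with top-N channel extraction.

Original ECA weights each feature channel by a sigmoid-squashed local
interaction: the feature map is global-average-pooled to one scalar per
channel, a single shared k-tap 1-D convolution mixes each channel with its
k neighbours, and the sigmoid of the result is the channel's attention
weight omega_i in (0, 1).  The kernel size adapts to the channel count:

    k = nearest odd integer of  log2(C)/gamma + b/gamma      (gamma=2, b=1)

The improvement implemented here then ranks channels by |omega_i| in
descending order and extracts only the top N weighted channels,

    N = nearest even integer of  k + log2(C)/2,

so the recurrent head downstream sees a compact map of the most informative
channels.  Setting N = C (and undoing the ordering) recovers original ECA.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from ._nn import Conv2d, Layer, Param, _sigmoid
from ._rounding import nearest_even, nearest_odd


@dataclass
class AttentionResult:
    """All intermediates of one improved-ECA pass (channels-last layout)."""

    omega: np.ndarray  # (C,) per-channel weights, each in (0, 1)
    k: int  # adaptive 1-D kernel size
    n: int  # number of retained channels
    selected: np.ndarray  # (N,) indices of retained channels, by |omega| desc
    output: np.ndarray  # (W, H, N) weighted, extracted feature map


def eca_kernel_size(channels: int, gamma: float = 2.0, b: float = 1.0) -> int:
    """Adaptive 1-D kernel size: nearest odd integer to log2(C)/gamma + b/gamma.

    Half-way ties round down (the smaller neighbourhood); minimum 1.
    C=384 gives 5.
    """
    if channels < 2:
        raise ValueError("adaptive kernel size requires at least 2 channels")
    t = np.log2(channels) / gamma + b / gamma
    return nearest_odd(t, minimum=1)


def selection_count(channels: int, k: int) -> int:
    """Number of channels to retain: nearest even integer to k + log2(C)/2.

    Half-way ties round up; the result is clamped to [2, C].
    """
    if channels < 2:
        raise ValueError("selection requires at least 2 channels")
    if k < 1:
        raise ValueError("kernel size must be >= 1")
    t = k + np.log2(channels) / 2.0
    return int(np.clip(nearest_even(t), 2, channels))


def global_avg_pool(feature_map: np.ndarray) -> np.ndarray:
    """Per-channel spatial mean of a (W, H, C) map -> length-C vector."""
    fm = np.asarray(feature_map, dtype=float)
    if fm.ndim != 3 or fm.shape[0] < 1 or fm.shape[1] < 1:
        raise ValueError("expected a W x H x C feature map with W, H >= 1")
    return fm.mean(axis=(0, 1))


def eca_weights(pooled: np.ndarray, kernel: np.ndarray) -> np.ndarray:
    """Attention weights: shared k-tap 1-D convolution over the pooled vector,
    zero-padded at the ends, followed by the logistic sigmoid.

    omega_i = sigmoid( sum_j kernel_j * pooled_{i + j - (k-1)/2} ).
    """
    pooled = np.asarray(pooled, dtype=float)
    kernel = np.asarray(kernel, dtype=float)
    k = kernel.shape[0]
    if k % 2 == 0:
        raise ValueError("ECA kernel size must be odd")
    if k > pooled.shape[-1]:
        raise ValueError("kernel longer than the channel vector")
    p = (k - 1) // 2
    padded = np.pad(np.atleast_2d(pooled), ((0, 0), (p, p)))
    z = sliding_window_view(padded, k, axis=1) @ kernel
    # clamp away from the float-saturation endpoints so the documented
    # open-interval range 0 < omega < 1 holds for arbitrary magnitudes
    omega = np.clip(_sigmoid(z), np.finfo(float).tiny, np.nextafter(1.0, 0.0))
    return omega[0] if pooled.ndim == 1 else omega


def rank_channels(omega: np.ndarray) -> np.ndarray:
    """Channel indices sorted by |omega| descending; ties keep lower index first."""
    omega = np.asarray(omega)
    return np.argsort(-np.abs(omega), axis=-1, kind="stable")


class ImprovedECA(Layer):
    """Batched improved-ECA layer (NCHW) with backpropagation.

    ``channel_reduce`` chooses how C channels become N: ``"gather"`` extracts
    the top-N weighted channels (the attention-ranking mechanism); ``"conv1x1"``
    instead applies a learned 1x1 convolution C -> N over the weighted map
    (the parameterization whose count a layer table would report as
    N*C + N).  Selection indices are per sample and treated as constants in
    the backward pass.
    """

    def __init__(
        self,
        channels: int,
        gamma: float = 2.0,
        b: float = 1.0,
        n_override: int | None = None,
        channel_reduce: str = "gather",
        rng: np.random.Generator | None = None,
    ) -> None:
        super().__init__()
        rng = rng or np.random.default_rng(0)
        self.channels = channels
        self.k = eca_kernel_size(channels, gamma, b)
        if n_override is not None:
            if not 1 <= n_override <= channels:
                raise ValueError(f"n_override must be in [1, {channels}], got {n_override}")
            self.n = int(n_override)
        else:
            self.n = selection_count(channels, self.k)
        self.kernel = Param(rng.normal(0.0, 1.0 / np.sqrt(self.k), size=self.k), "eca.kernel")
        self.params = [self.kernel]
        if channel_reduce not in ("gather", "conv1x1"):
            raise ValueError("channel_reduce must be 'gather' or 'conv1x1'")
        self.channel_reduce = channel_reduce
        self.reduce_conv: Conv2d | None = None
        if channel_reduce == "conv1x1":
            self.reduce_conv = Conv2d(channels, self.n, 1, 1, activation=None,
                                      rng=rng, name="feature_extraction")
            self.params.extend(self.reduce_conv.params)
        self._cache: tuple | None = None
        self.last_result: AttentionResult | None = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        B, C, H, W = x.shape
        if C != self.channels:
            raise ValueError(f"ECA configured for {self.channels} channels, got {C}")
        pooled = x.mean(axis=(2, 3))  # (B, C)
        omega = eca_weights(pooled, self.kernel.value)  # (B, C)
        scaled = x * omega[:, :, None, None]
        order = np.argsort(-np.abs(omega), axis=1, kind="stable")
        selected = order[:, : self.n]  # (B, N)
        if self.channel_reduce == "gather":
            out = np.take_along_axis(scaled, selected[:, :, None, None], axis=1)
        else:
            out = self.reduce_conv.forward(scaled)
        self._cache = (x, pooled, omega, selected)
        self.last_result = AttentionResult(
            omega=omega[0].copy(), k=self.k, n=self.n, selected=selected[0].copy(),
            output=out[0].transpose(1, 2, 0).copy(),
        )
        return out

    def backward(self, dout: np.ndarray) -> np.ndarray:
        x, pooled, omega, selected = self._cache
        B, C, H, W = x.shape
        if self.channel_reduce == "gather":
            dscaled = np.zeros_like(x)
            bb = np.arange(B)[:, None]
            np.add.at(dscaled, (bb, selected), dout)
        else:
            dscaled = self.reduce_conv.backward(dout)
        dx = dscaled * omega[:, :, None, None]
        domega = (dscaled * x).sum(axis=(2, 3))
        dz = domega * omega * (1.0 - omega)
        p = (self.k - 1) // 2
        padded = np.pad(pooled, ((0, 0), (p, p)))
        win = sliding_window_view(padded, self.k, axis=1)  # (B, C, k)
        self.kernel.grad += np.einsum("bc,bck->k", dz, win)
        dpad = np.zeros((B, C + 2 * p))
        for j in range(self.k):
            dpad[:, j : j + C] += dz * self.kernel.value[j]
        dpooled = dpad[:, p : p + C]
        dx += dpooled[:, :, None, None] / (H * W)
        return dx


def improved_eca_forward(
    feature_map: np.ndarray,
    gamma: float = 2.0,
    b: float = 1.0,
    n_override: int | None = None,
    kernel: np.ndarray | None = None,
    rng: np.random.Generator | None = None,
) -> AttentionResult:
    """Run improved ECA on one (W, H, C) feature map and return all
    intermediates (weights, adaptive kernel size, selection, output map)."""
    fm = np.asarray(feature_map, dtype=float)
    if fm.ndim != 3:
        raise ValueError("expected a W x H x C feature map")
    C = fm.shape[2]
    eca = ImprovedECA(C, gamma=gamma, b=b, n_override=n_override, rng=rng)
    if kernel is not None:
        kernel = np.asarray(kernel, dtype=float)
        if kernel.shape != (eca.k,):
            raise ValueError(f"kernel must have the adaptive size ({eca.k},), got {kernel.shape}")
        eca.kernel.value = kernel
    eca.forward(fm.transpose(2, 0, 1)[None])
    return eca.last_result
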