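"""Spatial feature extraction: four parallel asymmetric-convolution branches.

A window of IMU samples is treated as a single-channel image with height =
time (K samples) and width = sensor axes (D channels of the recording).  Four
branches process it in parallel and their outputs are concatenated along the
feature-channel dimension:

* branch 1: 1x1 conv -> 1x1 conv (pointwise mixing, like a per-pixel MLP);
* branch 2: 1x1 conv -> 1x3 conv (lateral, across sensor axes) -> 3x1 conv
  (longitudinal, across adjacent time steps);
* branch 3: 1x1 conv -> 1x5 lateral -> 5x1 longitudinal (wider receptive
  field in both directions);
* branch 4: 3x3 max pooling (stride 1) -> 1x1 conv.

Every convolution uses "same" zero padding so all branches keep the input's
K x D spatial extent and can be concatenated; with the default widths the
concatenated map has 64 + 128 + 128 + 64 = 384 feature channels.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ._nn import Conv2d, Layer, MaxPool2d


@dataclass
class InceptionConfig:
    """Branch widths; defaults give the 384-channel reference architecture."""

    branch1: tuple[int, int] = (64, 64)  # two stacked 1x1 convs
    branch2: tuple[int, int, int] = (64, 128, 128)  # 1x1, 1x3, 3x1
    branch3: tuple[int, int, int] = (64, 128, 128)  # 1x1, 1x5, 5x1
    branch4: int = 64  # 1x1 after the 3x3 max-pool
    pool_size: int = 3

    @property
    def out_channels(self) -> int:
        return self.branch1[-1] + self.branch2[-1] + self.branch3[-1] + self.branch4

    @classmethod
    def small(cls) -> "InceptionConfig":
        """Reduced widths (48 output channels) for fast experiments."""
        return cls(branch1=(8, 8), branch2=(8, 16, 16), branch3=(8, 16, 16), branch4=8)


def count_parameters(shape_spec: tuple[int, int, int, int], bias: bool = True) -> int:
    """Trainable parameters of a conv/linear layer given (out, in, kh, kw)."""
    out, cin, kh, kw = shape_spec
    if min(out, cin, kh, kw) < 1:
        raise ValueError("all layer dimensions must be positive")
    return out * cin * kh * kw + (out if bias else 0)


class InceptionBlock(Layer):
    """The four-branch parallel extractor as a single layer (NCHW batches)."""

    def __init__(self, config: InceptionConfig | None = None,
                 rng: np.random.Generator | None = None) -> None:
        super().__init__()
        cfg = config or InceptionConfig()
        rng = rng or np.random.default_rng(0)
        self.config = cfg
        c1a, c1b = cfg.branch1
        c2a, c2b, c2c = cfg.branch2
        c3a, c3b, c3c = cfg.branch3
        self.b1 = [Conv2d(1, c1a, 1, 1, rng=rng, name="conv1_1"),
                   Conv2d(c1a, c1b, 1, 1, rng=rng, name="conv1_2")]
        self.b2 = [Conv2d(1, c2a, 1, 1, rng=rng, name="conv2_1"),
                   Conv2d(c2a, c2b, 1, 3, rng=rng, name="conv2_21"),
                   Conv2d(c2b, c2c, 3, 1, rng=rng, name="conv2_22")]
        self.b3 = [Conv2d(1, c3a, 1, 1, rng=rng, name="conv3_1"),
                   Conv2d(c3a, c3b, 1, 5, rng=rng, name="conv3_21"),
                   Conv2d(c3b, c3c, 5, 1, rng=rng, name="conv3_22")]
        self.pool = MaxPool2d(cfg.pool_size, cfg.pool_size)
        self.b4 = [self.pool, Conv2d(1, cfg.branch4, 1, 1, rng=rng, name="conv4")]
        self.branches = [self.b1, self.b2, self.b3, self.b4]
        for branch in self.branches:
            for layer in branch:
                self.params.extend(layer.params)
        self._splits: list[int] | None = None

    @property
    def out_channels(self) -> int:
        return self.config.out_channels

    def forward(self, x: np.ndarray) -> np.ndarray:
        if x.ndim != 4 or x.shape[1] != 1:
            raise ValueError("inception block expects a (batch, 1, K, D) window image")
        outs = []
        for branch in self.branches:
            h = x
            for layer in branch:
                h = layer.forward(h)
            outs.append(h)
        self._splits = [o.shape[1] for o in outs]
        return np.concatenate(outs, axis=1)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        dx = np.zeros((dout.shape[0], 1) + dout.shape[2:])
        start = 0
        for branch, width in zip(self.branches, self._splits):
            d = dout[:, start : start + width]
            for layer in reversed(branch):
                d = layer.backward(d)
            dx += d
            start += width
        return dx

    def parameter_census(self) -> dict[str, int]:
        """Per-layer trainable-parameter counts, keyed by layer name."""
        census: dict[str, int] = {}
        for branch in self.branches:
            for layer in branch:
                if isinstance(layer, Conv2d):
                    census[layer.name] = count_parameters(layer.shape_spec, bias=layer.b is not None)
                else:
                    census["maxpool"] = 0
        return census


# --- functional wrappers (channels-last, single feature map) ----------------

def conv2d_forward(
    image: np.ndarray,
    kernel: np.ndarray,
    bias: float | np.ndarray = 0.0,
    activation: str | None = "relu",
) -> np.ndarray:
    """Same-padded single-map convolution; channels-last (W, H, C) layout.

    A 2-D ``image`` is treated as single-channel; ``kernel`` is (kh, kw) or
    (kh, kw, C_in) or (kh, kw, C_in, C_out).
    """
    img = np.asarray(image, dtype=float)
    if img.ndim == 2:
        img = img[:, :, None]
    ker = np.asarray(kernel, dtype=float)
    if ker.ndim == 2:
        ker = ker[:, :, None, None]
    elif ker.ndim == 3:
        ker = ker[:, :, :, None]
    kh, kw, cin, cout = ker.shape
    if cin != img.shape[2]:
        raise ValueError(f"kernel expects {cin} input channels, image has {img.shape[2]}")
    layer = Conv2d(cin, cout, kh, kw, activation=activation)
    layer.w.value = ker.transpose(3, 2, 0, 1)
    layer.b.value = np.broadcast_to(np.asarray(bias, dtype=float), (cout,)).copy()
    out = layer.forward(img.transpose(2, 0, 1)[None])[0]
    out = out.transpose(1, 2, 0)
    return out[:, :, 0] if cout == 1 and np.asarray(kernel).ndim == 2 else out


def inception_forward(window: np.ndarray, config: InceptionConfig | None = None,
                      rng: np.random.Generator | None = None,
                      block: InceptionBlock | None = None) -> np.ndarray:
    """Run one K x D window through the block; returns a (K, D, C) feature map."""
    block = block or InceptionBlock(config, rng=rng)
    w = np.asarray(window, dtype=float)
    if w.ndim != 2:
        raise ValueError("window must be a K x D matrix")
    out = block.forward(w[None, None])  # (1, C, K, D)
    return out[0].transpose(1, 2, 0)
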