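"""Missing-value interpolation, fixed-window segmentation, train/test split.

The pipeline is: linearly interpolate NaN gaps channel by channel, cut the
stream into fixed-length windows of K consecutive samples (each window is one
classification instance), then shuffle-split the windows 7:3 into train and
test sets.  Windows are labeled by majority vote over their samples; a window
with no label reaching half its length is discarded.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np

from .io_formats import SensorRecording

logger = logging.getLogger(__name__)


@dataclass
class Window:
    """One K x D segment with a single class label.

    ``origin`` records (recording id, start sample index) so that train/test
    disjointness can be audited.
    """

    data: np.ndarray  # (K, D)
    label: int
    origin: tuple[int, int] = (0, 0)


@dataclass
class SplitDataset:
    train: list[Window]
    test: list[Window]
    seed: int


class InterpolationError(ValueError):
    """A NaN run cannot be bridged by interior linear interpolation."""


def interpolate_missing(recording: SensorRecording) -> SensorRecording:
    """Fill NaN gaps by linear interpolation between the nearest valid neighbors.

    Each missing value y_i at time x_i becomes
    ``y_s + (y_d - y_s)/(x_d - x_s) * (x_i - x_s)`` where (x_s, y_s) and
    (x_d, y_d) are the closest valid samples to the left and right on the same
    channel.  There is no extrapolation rule: a gap touching the first or last
    sample of a channel, or a fully missing channel, is an error.

    Idempotent: a complete recording passes through unchanged.
    """
    x = recording.timestamps
    samples = recording.samples.copy()
    for j in range(samples.shape[1]):
        y = samples[:, j]
        missing = np.isnan(y)
        if not missing.any():
            continue
        if missing.all():
            raise InterpolationError(f"channel {j} ({recording.channel_meta[j].name}) is fully missing")
        if missing[0] or missing[-1]:
            raise InterpolationError(
                f"channel {j} ({recording.channel_meta[j].name}): missing run touches the "
                "recording boundary; no extrapolation rule is defined"
            )
        valid = ~missing
        samples[missing, j] = np.interp(x[missing], x[valid], y[valid])
    return replace(recording, samples=samples)


def segment_windows(
    recording: SensorRecording,
    window_length: int,
    stride: int | None = None,
    recording_id: int = 0,
) -> list[Window]:
    """Cut a complete recording into fixed-length windows.

    Windows start at 0, stride, 2*stride, ...; the trailing partial window is
    discarded, giving ``floor((T - K)/stride) + 1`` candidates.  A window's
    label is the majority label of its samples; candidates where no label
    reaches at least half the window (or where the top count is tied) are
    discarded.  Default stride is K (non-overlapping).
    """
    K = int(window_length)
    stride = K if stride is None else int(stride)
    if K < 1 or stride < 1:
        raise ValueError("window_length and stride must be >= 1")
    if np.isnan(recording.samples).any():
        raise ValueError("recording contains missing values; interpolate first")
    T = recording.n_samples
    if T < K:
        logger.warning("recording of length %d shorter than window %d: no windows", T, K)
        return []
    windows: list[Window] = []
    n_discarded = 0
    for start in range(0, T - K + 1, stride):
        block = recording.samples[start : start + K]
        seg_labels = recording.labels[start : start + K]
        values, counts = np.unique(seg_labels, return_counts=True)
        top = counts.max()
        if top * 2 < K or (counts == top).sum() > 1:
            n_discarded += 1
            continue
        label = int(values[np.argmax(counts)])
        windows.append(Window(data=block.copy(), label=label, origin=(recording_id, start)))
    if n_discarded:
        logger.info("segment_windows: discarded %d mixed-label windows", n_discarded)
    return windows


def split_train_test(windows: list[Window], ratio: float = 0.7, seed: int = 0) -> SplitDataset:
    """Seeded uniform shuffle, then split at ``round(ratio * n)``.

    Deterministic for a fixed seed; both parts are guaranteed non-empty.
    """
    n = len(windows)
    if n < 2:
        raise ValueError(f"need at least 2 windows to split, got {n}")
    rng = np.random.default_rng(seed)
    order = rng.permutation(n)
    n_train = int(round(ratio * n))
    n_train = min(max(n_train, 1), n - 1)
    train = [windows[i] for i in order[:n_train]]
    test = [windows[i] for i in order[n_train:]]
    return SplitDataset(train=train, test=test, seed=seed)


def windows_to_arrays(windows: list[Window]) -> tuple[np.ndarray, np.ndarray]:
    """Stack windows into (n, K, D) data and (n,) label arrays."""
    X = np.stack([w.data for w in windows])
    y = np.array([w.label for w in windows], dtype=int)
    return X, y


def standardize_channels(X: np.ndarray, eps: float = 1e-8) -> np.ndarray:
    """Optional per-channel z-scoring across all windows (off by default in
    the pipeline: the network consumes raw sensor units)."""
    mu = X.mean(axis=(0, 1), keepdims=True)
    sd = X.std(axis=(0, 1), keepdims=True)
    return (X - mu) / (sd + eps)
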