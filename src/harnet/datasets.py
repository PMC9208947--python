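"""Convenience dataset builders on top of the synthetic generator."""

from __future__ import annotations

import numpy as np

from .preprocessing import interpolate_missing, segment_windows, split_train_test, windows_to_arrays
from .synthetic_data import inject_missing, preset_recording


def make_windows(
    preset: str = "selfbuilt-like",
    window_length: int = 32,
    stride: int | None = None,
    seconds_per_class: float = 40.0,
    n_classes: int = 3,
    missing_fraction: float = 0.0,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Generate a preset recording and window it: returns (X, y) arrays."""
    rec = preset_recording(preset, seed=seed, seconds_per_class=seconds_per_class,
                           n_classes=n_classes)
    if missing_fraction:
        rec = interpolate_missing(inject_missing(rec, missing_fraction, seed=seed + 1))
    windows = segment_windows(rec, window_length, stride)
    return windows_to_arrays(windows)


def make_split(
    preset: str = "selfbuilt-like",
    window_length: int = 32,
    stride: int | None = None,
    seconds_per_class: float = 40.0,
    n_classes: int = 3,
    ratio: float = 0.7,
    seed: int = 0,
):
    """Windowed preset recording split 7:3; returns a SplitDataset."""
    rec = preset_recording(preset, seed=seed, seconds_per_class=seconds_per_class,
                           n_classes=n_classes)
    windows = segment_windows(rec, window_length, stride)
    return split_train_test(windows, ratio=ratio, seed=seed)
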