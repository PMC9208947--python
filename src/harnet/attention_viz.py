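"""Attention saliency export: which sensor axes, at which moments, the
network attends to.

The channel-attention weights live in feature-channel space; to map them back
to named sensor axes, the saliency proxy used here is the absolute value of
the attention-weighted, channel-extracted feature map aggregated over the
retained channels.  The result is a (time x axis) map normalized to [0, 1]
and a per-axis vector (its mean over time), labeled from the recording's
channel metadata.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io_formats import ChannelMeta
from .training import Network


@dataclass
class SaliencyResult:
    map: np.ndarray  # (W, H) in [0, 1]: time x sensor axis
    per_axis: np.ndarray  # (H,) mean-over-time saliency
    axis_labels: list[str]
    trained: bool  # False flags a randomly initialized model


def axis_saliency(model: Network, window: np.ndarray,
                  channel_meta: list[ChannelMeta] | None = None) -> SaliencyResult:
    """Saliency of one K x D window under a (trained) model.

    An untrained model is allowed — the result is then flagged via
    ``trained=False`` in the output metadata.
    """
    w = np.asarray(window, dtype=float)
    if w.ndim != 2:
        raise ValueError("window must be a K x D matrix")
    if w.shape[1] != model.n_axes:
        raise ValueError(f"model expects D={model.n_axes} axes, window has {w.shape[1]}")
    features = model.inception.forward(w[None, None])
    filtered = model.eca.forward(features)  # (1, N, K, D)
    sal = np.abs(filtered[0]).sum(axis=0)  # (K, D)
    peak = sal.max()
    if peak > 0:
        sal = sal / peak
    labels = ([m.name for m in channel_meta] if channel_meta
              else [f"axis{j}" for j in range(w.shape[1])])
    if len(labels) != w.shape[1]:
        raise ValueError("channel_meta length does not match window width")
    return SaliencyResult(map=sal, per_axis=sal.mean(axis=0), axis_labels=labels,
                          trained=model.trained)


def saliency_to_rows(result: SaliencyResult,
                     channel_meta: list[ChannelMeta] | None = None) -> list[dict]:
    """Long-format rows: time_index, site, modality, axis, saliency."""
    rows = []
    K, D = result.map.shape
    for t in range(K):
        for j in range(D):
            meta = channel_meta[j] if channel_meta else None
            rows.append({
                "time_index": t,
                "site": meta.site if meta else result.axis_labels[j],
                "modality": meta.modality if meta else "",
                "axis": meta.axis if meta else "",
                "saliency": float(result.map[t, j]),
            })
    return rows


def save_saliency_csv(result: SaliencyResult, path,
                      channel_meta: list[ChannelMeta] | None = None) -> None:
    import pandas as pd

    df = pd.DataFrame(saliency_to_rows(result, channel_meta))
    df.attrs["trained"] = result.trained
    df.to_csv(path, index=False)


def save_saliency_png(result: SaliencyResult, path) -> None:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 4))
    im = ax.imshow(result.map.T, aspect="auto", origin="lower", cmap="viridis",
                   vmin=0.0, vmax=1.0)
    ax.set_yticks(range(len(result.axis_labels)))
    ax.set_yticklabels(result.axis_labels, fontsize=6)
    ax.set_xlabel("time step")
    title = "attention saliency"
    if not result.trained:
        title += " (untrained model)"
    ax.set_title(title)
    fig.colorbar(im, ax=ax)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
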