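"""Display helpers: class maps, PCC slices, RIA profiles, difference maps.

Visualization only — nothing here is part of any feature contract.  The
log/moving-average RIA display mirrors how such profiles are usually shown
to highlight class differences away from the direct beam.
"""

from __future__ import annotations

import numpy as np

from .labeling import CLASS_NAMES

CLASS_COLORS = ("#888888", "#4477cc", "#cc4444", "#eecc44")  # carbon, a-ice, c-ice, mixed


def _mpl():
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    return plt


def plot_class_map(labels: np.ndarray, ax=None, title: str | None = None):
    """Colour-coded scan-grid class map with a legend."""
    plt = _mpl()
    from matplotlib.colors import ListedColormap
    from matplotlib.patches import Patch

    if ax is None:
        _, ax = plt.subplots(figsize=(4, 4))
    ax.imshow(labels, cmap=ListedColormap(CLASS_COLORS), vmin=-0.5, vmax=3.5, interpolation="nearest")
    ax.legend(handles=[Patch(color=c, label=n) for c, n in zip(CLASS_COLORS, CLASS_NAMES)],
              loc="upper left", bbox_to_anchor=(1.02, 1), fontsize=8)
    if title:
        ax.set_title(title)
    return ax


def plot_pcc_slice(slice_map: np.ndarray, scan_position=None, ax=None):
    plt = _mpl()
    if ax is None:
        _, ax = plt.subplots(figsize=(4, 4))
    im = ax.imshow(slice_map, cmap="viridis", vmin=-1, vmax=1)
    if scan_position is not None:
        ax.plot(scan_position[1], scan_position[0], "r+", markersize=10)
    plt.colorbar(im, ax=ax, shrink=0.8)
    return ax


def plot_ria(profiles: np.ndarray, labels=None, smooth: int = 13, log: bool = True, ax=None):
    """RIA curves, optionally as a moving average of log(RIA) to suppress
    noise and compress the direct beam's dynamic range."""
    plt = _mpl()
    if ax is None:
        _, ax = plt.subplots(figsize=(6, 3.5))
    profiles = np.atleast_2d(profiles)
    for i, p in enumerate(profiles):
        v = np.log(np.clip(p, 1e-3, None)) if log else p.astype(float)
        if smooth > 1:
            kernel = np.ones(smooth) / smooth
            v = np.convolve(np.nan_to_num(v), kernel, mode="same")
        color = CLASS_COLORS[int(labels[i])] if labels is not None else None
        ax.plot(v, color=color, lw=0.8, alpha=0.7)
    ax.set_xlabel("radial bin (px)")
    ax.set_ylabel("log RIA" if log else "RIA")
    return ax


def plot_difference_map(actual: np.ndarray, predicted: np.ndarray, ax=None):
    """Predicted class map with misclassified points flagged in red."""
    plt = _mpl()
    ax = plot_class_map(predicted, ax=ax, title="prediction (errors in red)")
    diff = actual != predicted
    ys, xs = np.nonzero(diff)
    ax.scatter(xs, ys, marker="x", s=18, c="red", linewidths=1)
    return ax
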