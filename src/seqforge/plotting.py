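"""Optional matplotlib helpers for latent-space figures."""

from __future__ import annotations

import numpy as np

#: channel colors: A green, C blue, G yellow, T red
BASE_COLORS = {"A": "#2ca02c", "C": "#1f77b4", "G": "#ffd700", "T": "#d62728"}


def interpolation_heatmap(path, max_positions: int = 8, ax=None):
    """Render an InterpolationPath as a color grid.

    Rows are interpolation steps (top to bottom), columns are the first
    ``max_positions`` sequence positions (left to right); each cell mixes
    the four base channel colors by the soft one-hot weights.
    """
    import matplotlib.pyplot as plt
    from matplotlib.colors import to_rgb

    decoded = path.decoded[:, :max_positions, :]
    # one-hot column order is (A, T, C, G)
    palette = np.array([to_rgb(BASE_COLORS[b]) for b in "ATCG"])
    img = decoded @ palette
    if ax is None:
        _, ax = plt.subplots(figsize=(max_positions * 0.6, path.n_steps * 0.4))
    ax.imshow(img, aspect="auto", interpolation="nearest")
    ax.set_xlabel("position")
    ax.set_ylabel("interpolation step")
    return ax


def complementation_heatmap(report, ax=None):
    """4×4 base→base transition matrix of a ComplementationReport."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(4, 4))
    im = ax.imshow(report.matrix, vmin=0, vmax=1, cmap="viridis")
    bases = list("ATCG")
    ax.set_xticks(range(4), bases)
    ax.set_yticks(range(4), bases)
    ax.set_xlabel("base decoded from -z")
    ax.set_ylabel("base decoded from z")
    for i in range(4):
        for j in range(4):
            ax.text(j, i, f"{report.matrix[i, j]:.2f}", ha="center", va="center", color="w")
    plt.colorbar(im, ax=ax)
    return ax
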