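"""Optional matplotlib rendering of heatmaps, profiles and tracks."""

from __future__ import annotations

from pathlib import Path

import numpy as np

from .profiles import SignalMatrix


def plot_heatmap(matrix: SignalMatrix, path: str | Path,
                 vmax_quantile: float = 0.98) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    vmax = np.quantile(matrix.values, vmax_quantile) or 1.0
    fig, ax = plt.subplots(figsize=(4, 6))
    ax.imshow(matrix.values, aspect="auto", cmap="Blues", vmin=0, vmax=vmax,
              extent=[matrix.bin_edges[0], matrix.bin_edges[-1],
                      len(matrix.row_names), 0], interpolation="nearest")
    ax.set_xlabel(f"offset from {matrix.anchor.replace('_', ' ')} (bp)")
    ax.set_ylabel("regions (increasing Q, bottom to top)")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_profile(offsets: np.ndarray, profiles: dict[str, np.ndarray],
                 path: str | Path) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 3))
    for label, vec in profiles.items():
        ax.plot(offsets, vec, label=label)
    ax.set_xlabel("offset (bp)")
    ax.set_ylabel("mean RPM per bin")
    ax.legend(frameon=False)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
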