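"""Figure helpers: connectivity heatmaps and simulation panels."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np

from .columns import PB_LABELS
from .simulate import SimulationResult


def connectivity_heatmap(matrix: np.ndarray, title: str = "",
                         clip: float = 0.7, path: str | Path | None = None):
    """Heatmap of a 32x32 connectivity matrix, values clipped at +-clip.

    Clipping only affects display; quadrants are CL1a/CL2 blocks indexed
    by PB column.
    """
    fig, ax = plt.subplots(figsize=(6.5, 6))
    im = ax.imshow(np.clip(matrix, -clip, clip), cmap="RdYlBu_r",
                   vmin=-clip, vmax=clip)
    labels = [f"CL1a {lab}" for lab in PB_LABELS] + [f"CL2 {lab}" for lab in PB_LABELS]
    ax.set_xticks(range(0, 32, 4))
    ax.set_xticklabels(labels[::4], rotation=90, fontsize=6)
    ax.set_yticks(range(0, 32, 4))
    ax.set_yticklabels(labels[::4], fontsize=6)
    ax.axhline(15.5, color="k", lw=0.8)
    ax.axvline(15.5, color="k", lw=0.8)
    ax.set_xlabel("presynaptic")
    ax.set_ylabel("postsynaptic")
    if title:
        ax.set_title(title)
    fig.colorbar(im, ax=ax, label="synaptic weight")
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=150)
        plt.close(fig)
        return None
    return fig


def simulation_panels(result: SimulationResult, path: str | Path | None = None):
    """Three-panel view: commands, CL1a rates, CL2 rates over time."""
    t = np.arange(result.states.shape[0])
    cmd_level = {"forward": 0, "turn_left": 1, "turn_right": -1}
    levels = [0] + [cmd_level[c] for c in result.commands]
    fig, axes = plt.subplots(3, 1, figsize=(8, 7), sharex=True,
                             gridspec_kw={"height_ratios": [1, 3, 3]})
    axes[0].step(t, levels, where="post", color="k")
    axes[0].set_yticks([-1, 0, 1])
    axes[0].set_yticklabels(["right turn", "forward", "left turn"])
    axes[0].set_ylabel("command")
    for ax, pop, sl in ((axes[1], "CL1a", slice(0, 16)),
                        (axes[2], "CL2", slice(16, 32))):
        im = ax.imshow(result.states[:, sl].T, aspect="auto", origin="upper",
                       cmap="viridis", extent=(0, t[-1], 15.5, -0.5))
        ax.set_yticks(range(0, 16, 2))
        ax.set_yticklabels(PB_LABELS[::2])
        ax.set_ylabel(f"{pop} (PB column)")
        fig.colorbar(im, ax=ax, label="activity")
    axes[2].set_xlabel("time step")
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=150)
        plt.close(fig)
        return None
    return fig
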