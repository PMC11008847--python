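"""Minimal rendering of trajectory frames (cross-section snapshots)."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np


def render_frame(cell_nodes: list[np.ndarray], substrate_x: tuple[float, float],
                 ax=None, title: str | None = None):
    """Draw filled cell outlines above the substrate line."""
    if ax is None:
        _, ax = plt.subplots(figsize=(8, 3))
    for nodes in cell_nodes:
        ax.fill(nodes[:, 0], nodes[:, 1], alpha=0.5, edgecolor="k",
                linewidth=0.8)
    ax.plot(substrate_x, [0, 0], color="0.3", linewidth=2)
    ax.set_aspect("equal")
    ax.set_xlabel("x (model units)")
    ax.set_ylabel("z (model units)")
    if title:
        ax.set_title(title)
    return ax


def render_trajectory(frames, substrate_x: tuple[float, float],
                      out_dir: str | Path, stride: int = 1) -> list[Path]:
    """Write one PNG per (strided) frame; returns the written paths."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = []
    for f in frames[::stride]:
        fig, ax = plt.subplots(figsize=(8, 3))
        render_frame(f.cells, substrate_x, ax=ax,
                     title=f"t = {f.time_h:.2f} h (step {f.step})")
        p = out_dir / f"frame_{f.step:07d}.png"
        fig.savefig(p, dpi=110, bbox_inches="tight")
        plt.close(fig)
        paths.append(p)
    return paths
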