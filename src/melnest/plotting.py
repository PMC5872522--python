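"""Simple static projections of a simulation state (no 3D rendering).

``plot_surface`` draws the top-down view of the uppermost occupied layers
(melanoma over skin); ``plot_cross_section`` a vertical slice, with the
seeding surface at the top of the axes.
"""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from .engine import SimulationState
from .lattice import MELANOMA

_SKIN_COLOR = "#2ca02c"
_MEL_COLOR = "#1f3bb3"


def plot_surface(state: SimulationState, depth_layers: int = 3, ax=None):
    """Top-down projection of the top ``depth_layers`` lattice layers."""
    if ax is None:
        _, ax = plt.subplots(figsize=(5, 5))
    pos, spc = state.positions, state.species
    sel = pos[:, 2] < depth_layers
    for code, color, zorder in ((0, _SKIN_COLOR, 1), (MELANOMA, _MEL_COLOR, 2)):
        m = sel & (spc == code)
        ax.scatter(pos[m, 0], pos[m, 1], s=4, c=color, zorder=zorder, lw=0)
    ax.set_xlim(-0.5, state.geometry.nx - 0.5)
    ax.set_ylim(-0.5, state.geometry.ny - 0.5)
    ax.set_aspect("equal")
    ax.set_xlabel("i")
    ax.set_ylabel("j")
    ax.set_title(f"surface view, t = {state.t:.1f} h")
    return ax


def plot_cross_section(state: SimulationState, j: int | None = None, ax=None):
    """Vertical (i, k) slice at lateral index ``j`` (default: mid-domain)."""
    if ax is None:
        _, ax = plt.subplots(figsize=(5, 3))
    j = state.geometry.ny // 2 if j is None else j
    pos, spc = state.positions, state.species
    sel = pos[:, 1] == j
    for code, color in ((0, _SKIN_COLOR), (MELANOMA, _MEL_COLOR)):
        m = sel & (spc == code)
        ax.scatter(pos[m, 0], pos[m, 2], s=6, c=color, lw=0)
    ax.set_xlim(-0.5, state.geometry.nx - 0.5)
    ax.set_ylim(state.geometry.nz - 0.5, -0.5)  # depth increases downward
    ax.set_xlabel("i")
    ax.set_ylabel("k (depth)")
    ax.set_title(f"cross-section j = {j}, t = {state.t:.1f} h")
    return ax


def save_projections(state: SimulationState, prefix) -> list[str]:
    paths = []
    for name, fn in (("surface", plot_surface), ("section", plot_cross_section)):
        fig, ax = plt.subplots(figsize=(5, 4))
        fn(state, ax=ax)
        out = f"{prefix}_{name}.png"
        fig.savefig(out, dpi=150, bbox_inches="tight")
        plt.close(fig)
        paths.append(out)
    return paths
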