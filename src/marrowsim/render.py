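"""Snapshot export: raw array dumps plus raster renders of the lattice."""

from __future__ import annotations

from pathlib import Path

import matplotlib
import numpy as np

matplotlib.use("Agg")
import matplotlib.pyplot as plt
from matplotlib.colors import ListedColormap

from .grid import CellKind, WorldState

#: agent-kind color legend (marrow, preosteoclast, osteoclast, MSC,
#: preosteoblast, osteoblast, lining, myeloma)
KIND_COLORS = {
    CellKind.EMPTY: "#f7f2ec",
    CellKind.PRE_OC: "#c490d1",
    CellKind.OC: "#7b2d8b",
    CellKind.MSC: "#2e86c1",
    CellKind.PRE_OB: "#7fd4c1",
    CellKind.OB: "#1e8449",
    CellKind.LINING: "#b7950b",
    CellKind.MM: "#c0392b",
}


def dump_snapshot(state: WorldState, path: str | Path) -> None:
    """Raw array dump (compressed npz) of the full lattice state."""
    np.savez_compressed(
        Path(path),
        kind=state.kind, density=state.bone.density,
        resorbed_depth=state.bone.resorbed_depth,
        rankl=state.fields.R_L, bdf=state.fields.T_beta,
        clone=state.clone, resistant=state.resistant, t=state.t)


def render_snapshot(state: WorldState, path: str | Path, show_fields: bool = False) -> None:
    """PNG render: bone density in grayscale with agents colored by kind."""
    ncol = 3 if show_fields else 1
    fig, axes = plt.subplots(1, ncol, figsize=(4.2 * ncol, 4.2))
    axes = np.atleast_1d(axes)
    ax = axes[0]
    ax.imshow(1.0 - state.bone.density.T, cmap="gray", vmin=0, vmax=1,
              origin="lower", interpolation="nearest")
    cmap = ListedColormap([KIND_COLORS[k] for k in CellKind])
    overlay = np.ma.masked_where(state.kind == 0, state.kind)
    ax.imshow(overlay.T, cmap=cmap, vmin=0, vmax=len(CellKind) - 1,
              origin="lower", interpolation="nearest")
    ax.set_title(f"t = {state.t:.0f} d")
    ax.set_xticks([]), ax.set_yticks([])
    if show_fields:
        for axf, (name, u) in zip(axes[1:], [("RANKL", state.fields.R_L),
                                             ("BDF", state.fields.T_beta)]):
            im = axf.imshow(u.T, origin="lower", cmap="viridis", interpolation="nearest")
            axf.set_title(name)
            axf.set_xticks([]), axf.set_yticks([])
            fig.colorbar(im, ax=axf, fraction=0.046)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
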