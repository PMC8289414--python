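"""Small rendering helpers: false-colour coordination maps and network plots."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from .coordination import BLOCK, CoordinationMap
from .network import FunctionalNetwork, HUB_CUT_DEFAULT


def region_label_image(cmap: CoordinationMap, shape_zyx: tuple[int, int, int]) -> np.ndarray:
    """Paint block region labels back into a (Z, Y, X) volume (0 = uncoordinated)."""
    out = np.zeros(shape_zyx, dtype=np.uint16)
    blocks = cmap.blocks
    for i in range(blocks.n_blocks):
        lab = cmap.region_label[i]
        if lab == 0:
            continue
        z = int(blocks.z[i])
        r0 = int(blocks.tile_index[i, 0]) * BLOCK
        c0 = int(blocks.tile_index[i, 1]) * BLOCK
        out[z, r0 : r0 + BLOCK, c0 : c0 + BLOCK] = lab
    return out


def plot_coordination_map(
    cmap: CoordinationMap, shape_zyx: tuple[int, int, int], path: str | Path, z: int = 0
) -> Path:
    """False-colour map of the top coordinated regions in one z-plane."""
    labels = region_label_image(cmap, shape_zyx)[z]
    fig, ax = plt.subplots(figsize=(4, 4))
    shown = np.where(labels > 0, labels, np.nan)
    ax.imshow(shown, cmap="tab10", interpolation="nearest")
    ax.set_title(f"coordinated regions (z={z})")
    ax.axis("off")
    fig.savefig(path, dpi=120, bbox_inches="tight")
    plt.close(fig)
    return Path(path)


def plot_network(
    net: FunctionalNetwork,
    centroids: np.ndarray,
    path: str | Path,
    hub_cut: float = HUB_CUT_DEFAULT,
) -> Path:
    """Node-link rendering with hub cells highlighted in red."""
    share = net.degrees / (net.n_cells - 1)
    hubs = share >= hub_cut
    fig, ax = plt.subplots(figsize=(4, 4))
    ii, jj = np.nonzero(np.triu(net.A, k=1))
    for i, j in zip(ii, jj):
        ax.plot(
            [centroids[i, 1], centroids[j, 1]],
            [centroids[i, 0], centroids[j, 0]],
            color="0.7",
            lw=0.5,
            zorder=1,
        )
    ax.scatter(
        centroids[~hubs, 1], centroids[~hubs, 0], s=15, c="steelblue", zorder=2
    )
    ax.scatter(centroids[hubs, 1], centroids[hubs, 0], s=25, c="crimson", zorder=3)
    ax.invert_yaxis()
    ax.set_aspect("equal")
    ax.axis("off")
    fig.savefig(path, dpi=120, bbox_inches="tight")
    plt.close(fig)
    return Path(path)
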