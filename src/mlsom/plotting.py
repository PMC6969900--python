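"""Static figures: portraits, summary maps, and perturbation heatmaps."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np

from .datamodel import PerturbationMatrix

_DIRECTION_VALUE = {"down": -1, "none": 0, "up": 1}


def plot_portrait(portrait: np.ndarray, path: str | Path,
                  title: str = "") -> None:
    """Blue (under) -> white -> red (over) portrait, symmetric around 0."""
    vmax = float(np.abs(portrait).max()) or 1.0
    fig, ax = plt.subplots(figsize=(4, 4))
    im = ax.imshow(portrait, cmap="bwr", vmin=-vmax, vmax=vmax,
                   origin="upper", interpolation="nearest")
    ax.set_title(title)
    ax.set_xticks([])
    ax.set_yticks([])
    fig.colorbar(im, ax=ax, shrink=0.8, label="metagene Δe")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_summary_map(mask: np.ndarray, spots, path: str | Path) -> None:
    """Summary overexpression map with spot labels at their centroids."""
    fig, ax = plt.subplots(figsize=(4.5, 4.5))
    ax.imshow(mask.astype(int), cmap="Reds", origin="upper",
              interpolation="nearest", vmin=0, vmax=1.5)
    for spot in spots:
        rr = np.mean([u[0] for u in spot.units])
        cc = np.mean([u[1] for u in spot.units])
        ax.text(cc, rr, spot.label, ha="center", va="center", fontsize=9)
    ax.set_title("overexpression summary map")
    ax.set_xticks([])
    ax.set_yticks([])
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_perturbation_heatmap(pm: PerturbationMatrix, path: str | Path) -> None:
    """Spots x contrasts heatmap of joint directions (blue down, red up)."""
    frame = pm.direction_frame()
    data = frame.replace(_DIRECTION_VALUE).to_numpy(dtype=float)
    fig, ax = plt.subplots(
        figsize=(1.0 + 0.6 * len(frame.columns), 1.0 + 0.35 * len(frame)))
    ax.imshow(data, cmap="bwr", vmin=-1, vmax=1, aspect="auto",
              interpolation="nearest")
    ax.set_xticks(range(len(frame.columns)))
    ax.set_xticklabels(frame.columns, rotation=60, ha="right", fontsize=7)
    ax.set_yticks(range(len(frame)))
    ax.set_yticklabels(frame.index, fontsize=8)
    ax.set_title("spot perturbation")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
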