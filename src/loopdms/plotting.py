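"""Minimal matplotlib renderers for heatmaps and relative-entropy logos.

These are deliberately plain: the numeric TSV outputs are the primary
artifacts and remain consumable by dedicated visualization tools.
"""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np

from loopdms.motifs import HeatmapMatrix, ICMatrix

# chemistry-based letter colors: hydrophobic black, polar green, basic
# blue, acidic red, neutral purple
_AA_COLORS = {
    **{aa: "black" for aa in "AVLIMFWPG"},
    **{aa: "green" for aa in "STYCNQ"},
    **{aa: "blue" for aa in "KRH"},
    **{aa: "red" for aa in "DE"},
}


def plot_heatmap(hm: HeatmapMatrix, path: str | Path, cmap: str = "RdBu_r") -> None:
    values = hm.values
    fig, ax = plt.subplots(
        figsize=(max(4, 0.5 * values.shape[1] + 2), max(4, 0.22 * values.shape[0]))
    )
    data = np.ma.masked_invalid(values.to_numpy(dtype=float))
    vmax = np.nanmax(np.abs(values.to_numpy(dtype=float))) or 1.0
    im = ax.imshow(data, aspect="auto", cmap=cmap, vmin=-vmax, vmax=vmax)
    ax.set_xticks(range(values.shape[1]))
    ax.set_xticklabels([str(c) for c in values.columns])
    if values.index.nlevels == 1:
        ax.set_yticks(range(values.shape[0]))
        ax.set_yticklabels(values.index)
    ax.set_xlabel("position / site")
    ax.set_title(f"{hm.mutation_type}: GFP- enrichment (WT-normalized)")
    fig.colorbar(im, ax=ax, label="log2 fold change")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_logo(ic: ICMatrix, path: str | Path) -> None:
    """Stacked-letter logo of per-position KL information content.

    Positive per-letter contributions are stacked tallest-on-top per
    position; letters are text glyphs scaled by their IC value.
    """
    values = ic.values
    fig, ax = plt.subplots(figsize=(0.8 * len(values) + 1, 3))
    for i, (_, row) in enumerate(values.iterrows()):
        positive = row[row > 0].sort_values()
        y = 0.0
        for aa, h in positive.items():
            ax.text(
                i + 1, y + h / 2, aa,
                ha="center", va="center",
                fontsize=9 + 20 * min(h, 2.0),
                color=_AA_COLORS.get(aa, "purple"),
                fontweight="bold",
            )
            y += h
    sums = ic.position_sums
    ax.set_xlim(0.4, len(values) + 0.6)
    ax.set_ylim(0, max(float(sums.max()), 0.1) * 1.1)
    ax.set_xticks(range(1, len(values) + 1))
    ax.set_xlabel("position")
    ax.set_ylabel("IC (bits)")
    ax.set_title(f"{ic.category} relative-entropy logo")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
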