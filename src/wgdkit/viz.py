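"""Cosmetic SVG renderers for the tabular outputs (dot plots, dupStack
lanes, Ks histograms with fitted mixture densities). Rendering is a thin
matplotlib layer over the tables; all science lives upstream."""

from __future__ import annotations

from pathlib import Path
from typing import Sequence

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from .mixtures import MixtureFit


def render_dotplot(table: pd.DataFrame, path: str | Path) -> Path:
    fig, ax = plt.subplots(figsize=(5, 5))
    bg = table[~table["is_anchor"]]
    fg = table[table["is_anchor"]]
    ax.scatter(bg["x"], bg["y"], s=4, c="lightgrey")
    if len(fg):
        sc = ax.scatter(fg["x"], fg["y"], s=6, c=fg["ks"], cmap="viridis")
        fig.colorbar(sc, ax=ax, label="Ks")
    ax.set_xlabel("gene index (genome A)")
    ax.set_ylabel("gene index (genome B)")
    fig.savefig(path, format="svg")
    plt.close(fig)
    return Path(path)


def render_dupstack(table: pd.DataFrame, path: str | Path) -> Path:
    fig, ax = plt.subplots(figsize=(7, 3))
    chroms = sorted(table["chromosome"].unique())
    offset = {c: i for i, c in enumerate(chroms)}
    colors = {"intra": "tab:green", "inter": "tab:blue"}
    for row in table.itertuples(index=False):
        y = offset[row.chromosome] + 0.15 * (row.lane + 1)
        ax.plot([row.start, row.end], [y, y], lw=4,
                color=colors.get(row.scope, "grey"), solid_capstyle="butt")
    ax.set_yticks(list(offset.values()), chroms)
    ax.set_xlabel("position (bp)")
    fig.savefig(path, format="svg")
    plt.close(fig)
    return Path(path)


def render_ks_distribution(values: Sequence[float], path: str | Path,
                           weights: Sequence[float] | None = None,
                           fit: MixtureFit | None = None,
                           max_ks: float = 5.0) -> Path:
    fig, ax = plt.subplots(figsize=(6, 4))
    v = np.asarray(values, dtype=float)
    keep = (v > 0) & (v <= max_ks)
    w = None if weights is None else np.asarray(weights, dtype=float)[keep]
    ax.hist(v[keep], bins=50, weights=w, density=True, color="lightsteelblue")
    if fit is not None:
        grid = np.linspace(1e-3, max_ks, 400)
        total = np.zeros_like(grid)
        if fit.exp_rate is not None and fit.exp_weight > 0:
            bg = fit.exp_weight * fit.exp_rate * np.exp(-fit.exp_rate * grid)
            ax.plot(grid, bg, "--", color="grey", label="background")
            total += bg
        for i, c in enumerate(fit.components):
            dens = (c.weight / (grid * c.log_sd * np.sqrt(2 * np.pi)) *
                    np.exp(-0.5 * ((np.log(grid) - c.log_mean) / c.log_sd) ** 2))
            ax.plot(grid, dens, label=f"component {i} (peak {c.peak:.2f})")
            total += dens
        ax.plot(grid, total, color="black", lw=1)
        ax.legend(fontsize=8)
    ax.set_xlabel("Ks")
    ax.set_ylabel("density")
    fig.savefig(path, format="svg")
    plt.close(fig)
    return Path(path)
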