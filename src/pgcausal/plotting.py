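"""Optional plot helpers (heatmaps, preservation barplots, z-score trends).

Every plotted quantity is first available as TSV from the pipeline; these
helpers only render standard image files and are never needed for analysis.
"""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import pandas as pd


def save_heatmap(
    matrix: pd.DataFrame,
    path: str | Path,
    title: str = "",
    cmap: str = "RdBu_r",
    vmin: float | None = None,
    vmax: float | None = None,
) -> Path:
    fig, ax = plt.subplots(figsize=(6, 5))
    im = ax.imshow(matrix.to_numpy(), cmap=cmap, vmin=vmin, vmax=vmax)
    ax.set_xticks(range(matrix.shape[1]), [str(c) for c in matrix.columns], rotation=90)
    ax.set_yticks(range(matrix.shape[0]), [str(i) for i in matrix.index])
    ax.set_title(title)
    fig.colorbar(im, ax=ax)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return Path(path)


def save_barplot(values: pd.Series, path: str | Path, title: str = "") -> Path:
    fig, ax = plt.subplots(figsize=(6, 3))
    ax.bar([str(i) for i in values.index], values.to_numpy())
    ax.set_title(title)
    ax.set_ylim(0, 1)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return Path(path)


def save_trend_lines(
    profiles: pd.DataFrame, path: str | Path, title: str = ""
) -> Path:
    """One line per module across the (ordered, never re-sorted) samples."""
    fig, ax = plt.subplots(figsize=(6, 3.5))
    for module, row in profiles.iterrows():
        ax.plot(row.index, row.to_numpy(), marker="o", label=f"M{module}")
    ax.axhline(0.0, color="grey", lw=0.5)
    ax.set_ylabel("mean z-score")
    ax.set_title(title)
    ax.legend(fontsize=7)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return Path(path)
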