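"""Optional diagnostic figures for a pipeline run."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt

from .inference import pairwise_distances_km
import numpy as np


def save_default_plots(result, out_dir: str | Path) -> list[Path]:
    """Group boxplots per metric and a distance-decay scatter for Jaccard."""
    from .pipeline import METRICS

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    s = result.summaries
    written: list[Path] = []
    if not len(s):
        return written
    flags = s["alien_flag"].astype(bool)

    fig, axes = plt.subplots(2, 3, figsize=(11, 6), constrained_layout=True)
    for ax, metric in zip(axes.ravel(), METRICS):
        groups = [s.loc[flags, metric].dropna(), s.loc[~flags, metric].dropna()]
        ax.boxplot(groups, tick_labels=["with aliens", "no aliens"])
        ax.set_title(metric, fontsize=9)
    path = out / "group_boxplots.png"
    fig.savefig(path, dpi=120)
    plt.close(fig)
    written.append(path)

    coords = s[["latitude", "longitude"]].to_numpy(dtype=float)
    d = pairwise_distances_km(coords)
    iu, ju = np.triu_indices(len(s), k=1)
    x = s["median_beta_jac"].to_numpy(dtype=float)
    fig, ax = plt.subplots(figsize=(5, 4), constrained_layout=True)
    ax.scatter(d[iu, ju], np.abs(x[iu] - x[ju]), s=8, alpha=0.5)
    ax.set_xlabel("great-circle distance (km)")
    ax.set_ylabel("|median Jaccard difference|")
    ax.set_title("Distance decay: median Jaccard dissimilarity")
    path = out / "distance_decay_beta_jac.png"
    fig.savefig(path, dpi=120)
    plt.close(fig)
    written.append(path)
    return written
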