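"""Optional matplotlib figures: box/violin of angle series, polar orientation
histograms, and the PCA score scatter.  All functions save to a file and
never open a window."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

__all__ = ["plot_angle_distributions", "plot_polar_histogram", "plot_pca_scores"]


def plot_angle_distributions(series_by_sample: dict, path: str | Path) -> None:
    """Violin plot with superposed boxplot of each sample's angle series."""
    ids = list(series_by_sample)
    data = [np.asarray(getattr(s, "angles", s), float) for s in series_by_sample.values()]
    fig, ax = plt.subplots(figsize=(1.5 * len(ids) + 2, 4))
    ax.violinplot(data, showextrema=False)
    ax.boxplot(data, whis=1.5, medianprops={"color": "red"},
               flierprops={"marker": "s", "markeredgecolor": "red"})
    ax.set_xticks(range(1, len(ids) + 1), ids)
    ax.set_ylabel("orientation angle (deg)")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_polar_histogram(centers_deg: np.ndarray, masses: np.ndarray,
                         path: str | Path) -> None:
    """Polar plot of an orientation histogram (mirrored over 180 deg)."""
    fig = plt.figure(figsize=(4, 4))
    ax = fig.add_subplot(projection="polar")
    th = np.deg2rad(np.concatenate([centers_deg, centers_deg + 180.0]))
    m = np.concatenate([masses, masses])
    width = np.deg2rad(centers_deg[1] - centers_deg[0]) if len(centers_deg) > 1 else 0.1
    ax.bar(th, m, width=width, alpha=0.8)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_pca_scores(report: dict, path: str | Path) -> None:
    """Scatter of the first-two-component scores, one color per sample."""
    sc = report["scores_2d"]
    labels = np.asarray(report["labels"], dtype=object)
    fig, ax = plt.subplots(figsize=(5, 4))
    for s in report["samples"]:
        pts = sc[labels == s]
        ax.scatter(pts[:, 0], pts[:, 1], label=str(s))
    ax.set_xlabel("PC1")
    ax.set_ylabel("PC2")
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
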