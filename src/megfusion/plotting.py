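"""Figure-style outputs (timecourse plots) for pipeline artifacts."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from .fusion import CommonalityTimecourse
from .stats import ClusterTestResult


def plot_decoding(
    time_ms: np.ndarray,
    subject_accuracies: np.ndarray,
    cluster_result: ClusterTestResult,
    path,
    chance: float = 50.0,
) -> None:
    """Group-mean decoding accuracy with the significant-cluster bar."""
    fig, ax = plt.subplots(figsize=(6, 3.2))
    mean = subject_accuracies.mean(axis=0)
    sem = subject_accuracies.std(axis=0, ddof=1) / np.sqrt(subject_accuracies.shape[0])
    ax.fill_between(time_ms, mean - sem, mean + sem, alpha=0.3)
    ax.plot(time_ms, mean, lw=1.5)
    ax.axhline(chance, ls="--", c="gray", lw=0.8)
    ax.axvline(0, ls=":", c="gray", lw=0.8)
    if cluster_result.mask.any():
        y = mean.min() - 1.0
        ax.plot(time_ms[cluster_result.mask], np.full(cluster_result.mask.sum(), y),
                "s", ms=2, c="C3")
    ax.set(xlabel="time (ms)", ylabel="balanced accuracy (%)")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_commonality(
    commonalities: dict[str, CommonalityTimecourse], path, max_rois: int = 4
) -> None:
    """Commonality timecourses (both models) for up to ``max_rois`` ROIs."""
    rois = list(commonalities)[:max_rois]
    fig, axes = plt.subplots(
        1, len(rois), figsize=(3.2 * len(rois), 3.0), sharey=True, squeeze=False
    )
    for ax, roi in zip(axes[0], rois):
        ct = commonalities[roi]
        ax.fill_between(ct.time_ms, 0, ct.r2_fusion, color="0.85",
                        label="MEG-fMRI R²")
        for name, c in ct.c.items():
            ax.plot(ct.time_ms, c, lw=1.2, label=name)
        ax.axvline(0, ls=":", c="gray", lw=0.8)
        ax.set(title=roi, xlabel="time (ms)")
    axes[0][0].set_ylabel("commonality coefficient")
    axes[0][0].legend(fontsize=7)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
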