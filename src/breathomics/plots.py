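"""Figures: combined projection scatter, ROC curves, RMSECV curve."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from .rf import ROCResult

CLASS_COLORS = {
    "healthy": "#2a9d2a",
    "transient_wheeze": "#1f77b4",
    "asthma": "#d62728",
}


def plot_projection(scores: pd.DataFrame, path: str) -> None:
    """3-D scatter of the combined (score1, score2, score3) space."""
    fig = plt.figure(figsize=(6, 5))
    ax = fig.add_subplot(111, projection="3d")
    for cls, sub in scores.groupby("class"):
        ax.scatter(
            sub["score1"], sub["score2"], sub["score3"],
            s=14, alpha=0.7, label=cls.replace("_", " "),
            color=CLASS_COLORS.get(cls, "gray"),
        )
    ax.set_xlabel("score 1")
    ax.set_ylabel("score 2")
    ax.set_zlabel("score 3")
    ax.legend(loc="upper left", fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_roc(roc: ROCResult, path: str, title: str = "ROC") -> None:
    fig, ax = plt.subplots(figsize=(4.5, 4.5))
    ax.plot(1 - roc.specificity, roc.sensitivity, drawstyle="steps-post")
    ax.plot([0, 1], [0, 1], ls="--", c="gray", lw=0.8)
    i = int(np.argmin(np.abs(roc.thresholds - roc.optimal_cutoff)))
    ax.plot(1 - roc.specificity[i], roc.sensitivity[i], "o", c="k", ms=6,
            mfc="none")
    ax.set_xlabel("1 - specificity")
    ax.set_ylabel("sensitivity")
    ax.set_title(f"{title} (AUC {100 * roc.auc:.1f}%, cutoff "
                 f"{roc.optimal_cutoff:.2f})", fontsize=10)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_rmsecv(rmsecv: np.ndarray, n_lv: int, path: str) -> None:
    fig, ax = plt.subplots(figsize=(4.5, 3.2))
    lv = np.arange(1, len(rmsecv) + 1)
    ax.plot(lv, rmsecv, "o-", ms=4)
    ax.axvline(n_lv, ls="--", c="gray", lw=0.8)
    ax.set_xlabel("latent variables")
    ax.set_ylabel("RMSECV")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
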