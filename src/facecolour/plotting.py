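"""Optional figures: model-comparison bars, N-sweep curves, dendrogram."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402
import numpy as np  # noqa: E402
from scipy.cluster import hierarchy  # noqa: E402


def plot_model_comparison(report, path=None):
    """Train vs test RMSE bars per algorithm."""
    t = report.table
    x = np.arange(len(t))
    fig, ax = plt.subplots(figsize=(7, 3.5))
    ax.bar(x - 0.2, t["train_rmse"], width=0.4, label="training")
    if "test_rmse" in t:
        ax.bar(x + 0.2, t["test_rmse"], width=0.4, label="testing")
    ax.set_xticks(x, t.index)
    ax.set_ylabel("RMSE (rating units)")
    ax.legend(frameon=False)
    fig.tight_layout()
    if path:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig


def plot_varcount(result, path=None):
    """Mean ± SD RMSE against the number of predictors N, per method."""
    fig, ax = plt.subplots(figsize=(6, 4))
    for method in result.summary["method"].unique():
        sub = result.summary[result.summary["method"] == method]
        for which, ls in (("train", "--"), ("test", "-")):
            ax.errorbar(
                sub["N"], sub[f"mean_{which}_rmse"], yerr=sub[f"sd_{which}_rmse"],
                ls=ls, marker="o", capsize=2, label=f"{method} {which}",
            )
    ax.set_xlabel("number of predictors N")
    ax.set_ylabel("RMSE (rating units)")
    ax.legend(frameon=False, fontsize=8)
    fig.tight_layout()
    if path:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig


def plot_dendrogram(clusters, path=None):
    """Predictor dendrogram from :func:`facecolour.cluster_predictors`."""
    fig, ax = plt.subplots(figsize=(6, 4))
    hierarchy.dendrogram(
        clusters["linkage"], labels=clusters["leaf_order"], ax=ax,
        leaf_rotation=90, no_plot=False, count_sort=False,
    )
    ax.set_ylabel("1 - |r| (average linkage)")
    fig.tight_layout()
    if path:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig
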