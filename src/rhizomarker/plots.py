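"""Basic diagnostic figures: volcano, score scatter, dendrogram."""

from __future__ import annotations

import numpy as np

from .multivariate import Dendrogram


def volcano_plot(results, p_thresh: float = 0.01, fc_thresh: float = 2.0, ax=None):
    import matplotlib.pyplot as plt

    ax = ax or plt.gca()
    x = results["log2fc"]
    y = -np.log10(results["p"].clip(lower=np.finfo(float).tiny))
    cut = np.log2(fc_thresh)
    up = (results["p"] < p_thresh) & (x > cut)
    dn = (results["p"] < p_thresh) & (x < -cut)
    rest = ~(up | dn)
    ax.scatter(x[rest], y[rest], s=4, c="0.7")
    ax.scatter(x[up], y[up], s=6, c="tab:green", label="rhizosphere-enriched")
    ax.scatter(x[dn], y[dn], s=6, c="tab:red", label="soil-enriched")
    ax.axhline(-np.log10(p_thresh), ls="--", lw=0.8, c="k")
    for v in (-cut, cut):
        ax.axvline(v, ls="--", lw=0.8, c="k")
    ax.set_xlabel("log2 fold change (plant / control)")
    ax.set_ylabel("-log10 P (Welch)")
    ax.legend(frameon=False, fontsize=8)
    return ax


def score_plot(scores, labels, ax=None):
    import matplotlib.pyplot as plt

    ax = ax or plt.gca()
    labels = np.asarray(labels)
    for level in np.unique(labels):
        m = labels == level
        ax.scatter(scores[m, 0], scores[m, 1], label=str(level))
    ax.set_xlabel("component 1")
    ax.set_ylabel("component 2")
    ax.legend(frameon=False, fontsize=8)
    return ax


def dendrogram_plot(dend: Dendrogram, ax=None):
    import matplotlib.pyplot as plt
    from scipy.cluster.hierarchy import dendrogram as scipy_dendrogram

    ax = ax or plt.gca()
    scipy_dendrogram(dend.linkage_matrix, labels=dend.labels, ax=ax,
                     leaf_rotation=90)
    ax.set_ylabel("1 - Pearson r (average linkage)")
    return ax
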