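"""PCA, PLS-DA with cross-validated Q², and Pearson-correlation clustering.

These are the global views of the processed feature matrices: unsupervised
3D PCA and hierarchical clustering of sample profiles, and a supervised
two-class PLS-DA whose fit (R²Y) and leave-one-out predictability (Q²)
summarize how well soil type explains the metabolome.

PLS-DA is NIPALS PLS1 against a centered 0/1 class indicator with
R² = 1 - RSS/TSS and Q² = 1 - PRESS/TSS; cross-validation refits everything
per fold, including the centering. Leave-one-out is the default, matching
the small per-dataset sample counts (5 + 3).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import linkage
from scipy.spatial.distance import squareform

from .errors import ValidationError


@dataclass
class PcaModel:
    scores: np.ndarray  # samples x components
    loadings: np.ndarray  # features x components
    explained_pct: np.ndarray  # per retained component


@dataclass
class PlsdaModel:
    n_components: int
    r2: float
    q2: float
    scores: np.ndarray  # samples x components
    coef: np.ndarray  # regression vector on centered X


@dataclass
class Dendrogram:
    linkage_matrix: np.ndarray  # scipy format
    labels: list[str]

    @property
    def heights(self) -> np.ndarray:
        return self.linkage_matrix[:, 2]


def _as_matrix(matrix) -> tuple[np.ndarray, list[str]]:
    if isinstance(matrix, pd.DataFrame):
        return matrix.to_numpy(dtype=float), [str(i) for i in matrix.index]
    m = np.asarray(matrix, dtype=float)
    return m, [str(i) for i in range(m.shape[0])]


def pca(matrix, n_components: int = 3) -> PcaModel:
    """PCA of a samples x features matrix via SVD of the centered data.

    Sign convention: each loading vector's largest-magnitude entry is
    positive, so outputs are comparable across runs.
    """
    x, _ = _as_matrix(matrix)
    n, p = x.shape
    if n < 2:
        raise ValidationError("PCA needs at least 2 samples")
    if np.isnan(x).any():
        raise ValidationError("PCA input must not contain missing values")
    max_comp = min(n - 1, p)
    if n_components > max_comp:
        raise ValidationError(f"n_components {n_components} > max {max_comp}")
    xc = x - x.mean(axis=0)
    u, s, vt = np.linalg.svd(xc, full_matrices=False)
    total_var = (s**2).sum()
    k = n_components
    loadings = vt[:k].T
    scores = u[:, :k] * s[:k]
    # deterministic signs
    for j in range(k):
        i_max = np.argmax(np.abs(loadings[:, j]))
        if loadings[i_max, j] < 0:
            loadings[:, j] *= -1
            scores[:, j] *= -1
    explained = 100.0 * s[:k] ** 2 / total_var if total_var > 0 else np.zeros(k)
    return PcaModel(scores=scores, loadings=loadings, explained_pct=explained)


def _pls1_train(x: np.ndarray, y: np.ndarray, n_components: int):
    """NIPALS PLS1. Returns (x_mean, y_mean, B, T) for centered-x regression."""
    x_mean = x.mean(axis=0)
    y_mean = y.mean()
    xr = x - x_mean
    yr = y - y_mean
    n, p = x.shape
    W = np.zeros((p, n_components))
    P = np.zeros((p, n_components))
    C = np.zeros(n_components)
    T = np.zeros((n, n_components))
    for a in range(n_components):
        w = xr.T @ yr
        norm = np.linalg.norm(w)
        if norm == 0:
            break
        w /= norm
        t = xr @ w
        tt = t @ t
        if tt == 0:
            break
        p_a = xr.T @ t / tt
        c_a = (yr @ t) / tt
        xr = xr - np.outer(t, p_a)
        yr = yr - c_a * t
        W[:, a], P[:, a], C[a], T[:, a] = w, p_a, c_a, t
    B = W @ np.linalg.pinv(P.T @ W) @ C
    return x_mean, y_mean, B, T


def plsda(
    matrix,
    labels,
    n_components: int = 2,
    cv: str = "loo",
    seed: int | None = None,
    n_folds: int = 7,
) -> PlsdaModel:
    """Two-class PLS-DA on a samples x features matrix.

    ``labels`` is a two-level factor; the positive class is the
    lexicographically larger level. Q² uses leave-one-out by default; the
    seeded k-fold alternative (``cv="kfold"``) stratifies nothing and is
    provided for larger designs.
    """
    x, _ = _as_matrix(matrix)
    labels = np.asarray(labels)
    levels = sorted(set(labels.tolist()))
    if len(levels) != 2:
        raise ValidationError(f"PLS-DA needs exactly 2 classes, got {levels}")
    y = (labels == levels[1]).astype(float)
    if (y == 1).sum() < 2 or (y == 0).sum() < 2:
        raise ValidationError("each class needs at least 2 samples")
    n = x.shape[0]
    if n_components >= n:
        raise ValidationError(f"n_components {n_components} must be < n samples {n}")

    x_mean, y_mean, B, T = _pls1_train(x, y, n_components)
    y_hat = (x - x_mean) @ B + y_mean
    tss = float(((y - y.mean()) ** 2).sum())
    rss = float(((y - y_hat) ** 2).sum())
    r2 = 1.0 - rss / tss

    if cv == "loo":
        folds = [[i] for i in range(n)]
    elif cv == "kfold":
        rng = np.random.default_rng(seed)
        order = rng.permutation(n)
        folds = [list(order[k::n_folds]) for k in range(n_folds)]
        folds = [f for f in folds if f]
    else:
        raise ValidationError("cv must be 'loo' or 'kfold'")
    press = 0.0
    for held in folds:
        mask = np.ones(n, dtype=bool)
        mask[held] = False
        if y[mask].min() == y[mask].max():
            raise ValidationError("a cross-validation fold lost one class entirely")
        xm, ym, Bf, _ = _pls1_train(x[mask], y[mask], n_components)
        pred = (x[held] - xm) @ Bf + ym
        press += float(((y[held] - pred) ** 2).sum())
    q2 = 1.0 - press / tss
    return PlsdaModel(n_components=n_components, r2=r2, q2=q2, scores=T, coef=B)


def pearson_cluster(matrix) -> Dendrogram:
    """Average-linkage clustering of samples with d = 1 - Pearson r."""
    x, labels = _as_matrix(matrix)
    if x.shape[0] < 2:
        raise ValidationError("clustering needs at least 2 samples")
    sd = x.std(axis=1)
    if (sd == 0).any():
        bad = [labels[i] for i in np.flatnonzero(sd == 0)]
        raise ValidationError(f"zero-variance sample(s): {bad}")
    r = np.corrcoef(x)
    d = 1.0 - r
    np.fill_diagonal(d, 0.0)
    d = np.clip((d + d.T) / 2.0, 0.0, None)  # symmetrize fp noise
    z = linkage(squareform(d, checks=False), method="average")
    return Dendrogram(linkage_matrix=z, labels=labels)
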