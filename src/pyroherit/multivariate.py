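"""Exploratory layer: NIPALS PCA and ion/sample clustering.

PCA uses the NIPALS algorithm on mean-centered data (components extracted
one at a time with deflation), which on convergence coincides with the
singular value decomposition.  Ions are clustered hierarchically on
Spearman rank-correlation distance with complete linkage; samples by Ward's
method on Euclidean distance, and K-means partitions are available for both.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform
from scipy.stats import rankdata

__all__ = [
    "PCAResult",
    "ClusterResult",
    "pca_nipals",
    "spearman_complete_hclust",
    "ward_sample_clusters",
    "kmeans_partition",
]


@dataclass
class PCAResult:
    """Scores, unit-norm loadings and explained-variance fractions."""

    scores: pd.DataFrame  #: samples x components
    loadings: pd.DataFrame  #: variables x components
    explained_variance_ratio: np.ndarray
    n_components: int
    converged: list = field(default_factory=list)  #: per-component flags
    mean_: np.ndarray | None = None

    def summary(self) -> str:
        parts = ", ".join(
            f"PC{i + 1} {100 * v:.1f}%" for i, v in enumerate(self.explained_variance_ratio)
        )
        return f"NIPALS PCA ({self.n_components} components): {parts}"


def pca_nipals(matrix, n_components: int, max_iter: int = 100, tol: float = 1e-9) -> PCAResult:
    """NIPALS principal components of a mean-centered matrix.

    Iterates scores/loadings per component until the score vector changes by
    a relative amount below ``tol`` (or ``max_iter`` sweeps), then deflates.
    Fully converged components match the SVD up to sign.
    """
    X = matrix.to_numpy(dtype=float) if hasattr(matrix, "to_numpy") else np.asarray(matrix, float)
    index = getattr(matrix, "index", pd.RangeIndex(X.shape[0]))
    columns = getattr(matrix, "columns", pd.RangeIndex(X.shape[1]))
    if n_components > min(X.shape):
        raise ValueError("n_components exceeds matrix rank bound")
    mean = X.mean(axis=0)
    Xc = X - mean
    total_var = float((Xc**2).sum())
    if total_var == 0.0:
        raise ValueError("constant matrix has no principal components")
    scores = np.zeros((X.shape[0], n_components))
    loadings = np.zeros((X.shape[1], n_components))
    explained = np.zeros(n_components)
    converged = []
    for a in range(n_components):
        # start from the column with the largest remaining variance
        t = Xc[:, int(np.argmax((Xc**2).sum(axis=0)))].copy()
        ok = False
        for _ in range(max_iter):
            p = Xc.T @ t / float(t @ t)
            p /= np.linalg.norm(p)
            t_new = Xc @ p
            if np.linalg.norm(t_new - t) <= tol * max(np.linalg.norm(t_new), 1e-300):
                t = t_new
                ok = True
                break
            t = t_new
        p = Xc.T @ t / float(t @ t)
        norm_p = np.linalg.norm(p)
        p /= norm_p
        t = Xc @ p
        Xc = Xc - np.outer(t, p)
        scores[:, a], loadings[:, a] = t, p
        explained[a] = float(t @ t) / total_var
        converged.append(ok)
    comp_names = [f"PC{i + 1}" for i in range(n_components)]
    return PCAResult(
        scores=pd.DataFrame(scores, index=index, columns=comp_names),
        loadings=pd.DataFrame(loadings, index=columns, columns=comp_names),
        explained_variance_ratio=explained,
        n_components=n_components,
        converged=converged,
        mean_=mean,
    )


@dataclass
class ClusterResult:
    """Cluster labels (1..k) with the merge tree for hierarchical methods."""

    method: str
    labels: pd.Series
    metric: str
    linkage_matrix: np.ndarray | None = None
    inertia: float | None = None  #: within-cluster sum of squares (K-means)

    @property
    def k(self) -> int:
        return int(self.labels.nunique())

    def summary(self) -> str:
        sizes = self.labels.value_counts().sort_index().tolist()
        return f"{self.method} ({self.metric}): {self.k} clusters, sizes {sizes}"


def spearman_distance(ion_matrix: pd.DataFrame) -> pd.DataFrame:
    """d(a, b) = 1 - Spearman rho between ion intensity profiles (ties averaged)."""
    X = ion_matrix.to_numpy(dtype=float)
    ranks = np.apply_along_axis(rankdata, 0, X)
    rc = ranks - ranks.mean(axis=0)
    sd = rc.std(axis=0)
    zero = sd == 0
    if zero.any():
        raise ValueError(
            f"zero-variance ion(s) have undefined rank correlation: "
            f"{list(ion_matrix.columns[zero][:5])}"
        )
    rho = (rc / sd).T @ (rc / sd) / len(rc)
    np.clip(rho, -1.0, 1.0, out=rho)
    return pd.DataFrame(1.0 - rho, index=ion_matrix.columns, columns=ion_matrix.columns)


def spearman_complete_hclust(ion_matrix: pd.DataFrame, k: int) -> ClusterResult:
    """Complete-linkage hierarchy of ions on Spearman correlation distance.

    ``ion_matrix`` is samples x ions; zero-variance ions are reported and
    excluded before clustering.
    """
    if ion_matrix.shape[1] < 2 or ion_matrix.shape[0] < 3:
        raise ValueError("need at least 2 ions and 3 samples")
    cols = ion_matrix.columns
    sd = ion_matrix.std(axis=0)
    dropped = list(cols[sd == 0])
    use = ion_matrix.loc[:, sd > 0]
    D = spearman_distance(use)
    dist = squareform(D.to_numpy(), checks=False)
    Z = linkage(dist, method="complete")
    labels = pd.Series(fcluster(Z, t=k, criterion="maxclust"), index=use.columns, name="cluster")
    if dropped:
        labels = labels.reindex(cols)  # dropped ions get NaN labels
        labels.attrs["dropped_zero_variance"] = dropped
    return ClusterResult("complete-linkage HC", labels, "1 - spearman rho", Z)


def ward_sample_clusters(sample_matrix: pd.DataFrame, k: int) -> ClusterResult:
    """Ward hierarchy of samples on Euclidean distance, cut at k clusters."""
    if k > len(sample_matrix):
        raise ValueError("k exceeds the number of samples")
    Z = linkage(sample_matrix.to_numpy(dtype=float), method="ward")
    labels = pd.Series(
        fcluster(Z, t=k, criterion="maxclust"), index=sample_matrix.index, name="cluster"
    )
    return ClusterResult("Ward HC", labels, "euclidean", Z)


def kmeans_partition(matrix: pd.DataFrame, k: int, seed: int = 0, n_init: int = 10) -> ClusterResult:
    """Best-of-``n_init`` Lloyd's K-means; empty clusters are re-seeded.

    Deterministic for a fixed seed; returns labels 1..k and the within-
    cluster sum of squares of the best run.
    """
    X = matrix.to_numpy(dtype=float)
    n = len(X)
    if k < 1 or k > n:
        raise ValueError("k must be in 1..n_samples")
    rng = np.random.default_rng(seed)
    best_labels, best_wcss = None, np.inf
    for _ in range(n_init):
        centers = X[rng.choice(n, size=k, replace=False)].copy()
        for _ in range(300):
            d2 = ((X[:, None, :] - centers[None, :, :]) ** 2).sum(axis=2)
            lab = d2.argmin(axis=1)
            new_centers = centers.copy()
            for j in range(k):
                members = X[lab == j]
                if len(members):
                    new_centers[j] = members.mean(axis=0)
                else:  # re-seed an empty centroid at a random point
                    new_centers[j] = X[rng.integers(n)]
            if np.allclose(new_centers, centers):
                centers = new_centers
                break
            centers = new_centers
        wcss = float(((X - centers[lab]) ** 2).sum())
        if wcss < best_wcss:
            best_wcss, best_labels = wcss, lab
    labels = pd.Series(best_labels + 1, index=matrix.index, name="cluster")
    return ClusterResult("K-means", labels, "euclidean", None, inertia=best_wcss)
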