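"""z-scoring and shape-based clustering of expression time courses.

Rows (genes) are standardized to mean 0 / population SD 1 so that clustering
groups trajectory *shapes* rather than expression levels.  Clustering is
hierarchical agglomerative with distance ``1 - Pearson correlation`` and
average linkage — a fully deterministic, standard choice for seasonal
expression profiles.  The number of clusters is either fixed or selected by
maximizing the mean silhouette over a configured range (ties to the smaller
k).  Constant rows carry no shape information: they are z-scored to all
zeros, flagged, and excluded from clustering.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform
from sklearn.metrics import silhouette_score

__all__ = [
    "zscore_rows",
    "ClusterAssignment",
    "cluster_trajectories",
    "cluster_mean_profiles",
]


def zscore_rows(matrix: pd.DataFrame) -> tuple[pd.DataFrame, list[str]]:
    """Standardize each row to mean 0 and population SD 1.

    Returns the z-scored matrix and the list of constant rows (mapped to all
    zeros).  Requires >= 2 timepoints and no missing values.
    """
    if matrix.shape[1] < 2:
        raise ValueError("need at least 2 timepoints to z-score")
    if matrix.isna().any().any():
        raise ValueError("matrix contains missing values")
    values = matrix.to_numpy(dtype=float)
    means = values.mean(axis=1, keepdims=True)
    sds = values.std(axis=1, keepdims=True)  # population SD
    constant = (sds == 0).ravel()
    sds[sds == 0] = 1.0
    z = (values - means) / sds
    z[constant, :] = 0.0
    out = pd.DataFrame(z, index=matrix.index, columns=matrix.columns)
    return out, list(matrix.index[constant].astype(str))


@dataclass
class ClusterAssignment:
    """Gene -> cluster labels (1..k) plus per-cluster mean z-score profiles."""

    labels: pd.Series  # index = gene ids, values in 1..k
    k: int
    mean_profiles: pd.DataFrame  # index = cluster, columns = timepoints
    silhouette: float | None = None
    excluded_constant: list[str] | None = None


def _correlation_distance(z: np.ndarray) -> np.ndarray:
    corr = np.corrcoef(z)
    dist = 1.0 - corr
    np.fill_diagonal(dist, 0.0)
    return np.clip(dist, 0.0, 2.0)


def cluster_trajectories(
    zscored: pd.DataFrame,
    k: int | None = None,
    k_range: tuple[int, int] = (2, 10),
) -> ClusterAssignment:
    """Cluster z-scored trajectories; silhouette-selected k unless pinned.

    Constant (all-zero) rows are excluded and reported separately; clusters
    are relabelled 1..k by order of first appearance for determinism.
    """
    constant_mask = (zscored.to_numpy(dtype=float).std(axis=1) == 0)
    excluded = list(zscored.index[constant_mask].astype(str))
    active = zscored.loc[~constant_mask]
    n = active.shape[0]
    if n < 2:
        raise ValueError("need at least 2 non-constant rows to cluster")
    z = active.to_numpy(dtype=float)
    dist = _correlation_distance(z)
    condensed = squareform(dist, checks=False)
    tree = linkage(condensed, method="average")

    def cut(kk: int) -> np.ndarray:
        return fcluster(tree, t=kk, criterion="maxclust")

    if k is not None:
        if k > n:
            raise ValueError(f"k={k} exceeds number of clusterable genes ({n})")
        raw = cut(k)
        sil = None
    else:
        lo, hi = k_range
        hi = min(hi, n - 1)
        if lo < 2 or lo > hi:
            raise ValueError(f"invalid k range ({lo}, {hi}) for {n} genes")
        best_k, best_sil, best_raw = None, -np.inf, None
        for kk in range(lo, hi + 1):
            raw_kk = cut(kk)
            if len(np.unique(raw_kk)) < 2:
                continue
            s = silhouette_score(dist, raw_kk, metric="precomputed")
            if s > best_sil:  # strict: ties keep the smaller k
                best_k, best_sil, best_raw = kk, s, raw_kk
        if best_raw is None:
            raise ValueError("silhouette selection failed for every k in range")
        raw, sil = best_raw, float(best_sil)

    # relabel clusters by first appearance
    relabel: dict[int, int] = {}
    labels = np.empty_like(raw)
    for i, r in enumerate(raw):
        if r not in relabel:
            relabel[r] = len(relabel) + 1
        labels[i] = relabel[r]
    series = pd.Series(labels, index=active.index, name="cluster")
    assignment = ClusterAssignment(
        labels=series,
        k=int(labels.max()),
        mean_profiles=pd.DataFrame(),
        silhouette=sil,
        excluded_constant=excluded,
    )
    assignment.mean_profiles = cluster_mean_profiles(assignment, active)
    return assignment


def cluster_mean_profiles(
    assignment: ClusterAssignment, zscored: pd.DataFrame
) -> pd.DataFrame:
    """Arithmetic mean z-score profile per cluster (empty clusters excluded)."""
    common = assignment.labels.index.intersection(zscored.index)
    if len(common) < len(assignment.labels):
        raise ValueError("assignment refers to genes absent from the matrix")
    grouped = zscored.loc[assignment.labels.index].groupby(assignment.labels)
    return grouped.mean()
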