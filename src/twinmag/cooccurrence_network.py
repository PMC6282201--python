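"""Weighted cooccurrence networks from standardized abundance profiles.

Spearman correlation (after a 10% prevalence filter), soft-threshold
adjacency a_ij = |rho_ij|^beta, the unsigned topological overlap measure
(TOM), ward-linkage clustering of the 1 - TOM dissimilarity, and PageRank
centrality of the fully connected TOM-weighted graph.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

__all__ = [
    "spearman_matrix",
    "adjacency",
    "tom",
    "cluster_taxa",
    "pagerank",
    "build_network",
]


def spearman_matrix(
    values: pd.DataFrame,
    prevalence_min: float = 0.10,
    prevalence_source: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Pairwise Spearman rho between feature columns.

    Features present (value > 0) in fewer than ``prevalence_min`` of the
    samples are dropped before correlation; presence is judged on
    ``prevalence_source`` (e.g. the raw counts) when the input itself is
    already z-scored. The diagonal is exactly 1.
    """
    if len(values) < 3:
        raise ValueError("need at least 3 subjects")
    source = values if prevalence_source is None else prevalence_source[values.columns]
    prevalence = (source.to_numpy() > 0).mean(axis=0)
    keep = values.columns[prevalence >= prevalence_min]
    if len(keep) < 2:
        raise ValueError("fewer than 2 features survive the prevalence filter")
    sub = values[keep]
    rho = stats.spearmanr(sub.to_numpy(), axis=0).statistic
    if np.ndim(rho) == 0:  # scipy collapses the 2-feature case to a scalar
        rho = np.array([[1.0, float(rho)], [float(rho), 1.0]])
    np.fill_diagonal(rho, 1.0)
    return pd.DataFrame(rho, index=keep, columns=keep)


def adjacency(rho: pd.DataFrame, beta: float = 1.0) -> pd.DataFrame:
    """Unsigned soft-threshold adjacency |rho|^beta with zero diagonal."""
    if beta <= 0:
        raise ValueError("beta must be positive")
    a = np.abs(rho.to_numpy(dtype=float)) ** beta
    np.fill_diagonal(a, 0.0)
    return pd.DataFrame(a, index=rho.index, columns=rho.columns)


def tom(adj: pd.DataFrame) -> pd.DataFrame:
    """Unsigned topological overlap similarity.

    TOM_ij = (sum_u a_iu a_uj + a_ij) / (min(k_i, k_j) + 1 - a_ij) for
    i != j, with k_i the weighted degree; TOM_ii = 1. Credits shared
    neighborhoods on top of the direct edge weight.
    """
    A = adj.to_numpy(dtype=float)
    if not np.allclose(A, A.T):
        raise ValueError("adjacency must be symmetric")
    if (A < 0).any() or (A > 1).any():
        raise ValueError("adjacency entries must lie in [0, 1]")
    A = A.copy()
    np.fill_diagonal(A, 0.0)
    k = A.sum(axis=1)
    shared = A @ A  # diagonal of A is zero, so this is sum over u != i, j
    numer = shared + A
    denom = np.minimum.outer(k, k) + 1.0 - A
    with np.errstate(invalid="ignore", divide="ignore"):
        T = numer / denom
    T[~np.isfinite(T)] = 0.0
    np.fill_diagonal(T, 1.0)
    return pd.DataFrame(T, index=adj.index, columns=adj.columns)


def cluster_taxa(
    tom_sim: pd.DataFrame,
    n_clusters: int | None = None,
    height: float | None = None,
):
    """Ward-linkage agglomeration of the 1 - TOM dissimilarity.

    Returns (linkage matrix, flat cluster labels as a Series). The flat cut
    uses ``n_clusters`` if given, else ``height``, else 2 clusters.
    """
    if len(tom_sim) < 2:
        raise ValueError("need at least 2 features to cluster")
    D = 1.0 - tom_sim.to_numpy(dtype=float)
    np.fill_diagonal(D, 0.0)
    D = np.clip((D + D.T) / 2.0, 0.0, None)
    Z = hierarchy.linkage(squareform(D, checks=False), method="ward")
    if n_clusters is not None:
        labels = hierarchy.fcluster(Z, t=n_clusters, criterion="maxclust")
    elif height is not None:
        labels = hierarchy.fcluster(Z, t=height, criterion="distance")
    else:
        labels = hierarchy.fcluster(Z, t=2, criterion="maxclust")
    return Z, pd.Series(labels, index=tom_sim.index, name="cluster")


def pagerank(
    weights: pd.DataFrame,
    damping: float = 0.85,
    tol: float = 1e-10,
    max_iter: int = 10_000,
) -> pd.Series:
    """PageRank of the damped random walk on a weighted graph.

    Works on fully connected weighted networks (where unweighted degree
    centralities are uninformative). Rows with zero weight redistribute
    uniformly. The result sums to 1 and is invariant to global scaling of
    the weights.
    """
    W = weights.to_numpy(dtype=float)
    if (W < 0).any():
        raise ValueError("weights must be nonnegative")
    n = W.shape[0]
    rowsum = W.sum(axis=1)
    if (rowsum == 0).all():
        raise ValueError("all-zero weight matrix")
    P = np.zeros_like(W)
    nonzero = rowsum > 0
    P[nonzero] = W[nonzero] / rowsum[nonzero, None]
    dangling = ~nonzero
    p = np.full(n, 1.0 / n)
    for _ in range(max_iter):
        new = (1 - damping) / n + damping * (
            P.T @ p + p[dangling].sum() / n
        )
        if np.abs(new - p).sum() < tol:
            p = new
            break
        p = new
    p = p / p.sum()
    return pd.Series(p, index=weights.index, name="pagerank")


def build_network(
    standardized: pd.DataFrame,
    prevalence_source: pd.DataFrame | None = None,
    prevalence_min: float = 0.10,
    beta: float = 1.0,
    damping: float = 0.85,
    n_clusters: int | None = None,
) -> dict:
    """Full network stage: rho -> adjacency -> TOM -> clusters + PageRank."""
    rho = spearman_matrix(
        standardized, prevalence_min=prevalence_min, prevalence_source=prevalence_source
    )
    adj = adjacency(rho, beta=beta)
    T = tom(adj)
    Z, clusters = cluster_taxa(T, n_clusters=n_clusters)
    pr = pagerank(T, damping=damping)
    return {
        "rho": rho,
        "adjacency": adj,
        "tom": T,
        "linkage": Z,
        "clusters": clusters,
        "pagerank": pr,
        "variant": "unsigned adjacency, unsigned TOM",
    }


def to_networkx(tom_sim: pd.DataFrame):
    """TOM-weighted fully connected undirected graph (self-loops dropped)."""
    import networkx as nx

    G = nx.Graph()
    feats = list(tom_sim.index)
    G.add_nodes_from(feats)
    T = tom_sim.to_numpy()
    for i in range(len(feats)):
        for j in range(i + 1, len(feats)):
            G.add_edge(feats[i], feats[j], weight=float(T[i, j]))
    return G
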