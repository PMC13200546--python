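"""Clustering back-ends and partition-agreement metrics.

Embedding-space methods (k-means, Ward agglomerative, HDBSCAN, spectral)
run on an :class:`~golden.embeddings.EmbeddingMatrix`; graph methods
(Louvain, Girvan-Newman, spectral) run on a :class:`~golden.network.PagNetwork`
or a dense adjacency matrix.  Agreement between partitions is measured with
the Adjusted Rand Index (chance-corrected pair counting, perfect = 1) and
Normalized Mutual Information (arithmetic-mean normalisation, in [0, 1]).
HDBSCAN's noise label -1 is passed through to the metrics as an ordinary
label, matching the usual library convention.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import islice
from typing import Mapping

import numpy as np
import networkx as nx
from scipy.linalg import eigh
from sklearn import metrics as skmetrics
from sklearn.cluster import (HDBSCAN, AgglomerativeClustering, KMeans,
                             SpectralClustering)

from .embeddings import EmbeddingMatrix
from .network import PagNetwork

__all__ = [
    "ClusteringResult",
    "cluster",
    "spectral_adjacency",
    "ari",
    "nmi",
]

EMBEDDING_METHODS = {"kmeans", "agglomerative", "hdbscan", "spectral"}
GRAPH_METHODS = {"louvain", "girvan_newman", "spectral"}


@dataclass
class ClusteringResult:
    labels: dict[str, int]
    method: str
    params: dict = field(default_factory=dict)
    seed: int | None = None

    @property
    def k_effective(self) -> int:
        return len({l for l in self.labels.values() if l != -1})

    def label_array(self, ids: list[str]) -> np.ndarray:
        return np.array([self.labels[i] for i in ids])

    def write_tsv(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            for rid, lab in self.labels.items():
                fh.write(f"{rid}\t{lab}\n")


def _align(a: Mapping[str, int], b: Mapping[str, int]) -> tuple[np.ndarray, np.ndarray]:
    if set(a) != set(b):
        missing = set(a).symmetric_difference(b)
        raise ValueError(f"label mappings cover different ids (e.g. {sorted(islice(missing, 3))})")
    keys = sorted(a)
    return (np.array([a[k] for k in keys]), np.array([b[k] for k in keys]))


def ari(a: Mapping[str, int], b: Mapping[str, int]) -> float:
    """Adjusted Rand Index between two partitions of the same ids."""
    x, y = _align(a, b)
    return float(skmetrics.adjusted_rand_score(x, y))


def nmi(a: Mapping[str, int], b: Mapping[str, int]) -> float:
    """Normalized Mutual Information (arithmetic-mean normalisation)."""
    x, y = _align(a, b)
    return float(skmetrics.normalized_mutual_info_score(x, y, average_method="arithmetic"))


def spectral_adjacency(adj: np.ndarray, k: int, seed: int = 0, mode: str = "assortative") -> np.ndarray:
    """Spectral clustering of a (weighted) adjacency matrix.

    ``assortative`` embeds with the k bottom eigenvectors of the normalised
    Laplacian (classic min-cut communities).  ``general`` embeds with the k
    eigenvectors whose normalised-Laplacian eigenvalues lie furthest from 1
    (equivalently, largest |eigenvalue| of the normalised adjacency), which
    also recovers disassortative/bipartite-like block structure.  Rows are
    normalised, then k-means.  Isolated nodes are treated as degree 1.
    """
    n = adj.shape[0]
    if k > n:
        raise ValueError(f"k={k} exceeds number of nodes {n}")
    deg = adj.sum(axis=1)
    deg[deg == 0] = 1.0
    d_isqrt = 1.0 / np.sqrt(deg)
    lap = np.eye(n) - d_isqrt[:, None] * adj * d_isqrt[None, :]
    if mode == "assortative":
        _, vecs = eigh(lap, subset_by_index=[0, k - 1])
    elif mode == "general":
        vals, vecs = eigh(lap)
        order = np.argsort(-np.abs(1.0 - vals), kind="stable")[:k]
        vecs = vecs[:, order]
    else:
        raise ValueError(f"unknown spectral mode {mode!r}")
    norms = np.linalg.norm(vecs, axis=1, keepdims=True)
    norms[norms == 0] = 1.0
    vecs = vecs / norms
    km = KMeans(n_clusters=k, n_init=10, random_state=seed)
    return km.fit_predict(vecs)


def cluster(
    data: EmbeddingMatrix | PagNetwork,
    method: str,
    k: int | None = None,
    min_cluster_size: int = 5,
    seed: int = 0,
    **params,
) -> ClusteringResult:
    """Cluster an embedding matrix or a PAG network.

    k-means/agglomerative/spectral require ``k``; HDBSCAN infers the number
    of clusters (``min_cluster_size`` defaults to 5) and may emit -1 noise
    labels; Louvain and Girvan-Newman operate on the graph form only.
    Deterministic for a fixed seed.
    """
    if isinstance(data, EmbeddingMatrix):
        if method not in EMBEDDING_METHODS:
            raise TypeError(f"method {method!r} cannot run on an embedding matrix")
        ids = list(data.row_ids)
        X = data.vectors
        if method in ("kmeans", "agglomerative", "spectral"):
            if k is None:
                raise ValueError(f"{method} requires k")
            if k > len(ids):
                raise ValueError(f"k={k} exceeds {len(ids)} points")
        if method == "kmeans":
            labels = KMeans(n_clusters=k, n_init=10, random_state=seed).fit_predict(X)
        elif method == "agglomerative":
            labels = AgglomerativeClustering(n_clusters=k, linkage=params.pop("linkage", "ward")).fit_predict(X)
        elif method == "hdbscan":
            if len(ids) < min_cluster_size:
                labels = np.full(len(ids), -1)
            else:
                labels = HDBSCAN(min_cluster_size=min_cluster_size, copy=True,
                                 **params).fit_predict(X)
        else:  # spectral on embeddings: RBF affinity (scikit-learn)
            labels = SpectralClustering(n_clusters=k, random_state=seed,
                                        **params).fit_predict(X)
    elif isinstance(data, PagNetwork):
        if method not in GRAPH_METHODS:
            raise TypeError(f"method {method!r} cannot run on a graph")
        ids = list(data.node_ids)
        if method == "spectral":
            if k is None:
                raise ValueError("spectral requires k")
            labels = spectral_adjacency(data.adjacency(weighted=True), k, seed)
        elif method == "louvain":
            g = data.to_networkx()
            comms = nx.community.louvain_communities(g, weight="weight", seed=seed)
            labels = _communities_to_labels(ids, comms)
        else:  # girvan_newman, cut at the first split reaching k
            if k is None:
                raise ValueError("girvan_newman requires k")
            g = data.to_networkx()
            comms = _girvan_newman_k(g, k)
            labels = _communities_to_labels(ids, comms)
    else:
        raise TypeError(f"unsupported input type {type(data).__name__}")
    return ClusteringResult(dict(zip(ids, (int(l) for l in labels))), method,
                            params={"k": k, "min_cluster_size": min_cluster_size, **params},
                            seed=seed)


def _communities_to_labels(ids: list[str], comms) -> np.ndarray:
    lab = {}
    for ci, comm in enumerate(comms):
        for node in comm:
            lab[node] = ci
    return np.array([lab[i] for i in ids])


def _girvan_newman_k(g: nx.Graph, k: int) -> list[set]:
    n_comp = nx.number_connected_components(g)
    if n_comp >= k:
        return list(nx.connected_components(g))
    for parts in nx.community.girvan_newman(g):
        if len(parts) >= k:
            return list(parts)
    return [set(g.nodes)]
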