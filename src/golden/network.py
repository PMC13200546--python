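"""Co-membership (m-type) gene-set networks.

Nodes are PAGs; an edge connects two PAGs whose gene overlap is significant
under a one-sided hypergeometric (enrichment) test against the collection's
gene universe.  Edge weight is -log10(p), so larger means stronger overlap.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from pathlib import Path

import math

import networkx as nx
import numpy as np
from scipy import stats

from .geneset import GeneSetCollection

__all__ = [
    "PagNetwork",
    "hypergeometric_overlap_pvalue",
    "build_mtype_network",
    "threshold_network",
    "read_edge_list",
]


@dataclass(frozen=True)
class Edge:
    i: str
    j: str
    overlap: int
    p_value: float
    weight: float


@dataclass
class PagNetwork:
    """Undirected weighted PAG-PAG overlap graph G = (V, E, W)."""

    node_ids: list[str]
    edges: list[Edge]
    universe_size: int
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        known = set(self.node_ids)
        for e in self.edges:
            if e.i == e.j:
                raise ValueError(f"self-loop on {e.i}")
            if e.i not in known or e.j not in known:
                raise ValueError(f"edge endpoint not in node_ids: {e.i}-{e.j}")

    @property
    def n_nodes(self) -> int:
        return len(self.node_ids)

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def degrees(self) -> dict[str, int]:
        deg = {n: 0 for n in self.node_ids}
        for e in self.edges:
            deg[e.i] += 1
            deg[e.j] += 1
        return deg

    def to_networkx(self) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(self.node_ids)
        for e in self.edges:
            g.add_edge(e.i, e.j, weight=e.weight, overlap=e.overlap, p_value=e.p_value)
        return g

    def adjacency(self, weighted: bool = True) -> np.ndarray:
        """Dense symmetric adjacency with rows/cols ordered as node_ids."""
        idx = {n: k for k, n in enumerate(self.node_ids)}
        a = np.zeros((self.n_nodes, self.n_nodes))
        for e in self.edges:
            w = e.weight if weighted else 1.0
            a[idx[e.i], idx[e.j]] = w
            a[idx[e.j], idx[e.i]] = w
        return a

    def write_edge_list(self, path: str | Path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            fh.write("#nodes\t" + "\t".join(self.node_ids) + "\n")
            fh.write(f"#universe_size\t{self.universe_size}\n")
            for e in self.edges:
                fh.write(f"{e.i}\t{e.j}\t{e.overlap}\t{e.p_value:.17g}\t{e.weight:.17g}\n")

    def write_graphml(self, path: str | Path) -> None:
        nx.write_graphml(self.to_networkx(), path)


def read_edge_list(path: str | Path) -> PagNetwork:
    nodes: list[str] = []
    universe_size = 0
    edges: list[Edge] = []
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if parts[0] == "#nodes":
                nodes = parts[1:]
            elif parts[0] == "#universe_size":
                universe_size = int(parts[1])
            else:
                i, j, k, p, w = parts
                edges.append(Edge(i, j, int(k), float(p), float(w)))
    return PagNetwork(nodes, edges, universe_size)


def hypergeometric_overlap_pvalue(k: int, n_a: int, n_b: int, N: int) -> float:
    """Upper-tail P(X >= k) for X ~ Hypergeometric(N, n_a, n_b).

    The probability that two gene sets of sizes ``n_a`` and ``n_b`` drawn
    from a universe of ``N`` genes share at least ``k`` members by chance.
    Enrichment (one-sided) only; always in (0, 1].
    """
    if not (0 <= n_a <= N and 0 <= n_b <= N):
        raise ValueError(f"set sizes must satisfy 0 <= n_a,n_b <= N (got {n_a},{n_b},{N})")
    lo = max(0, n_a + n_b - N)
    if not (lo <= k <= min(n_a, n_b)):
        raise ValueError(
            f"overlap k={k} outside feasible range [{lo},{min(n_a, n_b)}]"
        )
    if k <= lo:
        return 1.0
    # sf(k-1) = P(X >= k)
    p = float(stats.hypergeom.sf(k - 1, N, n_a, n_b))
    return min(max(p, 5e-324), 1.0)


def build_mtype_network(
    collection: GeneSetCollection,
    p_cutoff: float = 0.05,
    min_overlap: int = 1,
    universe_size: int | None = None,
) -> PagNetwork:
    """Build the m-type network: one edge per PAG pair whose overlap count is
    >= ``min_overlap`` and hypergeometric p <= ``p_cutoff``.

    Isolated PAGs are retained as nodes.  ``universe_size`` overrides the
    default background |collection.universe|.
    """
    if len(collection) == 0:
        raise ValueError("collection is empty")
    N = universe_size if universe_size is not None else len(collection.universe)
    edges: list[Edge] = []
    for a, b in combinations(collection.pags, 2):
        k = len(a.gene_set & b.gene_set)
        if k < min_overlap:
            continue
        p = hypergeometric_overlap_pvalue(k, len(a), len(b), N)
        if p <= p_cutoff:
            edges.append(Edge(a.id, b.id, k, p, -math.log10(p)))
    return PagNetwork(collection.ids, edges, N, meta={"p_cutoff": p_cutoff, "min_overlap": min_overlap})


def threshold_network(net: PagNetwork, min_weight: float) -> PagNetwork:
    """Keep edges with weight >= ``min_weight``; nodes are never dropped."""
    kept = [e for e in net.edges if e.weight >= min_weight]
    return PagNetwork(list(net.node_ids), kept, net.universe_size, meta=dict(net.meta))
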