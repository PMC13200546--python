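"""Shared fixtures: small gene-set collections, toy networks, and a
session-scoped trained clusterability model (reused by several tests to
keep the suite fast)."""

from __future__ import annotations

import itertools

import pytest

from golden.clusterability import build_training_set, train_cdi
from golden.geneset import PAG, GeneSetCollection
from golden.network import Edge, PagNetwork


@pytest.fixture()
def tiny_collection() -> GeneSetCollection:
    return GeneSetCollection([
        PAG("A", "A", "descA", ("g1", "g2", "g3", "g4", "g5")),
        PAG("B", "B", "descB", ("g1", "g2", "g3", "g4", "g5")),
        PAG("C", "C", "descC", ("h1", "h2", "h3", "h4", "h5")),
    ])


@pytest.fixture()
def two_clique_network() -> tuple[PagNetwork, dict[str, int]]:
    """Two 10-cliques joined by a single bridge edge."""
    nodes = [f"n{i}" for i in range(20)]
    edges = []
    for grp in (range(10), range(10, 20)):
        for i, j in itertools.combinations(grp, 2):
            edges.append(Edge(nodes[i], nodes[j], 1, 0.01, 2.0))
    edges.append(Edge(nodes[0], nodes[10], 1, 0.01, 2.0))
    truth = {n: (0 if int(n[1:]) < 10 else 1) for n in nodes}
    return PagNetwork(nodes, edges, 100), truth


@pytest.fixture(scope="session")
def cdi_training_small():
    """A reduced clusterability sweep (3 replicates, 120-node graphs);
    adequate for scoring-behaviour tests."""
    return build_training_set(replicates=3, n_nodes=120, seed=7)


@pytest.fixture(scope="session")
def cdi_model_small(cdi_training_small):
    return train_cdi(cdi_training_small, split_seed=7)
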