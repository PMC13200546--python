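"""Synthetic ontologies, gene-set collections and descriptions with
controlled graph and semantic signal.

The generator emulates the statistical structure of an ontology benchmark:
one root, ``n_parents`` terms at depth 1, and their children at depth 2.
Each child's gene set mixes three pools — a global pool shared across all
parents (fraction ``between_parent_gene_overlap`` of the set), a
parent-specific core (bringing sibling overlap up to
``within_parent_gene_overlap``), and child-unique genes.  Descriptions are
bags of words drawn from a global vocabulary (fraction
``shared_vocab_fraction``) and a parent-specific vocabulary, which is
exactly the kind of signal the offline hashing encoder measures.  Setting
within == between and shared_vocab_fraction == 1 removes all class signal.
"""

from __future__ import annotations

from dataclasses import dataclass
import numpy as np

from .embeddings import EmbeddingMatrix
from .geneset import GeneSetCollection, OntologyDAG, PAG

__all__ = [
    "FixtureSpec",
    "Fixture",
    "make_fixture",
    "make_separable_embeddings",
    "make_random_collection",
    "make_toy_dag",
    "CLUSTERABLE",
    "NO_SIGNAL",
    "GRAPH_ONLY",
    "TEXT_ONLY",
]


@dataclass(frozen=True)
class FixtureSpec:
    n_parents: int = 2
    children_per_parent: tuple[int, int] = (8, 10)  # inclusive range
    genes_per_child: int = 50
    within_parent_gene_overlap: float = 0.8
    between_parent_gene_overlap: float = 0.0
    vocabulary_per_parent: int = 40
    description_length: int = 30
    shared_vocab_fraction: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        w, b = self.within_parent_gene_overlap, self.between_parent_gene_overlap
        if not (0 <= b <= w <= 1):
            raise ValueError(
                "need 0 <= between_parent_gene_overlap <= within_parent_gene_overlap <= 1"
            )
        if not 0 <= self.shared_vocab_fraction <= 1:
            raise ValueError("shared_vocab_fraction must lie in [0, 1]")
        if self.children_per_parent[0] < 2 or self.children_per_parent[0] > self.children_per_parent[1]:
            raise ValueError("children_per_parent must be a valid (lo, hi) range with lo >= 2")


# Presets used throughout the test-suite and docs.
CLUSTERABLE = FixtureSpec()
NO_SIGNAL = FixtureSpec(within_parent_gene_overlap=0.3, between_parent_gene_overlap=0.3,
                        shared_vocab_fraction=1.0)
GRAPH_ONLY = FixtureSpec(shared_vocab_fraction=1.0)
TEXT_ONLY = FixtureSpec(within_parent_gene_overlap=0.3, between_parent_gene_overlap=0.3,
                        shared_vocab_fraction=0.0)


@dataclass
class Fixture:
    dag: OntologyDAG
    collection: GeneSetCollection
    descriptions: dict[str, str]
    labels: dict[str, int]  # child id -> parent index
    spec: FixtureSpec


def make_fixture(spec: FixtureSpec = CLUSTERABLE) -> Fixture:
    """Generate a deterministic synthetic benchmark fixture."""
    rng = np.random.default_rng(spec.seed)
    g = spec.genes_per_child
    n_between = int(round(spec.between_parent_gene_overlap * g))
    n_core = int(round(spec.within_parent_gene_overlap * g)) - n_between
    n_unique = g - n_between - n_core

    global_pool = [f"GSHARED{i}" for i in range(max(n_between, 1))]
    shared_vocab = [f"common{i}" for i in range(max(spec.vocabulary_per_parent, 1))]

    edges: list[tuple[str, str]] = []
    pags: list[PAG] = []
    descriptions: dict[str, str] = {}
    labels: dict[str, int] = {}
    root = "ROOT"
    uid = 0
    for pi in range(spec.n_parents):
        # one branch node per parent so parent pairs are parent-unique
        branch = f"B{pi}"
        parent = f"P{pi}"
        edges.append((branch, root))
        edges.append((parent, branch))
        core = [f"GP{pi}_{i}" for i in range(max(n_core, 1))]
        vocab = [f"theme{pi}word{i}" for i in range(spec.vocabulary_per_parent)]
        n_children = int(rng.integers(spec.children_per_parent[0],
                                      spec.children_per_parent[1] + 1))
        for ci in range(n_children):
            child = f"P{pi}C{ci}"
            edges.append((child, parent))
            genes = (
                list(rng.choice(global_pool, size=n_between, replace=False)) if n_between else []
            ) + (
                list(rng.choice(core, size=n_core, replace=False)) if n_core else []
            ) + [f"GU{uid}_{i}" for i in range(n_unique)]
            uid += 1
            n_shared_words = int(round(spec.shared_vocab_fraction * spec.description_length))
            words = list(rng.choice(shared_vocab, size=n_shared_words)) + \
                list(rng.choice(vocab, size=spec.description_length - n_shared_words))
            rng.shuffle(words)
            desc = " ".join(words)
            pags.append(PAG(id=child, name=child, description=desc, genes=tuple(genes)))
            descriptions[child] = desc
            labels[child] = pi
    dag = OntologyDAG(edges)
    return Fixture(dag, GeneSetCollection(pags), descriptions, labels, spec)


def make_separable_embeddings(
    n_per_cluster: int,
    k: int,
    separation: float = 6.0,
    dim: int = 8,
    cluster_std: float = 1.0,
    seed: int = 0,
) -> tuple[EmbeddingMatrix, dict[str, int]]:
    """Gaussian blobs as an EmbeddingMatrix, for clustering/consensus tests."""
    rng = np.random.default_rng(seed)
    centers = rng.standard_normal((k, dim))
    centers *= separation / np.maximum(np.linalg.norm(centers, axis=1, keepdims=True), 1e-12)
    ids, rows, labels = [], [], {}
    for c in range(k):
        pts = centers[c] + cluster_std * rng.standard_normal((n_per_cluster, dim))
        for i, p in enumerate(pts):
            rid = f"c{c}_{i}"
            ids.append(rid)
            rows.append(p)
            labels[rid] = c
    return EmbeddingMatrix(ids, np.asarray(rows), "fused"), labels


def make_random_collection(
    n_sets: int = 25,
    genes_per_set: int = 50,
    universe_size: int = 400,
    vocabulary: int = 60,
    description_length: int = 25,
    seed: int = 0,
) -> tuple[GeneSetCollection, dict[str, str]]:
    """Structureless gene sets: each set drawn uniformly from one shared
    universe, all descriptions from one shared vocabulary.

    Pairwise overlaps then straddle the significance cutoff at random, so
    the m-type network is Erdos-Renyi-like (low clustering coefficient, no
    block structure) -- the canonical *unclusterable* input."""
    rng = np.random.default_rng(seed)
    universe = [f"G{i}" for i in range(universe_size)]
    vocab = [f"word{i}" for i in range(vocabulary)]
    pags, descriptions = [], {}
    for i in range(n_sets):
        sid = f"R{i}"
        genes = tuple(rng.choice(universe, size=genes_per_set, replace=False))
        desc = " ".join(rng.choice(vocab, size=description_length))
        pags.append(PAG(id=sid, name=sid, description=desc, genes=genes))
        descriptions[sid] = desc
    return GeneSetCollection(pags), descriptions


def make_toy_dag() -> OntologyDAG:
    """A small multi-level hierarchy for benchmark-enumeration tests.

    Three branches under the root; mid-level terms at depth 2 with child
    counts spanning both eligibility regimes; plus the tricky cases: two
    eligible terms sharing an immediate parent (A, D under br0), a term at
    a different depth (DEEP, depth 3, child of A), and a child shared by
    two otherwise-valid parents (SHARED, under both A and E)."""
    edges = [("br0", "ROOT"), ("br1", "ROOT"), ("br2", "ROOT"),
             ("A", "br0"), ("D", "br0"),
             ("B", "br1"), ("E", "br1"),
             ("C", "br2"), ("F", "br2"),
             ("DEEP", "A"), ("SHARED", "A"), ("SHARED", "E")]
    child_counts = {"A": 6, "D": 6, "B": 11, "E": 8, "C": 5, "F": 14, "DEEP": 5}
    uid = 0
    for parent, cnt in child_counts.items():
        for _ in range(cnt):
            edges.append((f"t{uid}", parent))
            uid += 1
    return OntologyDAG(edges)
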