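"""Graph-walk embeddings, the offline text encoder, and PCA alignment."""

import itertools

import numpy as np
import pytest

from golden.embeddings import (
    EmbeddingMatrix,
    HashingEncoder,
    WalkConfig,
    embed_graph,
    encode_descriptions,
    generate_walks,
    l2_normalize,
    pca_align,
    read_embedding_tsv,
)
from golden.network import Edge, PagNetwork

SMALL = WalkConfig(dim=32, walk_length=40, walks_per_node=5, epochs=3, seed=1)


def test_walk_starts_cover_each_node_walks_per_node_times(two_clique_network):
    net, _ = two_clique_network
    walks = generate_walks(net, SMALL)
    starts = [w[0] for w in walks]
    for node_idx in range(net.n_nodes):
        assert starts.count(node_idx) == SMALL.walks_per_node


def test_unbiased_walk_reduces_to_simple_random_walk():
    # 5-node toy: star plus one extra edge; p=q=1, unweighted
    nodes = list("abcde")
    edges = [Edge("a", x, 1, 0.5, 1.0) for x in "bcde"] + [Edge("b", "c", 1, 0.5, 1.0)]
    net = PagNetwork(nodes, edges, 10)
    cfg = WalkConfig(dim=8, walk_length=200, walks_per_node=50, return_p=1.0,
                     inout_q=1.0, weighted=False, seed=3)
    walks = generate_walks(net, cfg)
    # empirical transition frequencies out of node b (neighbours: a, c)
    trans = {x: 0 for x in "ac"}
    for w in walks:
        for prev, cur in zip(w, w[1:]):
            if prev == 1:  # node b
                trans[nodes[cur]] += 1
    total = sum(trans.values())
    # degree-normalised simple walk: uniform over b's 2 neighbours
    assert trans["a"] / total == pytest.approx(0.5, abs=0.05)


def test_embed_graph_separates_cliques(two_clique_network):
    net, truth = two_clique_network
    margins = []
    for seed in range(5):
        cfg = WalkConfig(dim=32, walk_length=40, walks_per_node=5, epochs=3, seed=seed)
        emb = embed_graph(net, cfg)
        S = emb.vectors @ emb.vectors.T
        within = np.mean([S[i, j] for grp in (range(10), range(10, 20))
                          for i, j in itertools.combinations(grp, 2)])
        between = np.mean([S[i, j] for i in range(10) for j in range(10, 20)])
        margins.append(within - between)
    assert min(margins) > 0.2


def test_embed_graph_deterministic(two_clique_network):
    net, _ = two_clique_network
    a = embed_graph(net, SMALL)
    b = embed_graph(net, SMALL)
    np.testing.assert_array_equal(a.vectors, b.vectors)


def test_isolated_node_gets_zero_vector():
    net = PagNetwork(["a", "b", "lone"], [Edge("a", "b", 1, 0.01, 2.0)], 10)
    emb = embed_graph(net, SMALL)
    np.testing.assert_array_equal(emb.row("lone"), np.zeros(SMALL.dim))
    assert np.linalg.norm(emb.row("a")) == pytest.approx(1.0, abs=1e-9)


def test_encoder_identical_texts_identical_rows():
    emb = encode_descriptions({"x": "alpha beta", "y": "alpha beta"})
    np.testing.assert_array_equal(emb.row("x"), emb.row("y"))


def test_encoder_shared_vocabulary_raises_cosine():
    enc = HashingEncoder(dim=64)
    emb = encode_descriptions({
        "a": "kinase signaling cascade pathway",
        "b": "kinase signaling cascade response",   # 3/4 tokens shared with a
        "c": "ribosome translation elongation assembly",  # disjoint from a
    }, enc)
    def cos(u, v):
        return float(u @ v / (np.linalg.norm(u) * np.linalg.norm(v)))
    assert cos(emb.row("a"), emb.row("b")) > cos(emb.row("a"), emb.row("c"))


def test_encoder_empty_text_zero_row():
    emb = encode_descriptions({"x": ""})
    np.testing.assert_array_equal(emb.row("x"), np.zeros(emb.dim))


def test_pca_align_exact_rank():
    rng = np.random.default_rng(0)
    base = rng.standard_normal((2, 20))
    data = rng.standard_normal((30, 2)) @ base  # exact rank 2
    sem = EmbeddingMatrix([f"r{i}" for i in range(30)], data, "semantic")
    out = pca_align(sem, 2)
    assert out.meta["retained_variance"] == pytest.approx(1.0, abs=1e-9)
    assert out.dim == 2


def test_pca_align_isotropic_variance_matches_eigenvalue_sum(caplog):
    rng = np.random.default_rng(1)
    data = rng.standard_normal((5000, 100))
    sem = EmbeddingMatrix([f"r{i}" for i in range(5000)], data, "semantic")
    with caplog.at_level("WARNING", logger="golden.embeddings"):
        out = pca_align(sem, 10)
    # eigenvalue-sum oracle on the centred covariance
    centred = data - data.mean(axis=0)
    evals = np.sort(np.linalg.eigvalsh(np.cov(centred.T)))[::-1]
    expect = evals[:10].sum() / evals.sum()
    assert out.meta["retained_variance"] == pytest.approx(expect, rel=1e-9)
    assert out.meta["retained_variance"] == pytest.approx(0.10, abs=0.03)
    assert any("retains" in rec.message for rec in caplog.records)


def test_pca_full_dim_preserves_distances():
    rng = np.random.default_rng(2)
    data = rng.standard_normal((40, 8))
    sem = EmbeddingMatrix([f"r{i}" for i in range(40)], data, "semantic")
    out = pca_align(sem, 8, normalize=False)
    d_in = np.linalg.norm(data[:, None] - data[None, :], axis=-1)
    d_out = np.linalg.norm(out.vectors[:, None] - out.vectors[None, :], axis=-1)
    np.testing.assert_allclose(d_in, d_out, atol=1e-6)


def test_pca_target_dim_too_large_rejected():
    sem = EmbeddingMatrix(["a", "b", "c"], np.eye(3, 5), "semantic")
    with pytest.raises(ValueError):
        pca_align(sem, 3)  # n_rows-1 == 2


def test_l2_normalize_rows():
    m = EmbeddingMatrix(["u", "v", "z"], np.array([[1.0, 0.0], [3.0, 4.0], [0.0, 0.0]]), "graph")
    out = l2_normalize(m)
    np.testing.assert_allclose(out.row("u"), [1.0, 0.0])
    np.testing.assert_allclose(out.row("v"), [0.6, 0.8])
    np.testing.assert_array_equal(out.row("z"), [0.0, 0.0])
    assert out.l2_normalized


def test_embedding_tsv_round_trip(tmp_path):
    m = EmbeddingMatrix(["a", "b"], np.array([[0.1, -2.5], [3.25, 1e-7]]), "fused")
    p = tmp_path / "emb.tsv"
    m.write_tsv(p)
    back = read_embedding_tsv(p)
    assert back.row_ids == m.row_ids and back.source == "fused"
    np.testing.assert_array_equal(back.vectors, m.vectors)
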