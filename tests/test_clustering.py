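"""Clustering back-ends and ARI/NMI agreement metrics."""

import itertools
import math

import numpy as np
import pytest

from golden.clustering import ClusteringResult, ari, cluster, nmi
from golden.embeddings import EmbeddingMatrix


def _blobs(k=2, n=10, spread=10.0, seed=0):
    rng = np.random.default_rng(seed)
    ids, rows, truth = [], [], {}
    for c in range(k):
        center = np.array([spread * c, spread * c])
        for i in range(n):
            rid = f"b{c}_{i}"
            ids.append(rid)
            rows.append(center + rng.standard_normal(2) * 0.3)
            truth[rid] = c
    return EmbeddingMatrix(ids, np.array(rows), "fused"), truth


# ---------------------------------------------------------------- metrics


def ari_pair_oracle(a: dict, b: dict) -> float:
    """Brute-force pair enumeration with the expected-index correction."""
    keys = sorted(a)
    n = len(keys)
    sum_ij = sum(1 for x, y in itertools.combinations(keys, 2)
                 if a[x] == a[y] and b[x] == b[y])
    sum_a = sum(1 for x, y in itertools.combinations(keys, 2) if a[x] == a[y])
    sum_b = sum(1 for x, y in itertools.combinations(keys, 2) if b[x] == b[y])
    total = math.comb(n, 2)
    expected = sum_a * sum_b / total
    maximum = 0.5 * (sum_a + sum_b)
    if maximum == expected:
        return 1.0
    return (sum_ij - expected) / (maximum - expected)


def nmi_entropy_oracle(a: dict, b: dict) -> float:
    """Direct contingency-entropy computation, arithmetic-mean normalised."""
    keys = sorted(a)
    n = len(keys)
    la, lb = [a[k] for k in keys], [b[k] for k in keys]

    def entropy(labels):
        h = 0.0
        for lab in set(labels):
            p = labels.count(lab) / n
            h -= p * math.log(p)
        return h

    ha, hb = entropy(la), entropy(lb)
    mi = 0.0
    for ca in set(la):
        for cb in set(lb):
            nij = sum(1 for x, y in zip(la, lb) if x == ca and y == cb)
            if nij:
                mi += (nij / n) * math.log(n * nij / (la.count(ca) * lb.count(cb)))
    denom = (ha + hb) / 2
    if denom == 0:
        return 1.0 if ha == hb == 0 else 0.0
    return mi / denom


def test_ari_nmi_identity_and_permutation_invariance():
    a = {f"i{k}": v for k, v in enumerate([0, 0, 1, 1, 2])}
    renamed = {k: {0: 7, 1: 3, 2: 0}[v] for k, v in a.items()}
    assert ari(a, a) == 1.0
    assert ari(a, renamed) == 1.0
    assert nmi(a, a) == 1.0
    assert nmi(a, renamed) == 1.0


def test_ari_four_point_example_matches_oracle():
    a = {f"i{k}": v for k, v in enumerate([0, 0, 1, 1])}
    b = {f"i{k}": v for k, v in enumerate([0, 1, 0, 1])}
    assert ari(a, b) == pytest.approx(ari_pair_oracle(a, b), abs=1e-12)
    assert nmi(a, b) == pytest.approx(nmi_entropy_oracle(a, b), abs=1e-12)


def test_metrics_match_oracles_on_random_label_pairs():
    rng = np.random.default_rng(12)
    for _ in range(20):
        n = int(rng.integers(6, 14))
        a = {f"i{k}": int(v) for k, v in enumerate(rng.integers(0, 3, n))}
        b = {f"i{k}": int(v) for k, v in enumerate(rng.integers(0, 4, n))}
        assert ari(a, b) == pytest.approx(ari_pair_oracle(a, b), abs=1e-12)
        assert nmi(a, b) == pytest.approx(nmi_entropy_oracle(a, b), abs=1e-12)


def test_constant_partition_nmi_zero():
    a = {f"i{k}": 0 for k in range(6)}
    b = {f"i{k}": v for k, v in enumerate([0, 1, 2, 0, 1, 2])}
    assert nmi(a, b) == 0.0


def test_metrics_symmetric():
    rng = np.random.default_rng(5)
    a = {f"i{k}": int(v) for k, v in enumerate(rng.integers(0, 3, 15))}
    b = {f"i{k}": int(v) for k, v in enumerate(rng.integers(0, 3, 15))}
    assert ari(a, b) == ari(b, a)
    assert nmi(a, b) == pytest.approx(nmi(b, a), abs=1e-12)


def test_random_shuffle_ari_near_zero():
    rng = np.random.default_rng(9)
    base = [0] * 10 + [1] * 10
    a = {f"i{k}": v for k, v in enumerate(base)}
    vals = []
    for _ in range(200):
        shuffled = list(base)
        rng.shuffle(shuffled)
        vals.append(ari(a, {f"i{k}": v for k, v in enumerate(shuffled)}))
    assert abs(np.mean(vals)) < 0.05


def test_metric_key_mismatch_rejected():
    with pytest.raises(ValueError, match="different ids"):
        ari({"a": 0}, {"b": 0})


# ---------------------------------------------------------------- back-ends


def test_kmeans_recovers_separated_blobs():
    emb, truth = _blobs()
    res = cluster(emb, "kmeans", k=2, seed=0)
    assert ari(res.labels, truth) == 1.0


@pytest.mark.parametrize("method", ["agglomerative", "spectral"])
def test_other_embedding_backends_recover_blobs(method):
    emb, truth = _blobs(seed=3)
    res = cluster(emb, method, k=2, seed=0)
    assert ari(res.labels, truth) == 1.0


def test_girvan_newman_first_split_is_the_two_cliques(two_clique_network):
    net, truth = two_clique_network
    res = cluster(net, "girvan_newman", k=2)
    assert ari(res.labels, truth) == 1.0


def test_louvain_on_graph(two_clique_network):
    net, truth = two_clique_network
    res = cluster(net, "louvain", seed=1)
    assert ari(res.labels, truth) == 1.0


def test_hdbscan_degenerate_input_all_noise():
    emb = EmbeddingMatrix([f"p{i}" for i in range(4)],
                          np.random.default_rng(0).standard_normal((4, 2)), "fused")
    res = cluster(emb, "hdbscan", min_cluster_size=5)
    assert set(res.labels.values()) == {-1}
    assert res.k_effective == 0


def test_hdbscan_finds_blobs_and_k_effective():
    emb, truth = _blobs(n=20, seed=4)
    res = cluster(emb, "hdbscan", min_cluster_size=5)
    non_noise = {k: v for k, v in res.labels.items() if v != -1}
    assert res.k_effective == 2
    assert ari({k: truth[k] for k in non_noise}, non_noise) == 1.0


def test_k_larger_than_n_rejected():
    emb, _ = _blobs(n=3)
    with pytest.raises(ValueError, match="exceeds"):
        cluster(emb, "kmeans", k=10)


def test_graph_method_on_embedding_rejected():
    emb, _ = _blobs()
    with pytest.raises(TypeError):
        cluster(emb, "louvain")


def test_embedding_method_on_graph_rejected(two_clique_network):
    net, _ = two_clique_network
    with pytest.raises(TypeError):
        cluster(net, "kmeans", k=2)


def test_cluster_deterministic_for_fixed_seed():
    emb, _ = _blobs(seed=8)
    r1 = cluster(emb, "kmeans", k=2, seed=5)
    r2 = cluster(emb, "kmeans", k=2, seed=5)
    assert r1.labels == r2.labels


def test_labels_tsv_round_trip(tmp_path):
    res = ClusteringResult({"a": 0, "b": 1, "c": -1}, "kmeans")
    path = tmp_path / "labels.tsv"
    res.write_tsv(path)
    assert path.read_text() == "a\t0\nb\t1\nc\t-1\n"
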