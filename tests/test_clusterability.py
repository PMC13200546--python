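"""Block-model generation, clustering-coefficient features, and the CDI."""

import math

import networkx as nx
import numpy as np
import pytest

from golden.clusterability import (
    CdiModel,
    CdiTrainingSet,
    SyntheticGraphSpec,
    build_training_set,
    cc_features,
    cdi_score,
    extended_features,
    generate_dcsbm,
    generate_sbm,
    label_graph,
    train_cdi,
)


def test_sbm_extreme_probabilities():
    a, labels = generate_sbm(SyntheticGraphSpec(n_nodes=10, p_intra=1.0, p_inter=1.0, seed=0))
    assert a.sum() == 10 * 9  # complete graph (symmetric adjacency counts both directions)
    a, labels = generate_sbm(SyntheticGraphSpec(n_nodes=10, p_intra=1.0, p_inter=0.0, seed=0))
    # two disjoint 5-cliques
    assert a[:5, :5].sum() == 5 * 4 and a[5:, 5:].sum() == 5 * 4
    assert a[:5, 5:].sum() == 0
    assert list(labels) == [0] * 5 + [1] * 5


def test_sbm_edge_count_within_3_sigma():
    spec = SyntheticGraphSpec(n_nodes=200, p_intra=0.3, p_inter=0.1, seed=42)
    a, _ = generate_sbm(spec)
    m = a.sum() / 2
    n_within = 2 * math.comb(100, 2)
    n_between = 100 * 100
    mean = 0.3 * n_within + 0.1 * n_between
    var = 0.3 * 0.7 * n_within + 0.1 * 0.9 * n_between
    assert abs(m - mean) < 3 * math.sqrt(var)


def test_sbm_symmetric_no_self_loops():
    a, _ = generate_sbm(SyntheticGraphSpec(n_nodes=50, p_intra=0.5, p_inter=0.2, seed=1))
    np.testing.assert_array_equal(a, a.T)
    assert np.all(np.diag(a) == 0)


def test_dcsbm_all_ones_weights_matches_sbm_density():
    spec = SyntheticGraphSpec(n_nodes=100, p_intra=0.4, p_inter=0.1)
    counts_sbm, counts_dc = [], []
    for seed in range(100):
        s = SyntheticGraphSpec(n_nodes=100, p_intra=0.4, p_inter=0.1, seed=seed)
        counts_sbm.append(generate_sbm(s)[0].sum())
        s_dc = SyntheticGraphSpec(n_nodes=100, p_intra=0.4, p_inter=0.1,
                                  degree_correction=tuple([1.0] * 100), seed=seed)
        counts_dc.append(generate_dcsbm(s_dc)[0].sum())
    # identical seeds, identical probability matrices -> identical draws
    assert counts_sbm == counts_dc


def test_dcsbm_powerlaw_weights_increase_degree_variance():
    rng = np.random.default_rng(0)
    theta = np.clip(rng.pareto(2.0, 200) + 0.5, 0.2, 3.0)
    theta = theta / theta.mean()
    var_dc, var_sbm = [], []
    for seed in range(10):
        dc, _ = generate_dcsbm(SyntheticGraphSpec(
            n_nodes=200, p_intra=0.3, p_inter=0.1, degree_correction=tuple(theta), seed=seed))
        sbm, _ = generate_sbm(SyntheticGraphSpec(n_nodes=200, p_intra=0.3, p_inter=0.1, seed=seed))
        var_dc.append(dc.sum(1).var())
        var_sbm.append(sbm.sum(1).var())
    assert np.mean(var_dc) > np.mean(var_sbm)


def test_dcsbm_zero_weight_node_isolated():
    theta = [1.0] * 20
    theta[3] = 0.0
    a, _ = generate_dcsbm(SyntheticGraphSpec(n_nodes=20, p_intra=0.9, p_inter=0.5,
                                             degree_correction=tuple(theta), seed=2))
    assert a[3].sum() == 0


def test_cc_features_triangle_and_star():
    k3 = np.ones((3, 3)) - np.eye(3)
    assert cc_features(k3) == (1.0, 0.0)
    star = np.zeros((5, 5))
    star[0, 1:] = star[1:, 0] = 1
    assert cc_features(star) == (0.0, 0.0)


def test_cc_features_square_plus_diagonal_matches_enumeration():
    # square 0-1-2-3 plus diagonal 0-2: by exhaustive triangle/wedge count,
    # nodes 0 and 2 (degree 3, 2 triangles of 3 wedges) have cc 2/3;
    # nodes 1 and 3 (degree 2, closed wedge) have cc 1
    g = nx.Graph([(0, 1), (1, 2), (2, 3), (3, 0), (0, 2)])
    mean, std = cc_features(g)
    vals = [2 / 3, 1.0, 2 / 3, 1.0]
    assert mean == pytest.approx(np.mean(vals), abs=1e-12)
    assert std == pytest.approx(np.std(vals), abs=1e-12)


def test_cc_features_agree_with_networkx_on_random_graph():
    g = nx.gnp_random_graph(40, 0.2, seed=5)
    mean, std = cc_features(g)
    vals = list(nx.clustering(g).values())
    assert mean == pytest.approx(np.mean(vals), abs=1e-12)
    assert std == pytest.approx(np.std(vals), abs=1e-12)


def test_extended_features_consistent_with_networkx():
    g = nx.gnp_random_graph(60, 0.15, seed=7)
    f = extended_features(g)
    assert f["density"] == pytest.approx(nx.density(g), abs=1e-12)
    assert f["transitivity"] == pytest.approx(nx.transitivity(g), abs=1e-12)
    assert f["assortativity"] == pytest.approx(
        nx.degree_assortativity_coefficient(g), abs=1e-9)
    assert f["lcc_fraction"] == max(len(c) for c in nx.connected_components(g)) / 60


def test_label_graph_disjoint_cliques_perfect():
    a, planted = generate_sbm(SyntheticGraphSpec(n_nodes=40, p_intra=1.0, p_inter=0.0, seed=0))
    ari_raw, lab = label_graph(a, planted)
    assert ari_raw == 1.0 and lab == 1


def test_label_graph_no_structure_low_ari():
    hits = 0
    for seed in range(10):
        a, planted = generate_sbm(SyntheticGraphSpec(n_nodes=100, p_intra=0.3,
                                                     p_inter=0.3, seed=seed))
        ari_raw, lab = label_graph(a, planted, seed=seed)
        hits += (abs(ari_raw) < 0.2 and lab == 0)
    assert hits >= 9


def test_label_graph_tau_zero_always_positive():
    a, planted = generate_sbm(SyntheticGraphSpec(n_nodes=50, p_intra=0.2, p_inter=0.2, seed=3))
    _, lab = label_graph(a, planted, tau=0.0)
    assert lab == 1


def test_training_set_invariants_and_design_table():
    ts = build_training_set(probability_grid=(0.2, 0.8), replicates=2, n_nodes=60, seed=0)
    assert ts.X.shape == (8, 2)
    assert set(ts.design.columns) >= {"p_intra", "p_inter", "replicate", "ari", "label"}
    np.testing.assert_array_equal(ts.y_bin, (ts.y_raw >= ts.tau).astype(int))


def test_train_cdi_separable_toy_all_models_perfect():
    rng = np.random.default_rng(1)
    X = np.vstack([rng.normal(0.0, 0.05, (40, 2)), rng.normal(1.0, 0.05, (40, 2))])
    y = np.array([0] * 40 + [1] * 40)
    ts = CdiTrainingSet(X, y.astype(float), y, 0.5, ["f1", "f2"],
                        design=None)
    model = train_cdi(ts, split_seed=0)
    assert (model.cv_metrics["accuracy"] == 1.0).all()


def test_train_cdi_degenerate_labels_rejected():
    X = np.zeros((10, 2))
    y = np.ones(10)
    ts = CdiTrainingSet(X, y, y.astype(int), 0.5, ["a", "b"], design=None)
    with pytest.raises(ValueError, match="degenerate"):
        train_cdi(ts)


def test_separation_property_clusterable_graphs_have_higher_cc(cdi_training_small):
    d = cdi_training_small.design
    pos, neg = d[d.label == 1], d[d.label == 0]
    assert pos.cc_mean.mean() > neg.cc_mean.mean()
    assert pos.cc_std.mean() > neg.cc_std.mean()
    # the contrast is sharper among assortative graphs (the regime the
    # clusterable/unclusterable coefficient-distribution contrast describes)
    assortative = d[d.p_intra > d.p_inter]
    assert (assortative[assortative.label == 1].cc_mean.mean()
            > assortative[assortative.label == 0].cc_mean.mean() + 0.05)


def test_cdi_score_in_unit_interval_and_discriminates(cdi_model_small):
    strong, _ = generate_sbm(SyntheticGraphSpec(n_nodes=120, p_intra=0.9, p_inter=0.05, seed=0))
    er, _ = generate_sbm(SyntheticGraphSpec(n_nodes=120, p_intra=0.2, p_inter=0.2, seed=0))
    s1, s2 = cdi_score(cdi_model_small, strong), cdi_score(cdi_model_small, er)
    assert 0.0 <= s2 <= s1 <= 1.0
    assert s1 > 0.9 and s2 < 0.5


def test_cdi_model_json_round_trip(tmp_path, cdi_model_small):
    path = tmp_path / "model.json"
    cdi_model_small.save(path)
    back = CdiModel.load(path)
    assert back.model_kind == cdi_model_small.model_kind
    g, _ = generate_sbm(SyntheticGraphSpec(n_nodes=60, p_intra=0.8, p_inter=0.1, seed=4))
    assert cdi_score(back, g) == cdi_score(cdi_model_small, g)


def test_tau_robustness_nearby_thresholds():
    accs = {}
    for tau in (0.65, 0.75):
        ts = build_training_set(replicates=3, n_nodes=100, tau=tau, seed=11)
        model = train_cdi(ts, split_seed=11)
        best = model.cv_metrics.set_index("model")
        accs[tau] = float(best.loc[model.model_kind, "accuracy"])
    assert abs(accs[0.65] - accs[0.75]) < 0.1
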