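"""Clusterability modelling: synthetic block-model graphs, clustering-
coefficient features, and the Connection Disparity Index (CDI).

The CDI is the calibrated probability, from a classifier trained on
synthetic two-block stochastic block models (SBMs), that a network contains
recoverable cluster structure.  Training sweeps the intra- and inter-block
edge probabilities over {0.1, ..., 1.0}; each graph is labelled clusterable
when spectral clustering recovers the planted partition with ARI >= tau
(default 0.7), and is summarised by the mean and standard deviation of its
local clustering-coefficient distribution.  Candidate classifiers are
compared on a held-out 25% split and the best by F1 is kept.

A degree-corrected variant (DC-SBM) and an extended feature set (density,
degree statistics, transitivity, assortativity, largest-component fraction)
support the broader CDI-beta score.
"""

from __future__ import annotations

import base64
import json
import pickle
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import networkx as nx
import pandas as pd
from sklearn.calibration import CalibratedClassifierCV
from sklearn.ensemble import GradientBoostingClassifier, RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import accuracy_score, f1_score, precision_score, recall_score
from sklearn.model_selection import train_test_split
from sklearn.neighbors import KNeighborsClassifier
from sklearn.neural_network import MLPClassifier
from sklearn.svm import SVC

from .clustering import spectral_adjacency
from sklearn.metrics import adjusted_rand_score

__all__ = [
    "SyntheticGraphSpec",
    "CdiTrainingSet",
    "CdiModel",
    "generate_sbm",
    "generate_dcsbm",
    "cc_features",
    "extended_features",
    "label_graph",
    "build_training_set",
    "train_cdi",
    "cdi_score",
    "PROBABILITY_GRID",
]

PROBABILITY_GRID = tuple(round(0.1 * i, 1) for i in range(1, 11))

MODEL_FACTORIES = {
    "logistic": lambda seed: LogisticRegression(max_iter=1000, random_state=seed),
    "svm": lambda seed: CalibratedClassifierCV(SVC(random_state=seed), ensemble=False),
    "random_forest": lambda seed: RandomForestClassifier(n_estimators=100, random_state=seed),
    "knn": lambda seed: KNeighborsClassifier(),
    "gradient_boosting": lambda seed: GradientBoostingClassifier(random_state=seed),
    "mlp": lambda seed: MLPClassifier(hidden_layer_sizes=(32, 16), max_iter=2000, random_state=seed),
}

DEFAULT_MODEL_KINDS = ("logistic", "svm", "knn", "random_forest")


@dataclass(frozen=True)
class SyntheticGraphSpec:
    """Parameters of a planted-partition graph draw."""

    n_nodes: int = 200
    block_proportions: tuple[float, ...] = (0.5, 0.5)
    p_intra: float = 0.3
    p_inter: float = 0.1
    degree_correction: tuple[float, ...] | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 <= self.p_intra <= 1 and 0 <= self.p_inter <= 1):
            raise ValueError("edge probabilities must lie in [0, 1]")
        props = np.asarray(self.block_proportions, dtype=float)
        if np.any(props <= 0) or abs(props.sum() - 1.0) > 1e-9:
            raise ValueError("block proportions must be positive and sum to 1")
        if self.degree_correction is not None and len(self.degree_correction) != self.n_nodes:
            raise ValueError("degree_correction must supply one weight per node")

    def block_sizes(self) -> list[int]:
        props = np.asarray(self.block_proportions, dtype=float)
        sizes = np.floor(props * self.n_nodes).astype(int)
        sizes[0] += self.n_nodes - sizes.sum()
        return sizes.tolist()


def _planted_labels(spec: SyntheticGraphSpec) -> np.ndarray:
    return np.repeat(np.arange(len(spec.block_proportions)), spec.block_sizes())


def generate_sbm(spec: SyntheticGraphSpec) -> tuple[np.ndarray, np.ndarray]:
    """Draw a stochastic block model as a dense symmetric 0/1 adjacency.

    Each within-block pair is an edge with probability p_intra, each
    between-block pair with p_inter, independently.  Returns (adjacency,
    planted block labels).
    """
    labels = _planted_labels(spec)
    same = labels[:, None] == labels[None, :]
    P = np.where(same, spec.p_intra, spec.p_inter)
    return _draw(P, spec), labels


def generate_dcsbm(spec: SyntheticGraphSpec) -> tuple[np.ndarray, np.ndarray]:
    """Degree-corrected SBM: edge probabilities scaled by the product of
    endpoint degree weights, clipped to [0, 1].  With all-ones weights this
    is distributionally identical to :func:`generate_sbm`."""
    labels = _planted_labels(spec)
    same = labels[:, None] == labels[None, :]
    P = np.where(same, spec.p_intra, spec.p_inter)
    if spec.degree_correction is not None:
        theta = np.asarray(spec.degree_correction, dtype=float)
        P = np.clip(P * theta[:, None] * theta[None, :], 0.0, 1.0)
    return _draw(P, spec), labels


def _draw(P: np.ndarray, spec: SyntheticGraphSpec) -> np.ndarray:
    n = spec.n_nodes
    rng = np.random.default_rng(spec.seed)
    u = rng.random((n, n))
    upper = np.triu(u < P, k=1)
    return (upper | upper.T).astype(np.float64)


def _as_adjacency(graph) -> np.ndarray:
    if isinstance(graph, np.ndarray):
        return graph
    if isinstance(graph, nx.Graph):
        return nx.to_numpy_array(graph, weight=None)
    adj = getattr(graph, "adjacency", None)
    if callable(adj):  # PagNetwork
        return graph.adjacency(weighted=False)
    raise TypeError(f"cannot interpret {type(graph).__name__} as a graph")


def cc_features(graph) -> tuple[float, float]:
    """Mean and standard deviation of the local clustering coefficients.

    The local coefficient of a node is triangles/wedges (0 when degree < 2).
    Accepts an adjacency matrix, a networkx graph, or a PagNetwork (edges
    treated as unweighted).
    """
    a = _as_adjacency(graph)
    if a.shape[0] == 0:
        raise ValueError("graph has no nodes")
    a = (a != 0).astype(np.float64)
    deg = a.sum(axis=1)
    triangles = np.einsum("ij,jk,ki->i", a, a, a) / 2.0
    wedges = deg * (deg - 1) / 2.0
    cc = np.divide(triangles, wedges, out=np.zeros_like(wedges), where=wedges > 0)
    return float(cc.mean()), float(cc.std())


def extended_features(graph) -> dict[str, float]:
    """Feature superset used for CDI-beta: clustering-coefficient mean/std,
    density, degree mean/std/skew, transitivity, degree assortativity, and
    largest-connected-component fraction."""
    a = (_as_adjacency(graph) != 0).astype(np.float64)
    n = a.shape[0]
    deg = a.sum(axis=1)
    cc_mean, cc_std = cc_features(a)
    m = deg.sum() / 2.0
    density = 2.0 * m / (n * (n - 1)) if n > 1 else 0.0
    dstd = float(deg.std())
    skew = float(np.mean(((deg - deg.mean()) / dstd) ** 3)) if dstd > 0 else 0.0
    tri_total = float(np.einsum("ij,jk,ki->", a, a, a)) / 6.0
    wedge_total = float((deg * (deg - 1) / 2.0).sum())
    transitivity = 3.0 * tri_total / wedge_total if wedge_total > 0 else 0.0
    g = nx.from_numpy_array(a)
    try:
        assort = float(nx.degree_assortativity_coefficient(g))
        if not np.isfinite(assort):
            assort = 0.0
    except (ZeroDivisionError, ValueError):
        assort = 0.0
    lcc = max((len(c) for c in nx.connected_components(g)), default=0) / max(n, 1)
    return {
        "cc_mean": cc_mean,
        "cc_std": cc_std,
        "density": density,
        "degree_mean": float(deg.mean()),
        "degree_std": dstd,
        "degree_skew": skew,
        "transitivity": transitivity,
        "assortativity": assort,
        "lcc_fraction": float(lcc),
    }


def label_graph(graph, planted_labels: np.ndarray, tau: float = 0.7, seed: int = 0) -> tuple[float, int]:
    """Cluster with spectral clustering (k = number of planted blocks) and
    binarize: 1 iff ARI against the planted partition >= tau.

    The ``general`` spectral mode is used so that both assortative and
    disassortative planted structure count as recoverable."""
    a = _as_adjacency(graph)
    k = len(np.unique(planted_labels))
    pred = spectral_adjacency(a, k, seed=seed, mode="general")
    # ARI clipped to [0, 1]: below-chance agreement is "no recovery"
    ari_raw = max(0.0, float(adjusted_rand_score(planted_labels, pred)))
    return ari_raw, int(ari_raw >= tau)


@dataclass
class CdiTrainingSet:
    X: np.ndarray
    y_raw: np.ndarray
    y_bin: np.ndarray
    tau: float
    feature_names: list[str]
    design: pd.DataFrame

    def __post_init__(self) -> None:
        if len(self.X) != len(self.y_raw) or len(self.X) != len(self.y_bin):
            raise ValueError("feature/label length mismatch")
        expect = (self.y_raw >= self.tau).astype(int)
        if not np.array_equal(expect, self.y_bin):
            raise ValueError("y_bin inconsistent with y_raw and tau")


def build_training_set(
    probability_grid=PROBABILITY_GRID,
    replicates: int = 10,
    n_nodes: int = 200,
    block_proportions: tuple[float, ...] = (0.5, 0.5),
    tau: float = 0.7,
    seed: int = 0,
    extended: bool = False,
    degree_corrected: bool = False,
) -> CdiTrainingSet:
    """Exhaustive (p_intra, p_inter) sweep with replicate graphs per cell.

    Each graph contributes a feature vector (clustering-coefficient mean and
    std, or the extended set), its spectral-recovery ARI, and the binarized
    clusterability label.  The full design table is recorded.
    """
    rows = []
    feats = []
    base = np.random.default_rng(seed)
    for p_intra in probability_grid:
        for p_inter in probability_grid:
            for rep in range(replicates):
                gseed = int(base.integers(0, 2**31 - 1))
                theta = None
                if degree_corrected:
                    theta = tuple(np.clip(base.lognormal(0.0, 0.5, n_nodes), 0.2, 5.0))
                spec = SyntheticGraphSpec(
                    n_nodes=n_nodes, block_proportions=block_proportions,
                    p_intra=p_intra, p_inter=p_inter,
                    degree_correction=theta, seed=gseed,
                )
                a, planted = generate_dcsbm(spec) if degree_corrected else generate_sbm(spec)
                ari_raw, lab = label_graph(a, planted, tau=tau, seed=gseed % 10000)
                if extended:
                    f = extended_features(a)
                else:
                    mean, std = cc_features(a)
                    f = {"cc_mean": mean, "cc_std": std}
                feats.append(f)
                rows.append({"p_intra": p_intra, "p_inter": p_inter, "replicate": rep,
                             **f, "ari": ari_raw, "label": lab})
    design = pd.DataFrame(rows)
    names = list(feats[0])
    X = design[names].to_numpy()
    y_raw = design["ari"].to_numpy(dtype=float).clip(0.0, 1.0)
    y_bin = (y_raw >= tau).astype(int)
    return CdiTrainingSet(X, y_raw, y_bin, tau, names, design)


@dataclass
class CdiModel:
    """A fitted clusterability classifier with its held-out metrics."""

    model_kind: str
    estimator: object
    tau: float
    feature_names: list[str]
    cv_metrics: pd.DataFrame = field(repr=False, default=None)

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        return self.estimator.predict_proba(np.asarray(X))[:, 1]

    def save(self, path: str | Path) -> None:
        blob = base64.b64encode(zlib.compress(pickle.dumps(self.estimator))).decode("ascii")
        payload = {
            "format_version": 1,
            "model_kind": self.model_kind,
            "tau": self.tau,
            "feature_names": self.feature_names,
            "cv_metrics": self.cv_metrics.to_dict(orient="records") if self.cv_metrics is not None else None,
            "estimator_blob": blob,
        }
        Path(path).write_text(json.dumps(payload))

    @classmethod
    def load(cls, path: str | Path) -> "CdiModel":
        payload = json.loads(Path(path).read_text())
        if payload.get("format_version") != 1:
            raise ValueError("unsupported CDI model format version")
        est = pickle.loads(zlib.decompress(base64.b64decode(payload["estimator_blob"])))
        metrics = pd.DataFrame(payload["cv_metrics"]) if payload["cv_metrics"] else None
        return cls(payload["model_kind"], est, payload["tau"], payload["feature_names"], metrics)


def train_cdi(
    ts: CdiTrainingSet,
    model_kinds=DEFAULT_MODEL_KINDS,
    split_seed: int = 0,
) -> CdiModel:
    """Fit the candidate classifiers on a 75/25 split and keep the best by
    held-out F1.  Raises when the labels are degenerate (single class)."""
    if len(np.unique(ts.y_bin)) < 2:
        raise ValueError("degenerate labels: training set contains a single class")
    X_tr, X_te, y_tr, y_te = train_test_split(
        ts.X, ts.y_bin, test_size=0.25, random_state=split_seed, stratify=ts.y_bin
    )
    rows = []
    fitted = {}
    for kind in model_kinds:
        if kind not in MODEL_FACTORIES:
            raise ValueError(f"unknown model kind {kind!r}")
        est = MODEL_FACTORIES[kind](split_seed)
        est.fit(X_tr, y_tr)
        pred = est.predict(X_te)
        rows.append({
            "model": kind,
            "accuracy": accuracy_score(y_te, pred),
            "precision": precision_score(y_te, pred, zero_division=0),
            "recall": recall_score(y_te, pred, zero_division=0),
            "f1": f1_score(y_te, pred, zero_division=0),
        })
        fitted[kind] = est
    table = pd.DataFrame(rows)
    best = table.loc[table["f1"].idxmax(), "model"]
    return CdiModel(best, fitted[best], ts.tau, ts.feature_names, table)


def cdi_score(model: CdiModel, graph) -> float:
    """Calibrated probability that ``graph`` has recoverable cluster
    structure, from the graph's clustering-coefficient features."""
    if len(model.feature_names) == 2:
        mean, std = cc_features(graph)
        feats = [mean, std]
    else:
        f = extended_features(graph)
        feats = [f[name] for name in model.feature_names]
    return float(model.predict_proba(np.asarray(feats)[None, :])[0])
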