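"""Consensus clustering and CDF/delta-CDF selection of the cluster count.

For each candidate k the chosen clusterer is run on many random subsamples;
the consensus matrix entry (i, j) is the fraction of co-sampled runs in
which i and j were co-clustered.  The empirical CDF of the off-diagonal
consensus values summarises stability: its area A(k) grows as k increases,
and the relative change delta(k) = (A(k) - A(k-1)) / A(k-1) (with
delta(k_min) = A(k_min)) measures the structural gain of allowing one more
cluster.

Because A(k) equals one minus the mean consensus value, it keeps growing
whenever a partitioning clusterer (k-means, Ward) splits a genuine cluster
in half -- stably or not -- so the delta curve alone does not flatten at
the true cluster count on clean data.  Selection therefore uses the
crispness of the consensus distribution directly: the ambiguity fraction
(proportion of off-diagonal consensus values strictly between 0.1 and 0.9,
the PAC statistic of Senbabaoglu et al.).  A candidate k is *stable* when
its ambiguity is at most the stability tolerance; the selected k is the
largest stable candidate (the finest reproducible structure), falling back
to the smallest candidate when nothing is stable.  The CDF/delta-CDF curves
are still computed and reported for diagnostics.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from sklearn.cluster import AgglomerativeClustering, KMeans

from .embeddings import EmbeddingMatrix

__all__ = [
    "ConsensusProfile",
    "consensus_matrix",
    "consensus_profile",
    "select_k",
    "cdf_area",
    "ambiguity",
]

logger = logging.getLogger(__name__)


def _default_clusterer(X: np.ndarray, k: int, seed: int) -> np.ndarray:
    return KMeans(n_clusters=k, n_init=10, random_state=seed).fit_predict(X)


def agglomerative_clusterer(X: np.ndarray, k: int, seed: int) -> np.ndarray:
    return AgglomerativeClustering(n_clusters=k).fit_predict(X)


@dataclass
class ConsensusProfile:
    k_range: list[int]
    consensus: dict[int, np.ndarray]
    cdf_area: dict[int, float]
    delta_area: dict[int, float]
    selected_k: int
    meta: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "k_range": self.k_range,
            "cdf_area": {str(k): v for k, v in self.cdf_area.items()},
            "delta_area": {str(k): v for k, v in self.delta_area.items()},
            "selected_k": self.selected_k,
            "meta": self.meta,
        }


def consensus_matrix(
    data: EmbeddingMatrix | np.ndarray,
    k: int,
    n_resamples: int = 100,
    subsample_fraction: float = 0.8,
    clusterer: Callable[[np.ndarray, int, int], np.ndarray] | None = None,
    seed: int = 0,
) -> np.ndarray:
    """Co-assignment frequency matrix over resampled clustering runs.

    Entry (i, j) = (#runs where i,j co-clustered) / (#runs where both were
    sampled).  Pairs never co-sampled are imputed as 0 (count logged).
    """
    if n_resamples < 2:
        raise ValueError("n_resamples must be >= 2")
    if not 0 < subsample_fraction <= 1:
        raise ValueError("subsample_fraction must lie in (0, 1]")
    X = data.vectors if isinstance(data, EmbeddingMatrix) else np.asarray(data)
    clusterer = clusterer or _default_clusterer
    n = X.shape[0]
    m = max(k, int(round(subsample_fraction * n)))
    rng = np.random.default_rng(seed)
    co = np.zeros((n, n))
    together = np.zeros((n, n))
    for _r in range(n_resamples):
        idx = rng.choice(n, size=m, replace=False) if m < n else np.arange(n)
        # the clusterer is deterministic (fixed seed); all run-to-run
        # variation comes from the resampling, per the method's design
        labels = np.asarray(clusterer(X[idx], k, seed))
        together[np.ix_(idx, idx)] += 1.0
        same = labels[:, None] == labels[None, :]
        co[np.ix_(idx, idx)] += same
    never = (together == 0) & ~np.eye(n, dtype=bool)
    if never.any():
        logger.info("consensus: %d pairs never co-sampled, imputed 0", int(never.sum() // 2))
    with np.errstate(invalid="ignore", divide="ignore"):
        cons = np.where(together > 0, co / np.maximum(together, 1), 0.0)
    np.fill_diagonal(cons, 1.0)
    return cons


def cdf_area(consensus: np.ndarray) -> float:
    """Area under the empirical CDF of the off-diagonal consensus values.

    Equals 1 - mean(consensus values); in [0, 1].
    """
    n = consensus.shape[0]
    vals = consensus[np.triu_indices(n, k=1)]
    if vals.size == 0:
        return 0.0
    return float(1.0 - vals.mean())


def consensus_profile(
    data: EmbeddingMatrix | np.ndarray,
    k_range: Sequence[int],
    n_resamples: int = 100,
    subsample_fraction: float = 0.8,
    clusterer: Callable[[np.ndarray, int, int], np.ndarray] | None = None,
    stability_tolerance: float = 0.05,
    seed: int = 0,
) -> ConsensusProfile:
    """Consensus matrices, CDF areas, and the selected cluster count over
    a range of candidate k."""
    ks = sorted(set(int(k) for k in k_range))
    if len(ks) < 2:
        raise ValueError("need at least two candidate k")
    cons = {}
    areas = {}
    for k in ks:
        cons[k] = consensus_matrix(data, k, n_resamples, subsample_fraction, clusterer, seed)
        areas[k] = cdf_area(cons[k])
    deltas = _delta_areas(ks, areas)
    sel = select_k(ks, cons, stability_tolerance)
    return ConsensusProfile(ks, cons, areas, deltas, sel,
                            meta={"n_resamples": n_resamples,
                                  "subsample_fraction": subsample_fraction,
                                  "stability_tolerance": stability_tolerance,
                                  "seed": seed})


def _delta_areas(ks: list[int], areas: dict[int, float]) -> dict[int, float]:
    deltas: dict[int, float] = {}
    for prev, k in zip([None] + ks[:-1], ks):
        if prev is None:
            deltas[k] = areas[k]
        else:
            denom = max(areas[prev], 1e-12)
            deltas[k] = (areas[k] - areas[prev]) / denom
    return deltas


def ambiguity(consensus: np.ndarray, lo: float = 0.1, hi: float = 0.9) -> float:
    """Fraction of off-diagonal consensus values strictly between lo and hi.

    Zero for a perfectly reproducible partition (all values 0 or 1)."""
    n = consensus.shape[0]
    vals = consensus[np.triu_indices(n, k=1)]
    if vals.size == 0:
        return 0.0
    return float(np.mean((vals > lo) & (vals < hi)))


def select_k(
    ks: Sequence[int],
    consensus_by_k: dict[int, np.ndarray],
    stability_tolerance: float = 0.05,
) -> int:
    """Select the largest candidate k whose consensus matrix is crisp
    (ambiguity fraction <= stability tolerance); when no candidate is
    stable there is no structure beyond the floor and the smallest k is
    returned."""
    ks = sorted(ks)
    stable = [k for k in ks if ambiguity(consensus_by_k[k]) <= stability_tolerance]
    return max(stable) if stable else min(ks)
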