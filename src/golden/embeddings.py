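"""Graph and text embeddings for gene-set networks.

Two parallel representations of the same PAGs:

* ``embed_graph`` — node2vec-style biased second-order random walks on the
  weighted overlap network, fed to a skip-gram model with negative sampling
  (small batched numpy trainer).  Isolated nodes receive zero vectors.
* ``encode_descriptions`` — a pluggable text-encoder port.  The default
  offline encoder hashes token counts into a fixed number of buckets and
  applies a fixed-seed Gaussian random projection, so all quantitative
  behaviour is reproducible without network access.  ``pca_align`` projects
  semantic vectors down to the graph dimension before fusion.
"""

from __future__ import annotations

import hashlib
import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Protocol, Sequence

import numpy as np
from scipy.special import expit
from sklearn.decomposition import PCA

from .network import PagNetwork

__all__ = [
    "EmbeddingMatrix",
    "WalkConfig",
    "embed_graph",
    "generate_walks",
    "TextEncoder",
    "HashingEncoder",
    "encode_descriptions",
    "pca_align",
    "l2_normalize",
    "read_embedding_tsv",
]

logger = logging.getLogger(__name__)


@dataclass
class EmbeddingMatrix:
    """Row-indexed dense vectors tagged by provenance (graph/semantic/fused)."""

    row_ids: list[str]
    vectors: np.ndarray  # shape (len(row_ids), dim)
    source: str  # 'graph' | 'semantic' | 'fused'
    l2_normalized: bool = False
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.vectors = np.asarray(self.vectors, dtype=np.float64)
        if self.vectors.ndim != 2 or self.vectors.shape[0] != len(self.row_ids):
            raise ValueError("vectors must be 2-d with one row per id")
        if len(set(self.row_ids)) != len(self.row_ids):
            raise ValueError("duplicate row ids")
        if not np.all(np.isfinite(self.vectors)):
            raise ValueError("non-finite values in embedding matrix")
        if self.l2_normalized:
            norms = np.linalg.norm(self.vectors, axis=1)
            nz = norms > 0
            if not np.allclose(norms[nz], 1.0, atol=1e-9):
                raise ValueError("l2_normalized flag set but rows are not unit norm")

    @property
    def dim(self) -> int:
        return self.vectors.shape[1]

    def __len__(self) -> int:
        return len(self.row_ids)

    def row(self, rid: str) -> np.ndarray:
        return self.vectors[self.row_ids.index(rid)]

    def subset(self, ids: Sequence[str]) -> "EmbeddingMatrix":
        index = {r: k for k, r in enumerate(self.row_ids)}
        missing = [i for i in ids if i not in index]
        if missing:
            raise KeyError(f"ids not in embedding matrix: {missing[:5]}")
        rows = np.array([index[i] for i in ids])
        return EmbeddingMatrix(list(ids), self.vectors[rows].copy(), self.source,
                               self.l2_normalized, dict(self.meta))

    def write_tsv(self, path: str | Path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            fh.write(f"#source\t{self.source}\n")
            for rid, vec in zip(self.row_ids, self.vectors):
                fh.write(rid + "\t" + "\t".join(f"{v:.17g}" for v in vec) + "\n")


def read_embedding_tsv(path: str | Path) -> EmbeddingMatrix:
    ids: list[str] = []
    rows: list[list[float]] = []
    source = "graph"
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if parts[0] == "#source":
                source = parts[1]
                continue
            ids.append(parts[0])
            rows.append([float(v) for v in parts[1:]])
    return EmbeddingMatrix(ids, np.array(rows), source)


def l2_normalize(m: EmbeddingMatrix) -> EmbeddingMatrix:
    """Scale every nonzero row to unit Euclidean norm; zero rows stay zero."""
    v = _l2(m.vectors)
    return EmbeddingMatrix(list(m.row_ids), v, m.source, True, dict(m.meta))


def _l2(x: np.ndarray) -> np.ndarray:
    norms = np.linalg.norm(x, axis=1, keepdims=True)
    norms[norms == 0] = 1.0
    return x / norms


# ---------------------------------------------------------------------------
# Graph embeddings: biased walks + skip-gram with negative sampling
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class WalkConfig:
    """Hyperparameters for the biased second-order random walks and the
    skip-gram trainer.

    ``return_p`` and ``inout_q`` are the node2vec bias parameters: the
    unnormalised preference for stepping back to the previous node is 1/p,
    for staying in its neighbourhood 1, and for moving away 1/q.  Transition
    preferences are further multiplied by edge weight.
    """

    dim: int = 256
    walk_length: int = 80
    walks_per_node: int = 10
    window: int = 10
    negative_samples: int = 5
    return_p: float = 1.0
    inout_q: float = 0.25
    epochs: int = 5
    learning_rate: float = 0.025
    weighted: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("dim", "walk_length", "walks_per_node", "window",
                     "negative_samples", "epochs"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.return_p <= 0 or self.inout_q <= 0:
            raise ValueError("return_p and inout_q must be > 0")


def generate_walks(net: PagNetwork, cfg: WalkConfig) -> list[list[int]]:
    """Biased second-order random walks; node indices refer to net.node_ids.

    Each walk is seeded from (cfg.seed, start-node index, walk index), so the
    walk set is reproducible and independent of iteration order.  Isolated
    nodes produce no walks.
    """
    n = net.n_nodes
    index = {v: k for k, v in enumerate(net.node_ids)}
    nbrs: list[list[int]] = [[] for _ in range(n)]
    wts: list[list[float]] = [[] for _ in range(n)]
    for e in net.edges:
        i, j = index[e.i], index[e.j]
        w = e.weight if cfg.weighted else 1.0
        if w <= 0:
            continue
        nbrs[i].append(j)
        wts[i].append(w)
        nbrs[j].append(i)
        wts[j].append(w)
    nbr_sets = [set(x) for x in nbrs]
    nbrs_a = [np.array(x, dtype=np.int64) for x in nbrs]
    wts_a = [np.array(x, dtype=np.float64) for x in wts]

    walks: list[list[int]] = []
    for start in range(n):
        if len(nbrs[start]) == 0:
            continue
        for wi in range(cfg.walks_per_node):
            rng = np.random.default_rng([cfg.seed, start, wi])
            walk = [start]
            prev = -1
            cur = start
            while len(walk) < cfg.walk_length:
                cand = nbrs_a[cur]
                if cand.size == 0:
                    break
                probs = wts_a[cur].copy()
                if prev >= 0:
                    bias = np.empty(cand.size)
                    prev_nbrs = nbr_sets[prev]
                    for t, x in enumerate(cand):
                        if x == prev:
                            bias[t] = 1.0 / cfg.return_p
                        elif x in prev_nbrs:
                            bias[t] = 1.0
                        else:
                            bias[t] = 1.0 / cfg.inout_q
                    probs = probs * bias
                probs /= probs.sum()
                nxt = int(cand[rng.choice(cand.size, p=probs)])
                walk.append(nxt)
                prev, cur = cur, nxt
            walks.append(walk)
    return walks


def _sgns_train(
    walks: list[list[int]],
    n_nodes: int,
    cfg: WalkConfig,
) -> np.ndarray:
    """Skip-gram with negative sampling on integer-coded walks.

    Mini-batched SGD in numpy: per epoch, all (center, context) pairs within
    the window are shuffled and processed in batches with scatter-add
    updates; negatives are drawn from the unigram^0.75 distribution.
    Deterministic for a fixed config.
    """
    rng = np.random.default_rng([cfg.seed, 0xC0FFEE])
    centers_l: list[np.ndarray] = []
    contexts_l: list[np.ndarray] = []
    for walk in walks:
        arr = np.asarray(walk, dtype=np.int64)
        L = arr.size
        for off in range(1, cfg.window + 1):
            if L <= off:
                break
            centers_l.append(arr[:-off])
            contexts_l.append(arr[off:])
            centers_l.append(arr[off:])
            contexts_l.append(arr[:-off])
    if not centers_l:
        return np.zeros((n_nodes, cfg.dim))
    centers = np.concatenate(centers_l)
    contexts = np.concatenate(contexts_l)

    counts = np.bincount(centers, minlength=n_nodes).astype(np.float64)
    noise = counts**0.75
    noise /= noise.sum()

    W = (rng.random((n_nodes, cfg.dim)) - 0.5) / cfg.dim
    C = np.zeros((n_nodes, cfg.dim))

    n_pairs = centers.size
    # keep per-node update accumulation within a batch bounded, so the
    # scatter-add SGD stays stable even on tiny vocabularies
    batch = int(np.clip(n_nodes * 4, 64, 4096))
    total_steps = cfg.epochs * ((n_pairs + batch - 1) // batch)
    step = 0
    for _epoch in range(cfg.epochs):
        order = rng.permutation(n_pairs)
        for s in range(0, n_pairs, batch):
            idx = order[s : s + batch]
            lr = cfg.learning_rate * max(1e-4, 1.0 - step / max(1, total_steps))
            step += 1
            c = centers[idx]
            pos = contexts[idx]
            neg = rng.choice(n_nodes, size=(idx.size, cfg.negative_samples), p=noise)

            wc = W[c]  # (b, d)
            cp = C[pos]  # (b, d)
            cn = C[neg]  # (b, k, d)

            pos_score = expit(np.einsum("bd,bd->b", wc, cp))
            neg_score = expit(np.einsum("bd,bkd->bk", wc, cn))

            g_pos = (pos_score - 1.0)[:, None]  # (b, 1)
            g_neg = neg_score[:, :, None]  # (b, k, 1)

            grad_w = g_pos * cp + np.einsum("bkd,bk->bd", cn, neg_score)
            np.add.at(W, c, -lr * grad_w)
            np.add.at(C, pos, -lr * (g_pos * wc))
            np.add.at(C, neg.ravel(), -lr * (g_neg * wc[:, None, :]).reshape(-1, cfg.dim))
    return W


def embed_graph(net: PagNetwork, cfg: WalkConfig | None = None) -> EmbeddingMatrix:
    """Embed network nodes with biased random walks + skip-gram.

    Rows are L2-normalised; isolated nodes (degree zero) receive zero
    vectors.  Deterministic for a fixed (network, config) pair.
    """
    if net.n_nodes == 0:
        raise ValueError("network has no nodes")
    cfg = cfg or WalkConfig()
    walks = generate_walks(net, cfg)
    W = _sgns_train(walks, net.n_nodes, cfg)
    deg = net.degrees()
    for k, node in enumerate(net.node_ids):
        if deg[node] == 0:
            W[k] = 0.0
    return EmbeddingMatrix(list(net.node_ids), _l2(W), "graph", True,
                           meta={"walk_config": cfg.__dict__.copy()})


# ---------------------------------------------------------------------------
# Semantic embeddings
# ---------------------------------------------------------------------------


class TextEncoder(Protocol):
    """Port for description encoders (remote APIs or offline models)."""

    dim: int

    def encode(self, texts: Sequence[str]) -> np.ndarray: ...


_TOKEN_RE = re.compile(r"[a-z0-9]+")


def tokenize(text: str) -> list[str]:
    """Lowercase and split on non-alphanumerics (shared with ROUGE)."""
    return _TOKEN_RE.findall(text.lower())


class HashingEncoder:
    """Deterministic offline encoder: hashed token counts followed by a
    fixed-seed Gaussian random projection to ``dim``.

    Empty text maps to the zero vector.  Not a language model -- similarity
    reflects token overlap only, which is exactly what the synthetic
    description fixtures exercise.
    """

    def __init__(self, dim: int = 512, n_buckets: int = 4096, seed: int = 0) -> None:
        self.dim = dim
        self.n_buckets = n_buckets
        rng = np.random.default_rng([seed, 0x5EED])
        self._proj = rng.standard_normal((n_buckets, dim)) / np.sqrt(dim)

    def _bucket(self, token: str) -> int:
        h = hashlib.blake2b(token.encode("utf-8"), digest_size=8).digest()
        return int.from_bytes(h, "little") % self.n_buckets

    def counts(self, text: str) -> np.ndarray:
        c = np.zeros(self.n_buckets)
        for tok in tokenize(text):
            c[self._bucket(tok)] += 1.0
        return c

    def encode(self, texts: Sequence[str]) -> np.ndarray:
        counts = np.stack([self.counts(t) for t in texts]) if texts else np.zeros((0, self.n_buckets))
        return counts @ self._proj


def encode_descriptions(
    texts: Mapping[str, str], encoder: TextEncoder | None = None
) -> EmbeddingMatrix:
    """Encode id->text into a semantic EmbeddingMatrix (one row per id)."""
    encoder = encoder or HashingEncoder()
    ids = list(texts)
    try:
        vectors = np.asarray(encoder.encode([texts[i] for i in ids]), dtype=np.float64)
    except Exception as exc:  # re-raise with id context
        raise RuntimeError(f"text encoder failed on batch of {len(ids)} texts "
                           f"(first id: {ids[0] if ids else None})") from exc
    return EmbeddingMatrix(ids, vectors, "semantic")


def pca_align(
    sem: EmbeddingMatrix,
    target_dim: int,
    variance_goal: float = 0.95,
    normalize: bool = True,
) -> EmbeddingMatrix:
    """Project semantic vectors to ``target_dim`` principal components so
    they match the graph embedding dimension, then L2-normalise.

    The retained-variance ratio is stored in ``meta['retained_variance']``;
    a warning is logged when it falls short of ``variance_goal``.  The
    dimension match is mandatory (the blend formula requires it) even when
    the variance goal cannot be met.
    """
    n, d = sem.vectors.shape
    if target_dim > min(n - 1, d):
        raise ValueError(
            f"target_dim={target_dim} exceeds min(n_rows-1, dim)={min(n - 1, d)}"
        )
    pca = PCA(n_components=target_dim, svd_solver="full")
    proj = pca.fit_transform(sem.vectors)
    retained = float(np.sum(pca.explained_variance_ratio_))
    if retained < variance_goal:
        logger.warning(
            "PCA to %d dims retains %.3f of variance (< %.2f goal)",
            target_dim, retained, variance_goal,
        )
    out = _l2(proj) if normalize else proj
    return EmbeddingMatrix(list(sem.row_ids), out, "semantic", normalize,
                           meta={**sem.meta, "retained_variance": retained})
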