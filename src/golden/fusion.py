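"""Early fusion of graph and semantic embeddings.

The fused representation of PAG i is the convex blend
``D_f,i = (1 - alpha) * D_g,i + alpha * D_s,i`` with mixing weight
alpha in [0, 1]: alpha = 0 keeps only the network signal, alpha = 1 only the
description signal.  A concatenation mode ``[sqrt(1-alpha)*D_g,
sqrt(alpha)*D_s]`` reproduces the same alpha-weighted inner-product
structure without requiring equal dimensions.  ``grid_search_alpha`` tunes
alpha by maximising mean ARI over labelled validation groups.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .embeddings import EmbeddingMatrix

__all__ = ["FusionConfig", "fuse", "grid_search_alpha"]

DEFAULT_ALPHA_GRID = tuple(round(0.1 * i, 1) for i in range(11))


@dataclass
class FusionConfig:
    alpha: float = 0.8
    mode: str = "blend"  # 'blend' | 'concat'
    alpha_grid: tuple[float, ...] = DEFAULT_ALPHA_GRID
    normalize_after: bool = False

    def __post_init__(self) -> None:
        if not 0.0 <= self.alpha <= 1.0:
            raise ValueError("alpha must lie in [0, 1]")
        if self.mode not in ("blend", "concat"):
            raise ValueError(f"unknown fusion mode {self.mode!r}")
        grid = sorted(set(float(a) for a in self.alpha_grid))
        if any(a < 0 or a > 1 for a in grid):
            raise ValueError("alpha_grid values must lie in [0, 1]")
        self.alpha_grid = tuple(grid)


def _check_aligned(d_g: EmbeddingMatrix, d_s: EmbeddingMatrix) -> None:
    if d_g.row_ids != d_s.row_ids:
        for a, b in zip(d_g.row_ids, d_s.row_ids):
            if a != b:
                raise ValueError(f"row-id mismatch: graph has {a!r} where semantic has {b!r}")
        raise ValueError(
            f"row count mismatch: graph {len(d_g)} vs semantic {len(d_s)} rows"
        )


def fuse(d_g: EmbeddingMatrix, d_s: EmbeddingMatrix, cfg: FusionConfig | None = None) -> EmbeddingMatrix:
    """Blend (or concatenate) graph and semantic embeddings.

    alpha = 0 returns the graph matrix bitwise; alpha = 1 the semantic one.
    Blend mode requires equal dimensions and identically ordered row ids.
    """
    cfg = cfg or FusionConfig()
    _check_aligned(d_g, d_s)
    a = cfg.alpha
    if cfg.mode == "blend":
        if d_g.dim != d_s.dim:
            raise ValueError(
                f"blend mode requires equal dims (graph {d_g.dim} vs semantic {d_s.dim}); "
                "use pca_align or concat mode"
            )
        if a == 0.0:
            v = d_g.vectors.copy()
        elif a == 1.0:
            v = d_s.vectors.copy()
        else:
            v = (1.0 - a) * d_g.vectors + a * d_s.vectors
    else:
        v = np.hstack([np.sqrt(1.0 - a) * d_g.vectors, np.sqrt(a) * d_s.vectors])
    if cfg.normalize_after:
        norms = np.linalg.norm(v, axis=1, keepdims=True)
        norms[norms == 0] = 1.0
        v = v / norms
    return EmbeddingMatrix(list(d_g.row_ids), v, "fused",
                           l2_normalized=cfg.normalize_after,
                           meta={"alpha": a, "mode": cfg.mode})


def grid_search_alpha(
    d_g: EmbeddingMatrix,
    d_s: EmbeddingMatrix,
    groups: Sequence,
    clusterer: Callable[[EmbeddingMatrix, int], dict[str, int]],
    grid: Sequence[float] = DEFAULT_ALPHA_GRID,
    mode: str = "blend",
) -> tuple[float, pd.DataFrame]:
    """Grid search for the mixing weight alpha.

    ``groups`` are labelled validation groups (anything with ``members`` ids
    and ``labels`` id->int ground truth, e.g. ``benchmark.BenchmarkGroup``).
    ``clusterer(matrix, k) -> labels`` is applied to each group's fused rows
    with k = its number of classes.  Returns the alpha maximising mean ARI
    (ties broken toward larger alpha, favouring the semantic channel) and
    the full score table.
    """
    from .clustering import ari, nmi  # local import avoids a cycle

    if not grid:
        raise ValueError("alpha grid is empty")
    rows = []
    for alpha in grid:
        fused = fuse(d_g, d_s, FusionConfig(alpha=alpha, mode=mode))
        aris, nmis = [], []
        for grp in groups:
            members = list(grp.members)
            truth = {m: grp.labels[m] for m in members}
            k = len(set(truth.values()))
            pred = clusterer(fused.subset(members), k)
            aris.append(ari(pred, truth))
            nmis.append(nmi(pred, truth))
        rows.append({"alpha": float(alpha), "mean_ari": float(np.mean(aris)),
                     "mean_nmi": float(np.mean(nmis))})
    table = pd.DataFrame(rows)
    # ties broken toward larger alpha
    top = table[np.isclose(table["mean_ari"], table["mean_ari"].max())]
    best = float(top["alpha"].max())
    return best, table
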