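"""End-to-end orchestration: gene sets + descriptions -> overlap network ->
dual embeddings -> CDI gate -> fusion -> consensus k -> clusters ->
summaries.

``run_pipeline`` executes the stages in order, logging every seed and
parameter, and writes a versioned run directory:

    config.yaml      resolved configuration (all defaults filled in)
    cdi.json         CDI score and the gate decision
    network.tsv      the m-type overlap network
    consensus.json   CDF/delta-CDF profile and the selected k
    labels.tsv       final cluster labels
    summaries.jsonl  one summary record per cluster
    metrics.json     ARI/NMI when ground-truth labels are supplied
    run.log          stage log (no timestamps, so reruns are byte-identical)

A below-threshold CDI emits a prominent warning but does not abort unless
``cdi.hard_gate`` is set.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import yaml

from . import __version__
from .clusterability import CdiModel, build_training_set, cdi_score, train_cdi
from .clustering import ari, cluster, nmi
from .consensus import consensus_profile
from .embeddings import HashingEncoder, WalkConfig, embed_graph, encode_descriptions, pca_align
from .fusion import FusionConfig, fuse
from .geneset import GeneSetCollection, read_descriptions, read_gmt
from .network import build_mtype_network, threshold_network
from .summarize import CentroidSummarizer, summarize_clusters

__all__ = ["DEFAULT_CONFIG", "run_pipeline", "load_config"]

DEFAULT_CONFIG: dict = {
    "seed": 0,
    "inputs": {"gmt": None, "descriptions": None, "labels": None},
    "network": {"p_cutoff": 0.05, "min_overlap": 1, "min_weight": 0.0},
    "graph_embedding": {
        "dim": 64, "walk_length": 80, "walks_per_node": 10, "window": 10,
        "negative_samples": 5, "return_p": 1.0, "inout_q": 0.25, "epochs": 5,
        "weighted": True,
    },
    "semantic_embedding": {"encoder": "offline", "encoder_dim": 512},
    "fusion": {"alpha": 0.8, "mode": "blend"},
    "cdi": {
        "model_path": None, "threshold": 0.5, "hard_gate": False,
        "train": {"replicates": 3, "n_nodes": 120, "tau": 0.7},
    },
    "consensus": {"k_min": 2, "k_max": 6, "n_resamples": 100,
                  "subsample_fraction": 0.8, "stability_tolerance": 0.05},
    "clustering": {"method": "kmeans", "min_cluster_size": 5},
    "summarize": {"budget": 8000},
}


def load_config(path: str | Path) -> dict:
    with open(path, encoding="utf-8") as fh:
        user = yaml.safe_load(fh) or {}
    return _merge(DEFAULT_CONFIG, user)


def _merge(base: dict, override: dict) -> dict:
    out = {}
    for key, val in base.items():
        if isinstance(val, dict):
            out[key] = _merge(val, override.get(key, {}) or {})
        else:
            out[key] = override.get(key, val)
    extra = set(override) - set(base)
    if extra:
        raise ValueError(f"unknown config keys: {sorted(extra)}")
    return out


def _setup_logger(run_dir: Path) -> logging.Logger:
    log = logging.getLogger(f"golden.run.{run_dir}")
    log.setLevel(logging.INFO)
    log.handlers.clear()
    fmt = logging.Formatter("%(levelname)s %(message)s")  # no timestamps: reruns byte-identical
    fh = logging.FileHandler(run_dir / "run.log", mode="w")
    fh.setFormatter(fmt)
    log.addHandler(fh)
    sh = logging.StreamHandler()
    sh.setFormatter(fmt)
    log.addHandler(sh)
    return log


def run_pipeline(
    config: dict | str | Path,
    out_dir: str | Path,
    collection: GeneSetCollection | None = None,
    descriptions: dict[str, str] | None = None,
    truth_labels: dict[str, int] | None = None,
    cdi_model: CdiModel | None = None,
) -> dict:
    """Run the full pipeline and return a result summary dict.

    Inputs may be passed in memory or referenced by the config's
    ``inputs`` paths.  All randomness derives from ``config['seed']``.
    """
    cfg = load_config(config) if isinstance(config, (str, Path)) else _merge(DEFAULT_CONFIG, config)
    run_dir = Path(out_dir)
    run_dir.mkdir(parents=True, exist_ok=True)
    log = _setup_logger(run_dir)
    seed = int(cfg["seed"])

    if collection is None:
        if not cfg["inputs"]["gmt"]:
            raise ValueError("no gene-set collection: pass `collection` or set inputs.gmt")
        collection = read_gmt(cfg["inputs"]["gmt"])
    if descriptions is None:
        descriptions = (read_descriptions(cfg["inputs"]["descriptions"])
                        if cfg["inputs"]["descriptions"] else collection.descriptions())
    if truth_labels is None and cfg["inputs"]["labels"]:
        truth_labels = {k: int(v) for k, v in read_descriptions(cfg["inputs"]["labels"]).items()}

    (run_dir / "config.yaml").write_text(yaml.safe_dump({"version": __version__, **cfg}, sort_keys=True))
    log.info("stage=network n_pags=%d universe=%d", len(collection), len(collection.universe))
    net = build_mtype_network(collection, p_cutoff=cfg["network"]["p_cutoff"],
                              min_overlap=cfg["network"]["min_overlap"])
    if cfg["network"]["min_weight"] > 0:
        net = threshold_network(net, cfg["network"]["min_weight"])
    net.write_edge_list(run_dir / "network.tsv")
    log.info("stage=network edges=%d", net.n_edges)

    # --- CDI gate (scored and reported before clustering) ---
    if cdi_model is not None:
        model = cdi_model
        log.info("stage=cdi model=injected kind=%s", model.model_kind)
    elif cfg["cdi"]["model_path"]:
        model = CdiModel.load(cfg["cdi"]["model_path"])
        log.info("stage=cdi model=loaded kind=%s", model.model_kind)
    else:
        tr = cfg["cdi"]["train"]
        log.info("stage=cdi training replicates=%d n_nodes=%d", tr["replicates"], tr["n_nodes"])
        ts = build_training_set(replicates=tr["replicates"], n_nodes=tr["n_nodes"],
                                tau=tr["tau"], seed=seed)
        model = train_cdi(ts, split_seed=seed)
    score = cdi_score(model, net)
    gated = score < cfg["cdi"]["threshold"]
    (run_dir / "cdi.json").write_text(json.dumps(
        {"cdi": score, "threshold": cfg["cdi"]["threshold"], "below_threshold": gated,
         "model_kind": model.model_kind}, indent=2))
    if gated:
        log.warning("stage=cdi LOW CLUSTERABILITY: CDI=%.3f below threshold %.2f -- "
                    "clustering results may not reflect real structure", score,
                    cfg["cdi"]["threshold"])
        if cfg["cdi"]["hard_gate"]:
            raise RuntimeError(f"CDI {score:.3f} below hard gate {cfg['cdi']['threshold']}")
    else:
        log.info("stage=cdi score=%.3f", score)

    # --- dual embeddings ---
    ge = cfg["graph_embedding"]
    walk = WalkConfig(dim=ge["dim"], walk_length=ge["walk_length"],
                      walks_per_node=ge["walks_per_node"], window=ge["window"],
                      negative_samples=ge["negative_samples"], return_p=ge["return_p"],
                      inout_q=ge["inout_q"], epochs=ge["epochs"],
                      weighted=ge["weighted"], seed=seed)
    d_g = embed_graph(net, walk)
    log.info("stage=graph_embedding dim=%d", d_g.dim)
    encoder = HashingEncoder(dim=cfg["semantic_embedding"]["encoder_dim"], seed=seed)
    sem = encode_descriptions({p: descriptions.get(p, "") for p in collection.ids}, encoder)
    target = min(ge["dim"], len(collection) - 1, sem.dim)
    d_s = pca_align(sem, target)
    if d_g.dim != d_s.dim:
        d_g_red = pca_align(d_g, target)
        from .embeddings import EmbeddingMatrix
        d_g = EmbeddingMatrix(list(d_g_red.row_ids), d_g_red.vectors, "graph",
                              d_g_red.l2_normalized, dict(d_g_red.meta))
    log.info("stage=semantic_embedding dim=%d retained_variance=%.3f",
             d_s.dim, d_s.meta.get("retained_variance", float("nan")))

    fused = fuse(d_g, d_s, FusionConfig(alpha=cfg["fusion"]["alpha"], mode=cfg["fusion"]["mode"]))
    log.info("stage=fusion alpha=%.2f mode=%s", cfg["fusion"]["alpha"], cfg["fusion"]["mode"])

    # --- consensus k selection ---
    cc = cfg["consensus"]
    k_max = min(cc["k_max"], len(collection) - 1)
    prof = consensus_profile(fused, range(cc["k_min"], k_max + 1),
                             n_resamples=cc["n_resamples"],
                             subsample_fraction=cc["subsample_fraction"],
                             stability_tolerance=cc["stability_tolerance"], seed=seed)
    (run_dir / "consensus.json").write_text(json.dumps(prof.to_dict(), indent=2))
    log.info("stage=consensus selected_k=%d", prof.selected_k)

    # --- final clustering ---
    method = cfg["clustering"]["method"]
    res = cluster(fused, method, k=prof.selected_k,
                  min_cluster_size=cfg["clustering"]["min_cluster_size"], seed=seed)
    res.write_tsv(run_dir / "labels.tsv")
    log.info("stage=clustering method=%s k_effective=%d", method, res.k_effective)

    metrics = {}
    if truth_labels:
        metrics = {"ari": ari(res.labels, truth_labels), "nmi": nmi(res.labels, truth_labels)}
        (run_dir / "metrics.json").write_text(json.dumps(metrics, indent=2))
        log.info("stage=metrics ari=%.3f nmi=%.3f", metrics["ari"], metrics["nmi"])

    # --- summaries ---
    by_cluster: dict[int, list] = {}
    for pid, lab in res.labels.items():
        by_cluster.setdefault(lab, []).append(collection[pid])
    records = summarize_clusters(by_cluster, CentroidSummarizer(), encoder,
                                 budget=cfg["summarize"]["budget"])
    with open(run_dir / "summaries.jsonl", "w", encoding="utf-8") as fh:
        for rec in records:
            fh.write(json.dumps(rec.to_json()) + "\n")
    log.info("stage=summarize clusters=%d", len(records))

    return {"cdi": score, "cdi_below_threshold": gated, "selected_k": prof.selected_k,
            "labels": res.labels, "metrics": metrics, "run_dir": str(run_dir),
            "summaries": [r.summary for r in records]}
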