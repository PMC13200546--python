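"""Cluster description summarisation and summary-quality metrics.

Each super gene-set is described by concatenating its members' free-text
descriptions (condensing to first sentences when a length budget is
exceeded) and distilling the result into one sentence via a pluggable
summariser port.  The default offline summariser is extractive: it returns
the sentence with the highest token-frequency centrality.  Summary quality
is scored against a reference with cosine similarity on encoder vectors and
ROUGE-1/ROUGE-L F1 (tokenisation: lowercase, split on non-alphanumerics).
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass
from typing import Protocol, Sequence

import numpy as np

from .embeddings import HashingEncoder, TextEncoder, tokenize
from .geneset import PAG

__all__ = [
    "SummaryRecord",
    "Summarizer",
    "CentroidSummarizer",
    "concatenate_descriptions",
    "summarize",
    "eval_summary",
    "rouge_n_f",
    "rouge_l_f",
    "summarize_clusters",
]

logger = logging.getLogger(__name__)

SEPARATOR = " "
_SENT_RE = re.compile(r"(?<=[.!?])\s+")


@dataclass
class SummaryRecord:
    cluster_id: int | str
    source_text: str
    summary: str
    metrics: dict[str, float]

    def to_json(self) -> dict:
        return {"cluster_id": self.cluster_id, "source_text": self.source_text,
                "summary": self.summary, "metrics": self.metrics}


def split_sentences(text: str) -> list[str]:
    return [s.strip() for s in _SENT_RE.split(text.strip()) if s.strip()]


def concatenate_descriptions(members: Sequence[PAG], budget: int = 8000) -> str:
    """Join member descriptions with a separator; when the result exceeds
    ``budget`` characters, condense each member to its first sentence
    (iteratively trimming the longest contributions) so that every member
    still contributes before anything is truncated."""
    texts = [p.description.strip() for p in members if p.description.strip()]
    joined = SEPARATOR.join(texts)
    if len(joined) <= budget:
        return joined
    condensed = [split_sentences(t)[0] if split_sentences(t) else t for t in texts]
    joined = SEPARATOR.join(condensed)
    while len(joined) > budget and max(map(len, condensed), default=0) > 1:
        # trim the longest first-sentence contribution in half
        i = int(np.argmax([len(c) for c in condensed]))
        condensed[i] = condensed[i][: max(1, len(condensed[i]) // 2)].rstrip()
        joined = SEPARATOR.join(condensed)
    return joined[:budget]


class Summarizer(Protocol):
    """Port for summarisers (remote LLM adapters or offline extractive)."""

    def summarize(self, text: str) -> str: ...


class CentroidSummarizer:
    """Deterministic extractive summariser: scores each sentence by the sum
    of corpus token frequencies of its tokens (normalised by sentence
    length) and returns the highest-scoring sentence; earlier sentences win
    ties."""

    def summarize(self, text: str) -> str:
        sentences = split_sentences(text)
        if not sentences:
            return ""
        if len(sentences) == 1:
            return sentences[0]
        freq: dict[str, int] = {}
        for tok in tokenize(text):
            freq[tok] = freq.get(tok, 0) + 1
        best_i, best_score = 0, -1.0
        for i, sent in enumerate(sentences):
            toks = tokenize(sent)
            if not toks:
                continue
            score = sum(freq[t] for t in toks) / len(toks)
            if score > best_score + 1e-12:
                best_i, best_score = i, score
        return sentences[best_i]


def summarize(text: str, summarizer: Summarizer | None = None, context: str = "") -> str:
    """Produce a single-sentence summary via the given port."""
    summarizer = summarizer or CentroidSummarizer()
    try:
        return summarizer.summarize(text)
    except Exception as exc:
        raise RuntimeError(f"summarizer failed{f' for {context}' if context else ''}") from exc


def _ngram_counts(tokens: list[str], n: int) -> dict[tuple[str, ...], int]:
    out: dict[tuple[str, ...], int] = {}
    for i in range(len(tokens) - n + 1):
        g = tuple(tokens[i : i + n])
        out[g] = out.get(g, 0) + 1
    return out


def rouge_n_f(summary: str, reference: str, n: int = 1) -> float:
    """ROUGE-N F1: clipped n-gram overlap."""
    s, r = tokenize(summary), tokenize(reference)
    cs, cr = _ngram_counts(s, n), _ngram_counts(r, n)
    overlap = sum(min(c, cr.get(g, 0)) for g, c in cs.items())
    total_s, total_r = max(len(s) - n + 1, 0), max(len(r) - n + 1, 0)
    if overlap == 0 or total_s == 0 or total_r == 0:
        return 0.0
    prec, rec = overlap / total_s, overlap / total_r
    return 2 * prec * rec / (prec + rec)


def _lcs_len(a: list[str], b: list[str]) -> int:
    if not a or not b:
        return 0
    prev = [0] * (len(b) + 1)
    for x in a:
        cur = [0] * (len(b) + 1)
        for j, y in enumerate(b, start=1):
            cur[j] = prev[j - 1] + 1 if x == y else max(prev[j], cur[j - 1])
        prev = cur
    return prev[-1]


def rouge_l_f(summary: str, reference: str) -> float:
    """ROUGE-L F1: longest-common-subsequence overlap."""
    s, r = tokenize(summary), tokenize(reference)
    lcs = _lcs_len(s, r)
    if lcs == 0:
        return 0.0
    prec, rec = lcs / len(s), lcs / len(r)
    return 2 * prec * rec / (prec + rec)


def eval_summary(
    summary: str, reference: str, encoder: TextEncoder | None = None
) -> tuple[float, float, float]:
    """(cosine, ROUGE-1 F, ROUGE-L F) of a summary against its reference.

    Cosine is computed on encoder vectors (offline hashing encoder by
    default).  An empty reference yields (0, 0, 0) with a warning.
    """
    if not reference.strip():
        logger.warning("empty reference text; summary metrics defined as 0")
        return 0.0, 0.0, 0.0
    encoder = encoder or HashingEncoder()
    vs, vr = np.asarray(encoder.encode([summary, reference]), dtype=float)
    denom = np.linalg.norm(vs) * np.linalg.norm(vr)
    cosine = float(vs @ vr / denom) if denom > 0 else 0.0
    return cosine, rouge_n_f(summary, reference, 1), rouge_l_f(summary, reference)


def summarize_clusters(
    members_by_cluster: dict[int | str, Sequence[PAG]],
    summarizer: Summarizer | None = None,
    encoder: TextEncoder | None = None,
    budget: int = 8000,
) -> list[SummaryRecord]:
    """Summarise every cluster and score each summary against its own
    concatenated source text."""
    records = []
    for cid in sorted(members_by_cluster, key=str):
        source = concatenate_descriptions(members_by_cluster[cid], budget=budget)
        summ = summarize(source, summarizer, context=f"cluster {cid}")
        cos, r1, rl = eval_summary(summ, source, encoder)
        records.append(SummaryRecord(cid, source, summ,
                                     {"cosine": cos, "rouge1_f": r1, "rougeL_f": rl}))
    return records
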