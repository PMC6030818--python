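"""Okapi BM25 document scoring and ranking.

Scores are sums over query terms of three factors: the Robertson–Sparck-Jones
relevance weight (an IDF-like quantity when no relevance information is
available), a saturating within-document term-frequency factor with length
normalization, and a query term-frequency factor.  The first PRF pass is
blind, so by default no relevance counts enter the weight (R = rt = 0).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

from .corpus_io import Index, Topic

__all__ = [
    "BM25Params",
    "RelevanceCounts",
    "RankedList",
    "rsj_weight",
    "bm25_score",
    "retrieve",
    "write_run",
    "read_run",
]


@dataclass(frozen=True)
class BM25Params:
    """Okapi BM25 free parameters.

    k1 saturates within-document term frequency, k3 weights query term
    frequency, and b in [0, 1] tunes document-length normalization.
    Defaults are the canonical Okapi settings.
    """

    k1: float = 1.2
    b: float = 0.75
    k3: float = 7.0

    def __post_init__(self) -> None:
        if not (0.0 <= self.b <= 1.0):
            raise ValueError("b must lie in [0, 1]")
        if self.k1 < 0 or self.k3 < 0:
            raise ValueError("k1 and k3 must be nonnegative")


@dataclass(frozen=True)
class RelevanceCounts:
    """Counts feeding the RSJ weight: R known-relevant docs, rt of them
    containing the term, N corpus docs, n docs containing the term."""

    R: int
    rt: int
    N: int
    n: int

    def __post_init__(self) -> None:
        if self.N == 0:
            raise ValueError("empty corpus (N = 0)")
        if not (0 <= self.rt <= self.R <= self.N):
            raise ValueError("need 0 <= rt <= R <= N")
        if not (self.rt <= self.n <= self.N):
            raise ValueError("need rt <= n <= N")


@dataclass(frozen=True)
class RankedList:
    """Ordered (doc_id, score) pairs, descending by score, doc_id breaking ties."""

    topic_id: str
    entries: tuple[tuple[str, float], ...]

    def doc_ids(self) -> list[str]:
        return [d for d, _ in self.entries]

    def __len__(self) -> int:
        return len(self.entries)


def rsj_weight(c: RelevanceCounts) -> float:
    """Robertson–Sparck-Jones weight with 0.5 continuity corrections.

    log of ((rt+0.5)/(R-rt+0.5)) / ((n-rt+0.5)/(N-n-R+rt+0.5)); with no
    relevance information (R = rt = 0) this reduces to the IDF-like
    log((N-n+0.5)/(n+0.5)).  Natural logarithm; the base only rescales
    scores and leaves rankings unchanged.  When R, rt, N and n come from a
    consistent class partition the last factor equals the count of
    non-relevant documents lacking the term plus 0.5, so every corrected
    cell is positive and the weight is always finite.
    """
    num = (c.rt + 0.5) / (c.R - c.rt + 0.5)
    den_hi = c.n - c.rt + 0.5
    den_lo = c.N - c.n - c.R + c.rt + 0.5
    if den_lo <= 0:
        raise ValueError("degenerate counts: N - n - R + rt + 0.5 must be positive")
    return math.log(num / (den_hi / den_lo))


def _query_tf(topic: Topic) -> dict[str, int]:
    qtf: dict[str, int] = {}
    for t in topic.terms:
        qtf[t] = qtf.get(t, 0) + 1
    return qtf


def bm25_score(
    query: Topic,
    doc_id: str,
    index: Index,
    params: BM25Params = BM25Params(),
    rel: Mapping[str, RelevanceCounts] | None = None,
) -> float:
    """BM25 score of one document against a query; absent terms contribute 0."""
    if doc_id not in index:
        raise KeyError(f"unknown doc_id {doc_id!r}")
    dl = index.doc_len[doc_id]
    K = params.k1 * ((1 - params.b) + params.b * dl / index.avdl)
    score = 0.0
    for term, qtf in _query_tf(query).items():
        f_id = index.tf(term, doc_id)
        if f_id == 0:
            continue
        counts = rel[term] if rel is not None and term in rel else RelevanceCounts(
            R=0, rt=0, N=index.n_docs, n=index.df(term)
        )
        sj = rsj_weight(counts)
        doc_factor = ((params.k1 + 1) * f_id) / (K + f_id)
        query_factor = ((params.k3 + 1) * qtf) / (params.k3 + qtf)
        score += sj * doc_factor * query_factor
    return score


def retrieve(
    query: Topic,
    index: Index,
    params: BM25Params = BM25Params(),
    depth: int = 1000,
    rel: Mapping[str, RelevanceCounts] | None = None,
) -> RankedList:
    """Rank all documents containing at least one query term.

    Only documents with positive score are returned, sorted by score
    descending with deterministic doc_id-ascending tie-breaking, truncated
    to *depth*.
    """
    if depth < 1:
        raise ValueError("depth must be >= 1")
    if not query.terms:
        raise ValueError(f"topic {query.topic_id!r} has no terms after preprocessing")
    candidates: set[str] = set()
    for term in query.terms:
        candidates.update(index.postings.get(term, ()))
    scored = [
        (doc_id, bm25_score(query, doc_id, index, params, rel))
        for doc_id in candidates
    ]
    scored = [(d, s) for d, s in scored if s > 0]
    scored.sort(key=lambda e: (-e[1], e[0]))
    return RankedList(topic_id=query.topic_id, entries=tuple(scored[:depth]))


def write_run(ranked_lists: Iterable[RankedList], path: str | Path, tag: str = "prfqe") -> None:
    """Write rankings in TREC run-file format: topic Q0 doc rank score tag."""
    lines = []
    for rl in ranked_lists:
        for rank, (doc_id, score) in enumerate(rl.entries, 1):
            lines.append(f"{rl.topic_id} Q0 {doc_id} {rank} {score:.6f} {tag}")
    Path(path).write_text("\n".join(lines) + ("\n" if lines else ""))


def read_run(path: str | Path) -> dict[str, RankedList]:
    """Read a TREC run file back into per-topic ranked lists."""
    per_topic: dict[str, list[tuple[str, float]]] = {}
    for lineno, line in enumerate(Path(path).read_text().splitlines(), 1):
        if not line.strip():
            continue
        parts = line.split()
        if len(parts) != 6:
            raise ValueError(f"{path}:{lineno}: expected 6 whitespace-separated fields")
        topic_id, _, doc_id, _, score, _ = parts
        per_topic.setdefault(topic_id, []).append((doc_id, float(score)))
    return {
        t: RankedList(topic_id=t, entries=tuple(entries))
        for t, entries in per_topic.items()
    }
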