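"""The full pseudo-relevance-feedback loop.

Blind retrieval -> top-k feedback set -> term pool (unique terms of the
feedback documents minus the query terms) -> metric ranking -> append the
top-n terms to the query -> final retrieval over the whole corpus.  Also the
one-term-at-a-time incremental diagnostic: re-retrieve with every prefix of
the ranked expansion terms and record the evaluation measure, exposing query
drift term by term.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Sequence

from .corpus_io import Index, Topic
from .retrieval import BM25Params, RankedList, retrieve
from .term_selection import METRICS, TermScore, rank_terms

__all__ = ["PRFConfig", "ExpansionResult", "build_term_pool", "run_prf", "incremental_expansion"]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class PRFConfig:
    """Knobs of one PRF run.

    k_docs: feedback depth (top documents treated as the relevant class);
    n_terms: number of expansion terms appended to the query; metric: one of
    the nine term-selection identifiers; retrieval_depth: length of the final
    ranking.
    """

    k_docs: int = 10
    n_terms: int = 10
    metric: str = "dfc"
    bm25: BM25Params = field(default_factory=BM25Params)
    use_stemming: bool = False
    retrieval_depth: int = 1000
    lambda_mix: float = 0.6

    def __post_init__(self) -> None:
        if self.k_docs < 1:
            raise ValueError("k_docs must be >= 1")
        if self.n_terms < 0:
            raise ValueError("n_terms must be >= 0")
        if self.metric not in METRICS:
            raise ValueError(f"unknown metric {self.metric!r}; valid names: {', '.join(METRICS)}")


@dataclass(frozen=True)
class ExpansionResult:
    topic_id: str
    original_terms: tuple[str, ...]
    selected_terms: tuple[TermScore, ...]
    expanded_query: Topic
    baseline_ranking: RankedList
    final_ranking: RankedList


def build_term_pool(feedback_docs: set[str], index: Index, query: Topic) -> set[str]:
    """Unique terms of the feedback documents, minus the original query terms.

    Stopwords never reach the pool because they were removed at indexing.
    """
    pool: set[str] = set()
    for term, plist in index.postings.items():
        if any(d in plist for d in feedback_docs):
            pool.add(term)
    pool -= set(query.terms)
    if not pool:
        raise ValueError("degenerate feedback set: empty term pool")
    return pool


def expand_query(topic: Topic, selected: Sequence[TermScore]) -> Topic:
    """Original terms followed by the selected term strings, first-occurrence
    de-duplicated; expansion terms are appended unweighted (query tf 1)."""
    terms: list[str] = []
    seen: set[str] = set()
    for t in list(topic.terms) + [ts.term for ts in selected]:
        if t not in seen:
            terms.append(t)
            seen.add(t)
    return Topic(topic_id=topic.topic_id, terms=tuple(terms))


def run_prf(topic: Topic, index: Index, cfg: PRFConfig = PRFConfig()) -> ExpansionResult:
    """Execute the complete PRF loop for one topic.

    With n_terms = 0 the final ranking equals the baseline ranking.  If fewer
    than k_docs documents match the query, the feedback set is all matching
    documents (logged as a warning).
    """
    baseline = retrieve(topic, index, cfg.bm25, depth=cfg.retrieval_depth)
    feedback = set(baseline.doc_ids()[: cfg.k_docs])
    if len(feedback) < cfg.k_docs:
        logger.warning(
            "topic %s: only %d matching documents for feedback depth %d",
            topic.topic_id, len(feedback), cfg.k_docs,
        )
    if cfg.n_terms == 0:
        return ExpansionResult(
            topic_id=topic.topic_id,
            original_terms=topic.terms,
            selected_terms=(),
            expanded_query=topic,
            baseline_ranking=baseline,
            final_ranking=baseline,
        )
    pool = build_term_pool(feedback, index, topic)
    ranked = rank_terms(cfg.metric, pool, index, feedback, topic, cfg.lambda_mix)
    selected = tuple(ranked[: cfg.n_terms])
    logger.info(
        "topic %s: pool of %d terms, selected %s",
        topic.topic_id, len(pool), [ts.term for ts in selected],
    )
    expanded = expand_query(topic, selected)
    final = retrieve(expanded, index, cfg.bm25, depth=cfg.retrieval_depth)
    return ExpansionResult(
        topic_id=topic.topic_id,
        original_terms=topic.terms,
        selected_terms=selected,
        expanded_query=expanded,
        baseline_ranking=baseline,
        final_ranking=final,
    )


def incremental_expansion(
    topic: Topic,
    ranked_terms: Sequence[TermScore],
    index: Index,
    cfg: PRFConfig,
    qrels,
) -> list[tuple[int, float]]:
    """Add one ranked term at a time and measure average precision.

    Returns (prefix length, AP) for prefix sizes 0..len(ranked_terms);
    prefix 0 is the unexpanded baseline.  No monotonicity is implied —
    query drift can move the measure either way.
    """
    from .evaluation import average_precision

    if not ranked_terms:
        raise ValueError("ranked_terms must be non-empty")
    out: list[tuple[int, float]] = []
    for prefix in range(len(ranked_terms) + 1):
        q = expand_query(topic, ranked_terms[:prefix])
        ranking = retrieve(q, index, cfg.bm25, depth=cfg.retrieval_depth)
        out.append((prefix, average_precision(ranking, qrels)))
    return out
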