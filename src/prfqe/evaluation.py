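"""Retrieval evaluation: average precision, MAP, qrels, test-point grids.

Average precision follows the standard TREC definition: the sum over ranks
of precision-at-rank times the binary relevance indicator, divided by the
number of judged relevant documents for the topic (retrieved or not).
Graded judgments are binarized at grade >= 1.  The grid runs the PRF loop
over a cross product of (feedback depth, expansion terms, metric) test
points, for a stemmed and an unstemmed index of the same raw corpus, and
reports the per-cell MAP difference (unstemmed minus stemmed) — the
stemming delta.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .corpus_io import Index, Topic
from .retrieval import RankedList
from .pipeline import PRFConfig, run_prf

__all__ = [
    "Qrels",
    "EvalRecord",
    "GridResult",
    "read_qrels",
    "average_precision",
    "mean_average_precision",
    "evaluate_run",
    "run_grid",
]


@dataclass(frozen=True)
class Qrels:
    """Binary relevance judgments: (topic_id, doc_id) -> grade."""

    judgments: Mapping[tuple[str, str], int]

    def relevant_count(self, topic_id: str) -> int:
        return sum(
            1 for (t, _), g in self.judgments.items() if t == topic_id and g >= 1
        )

    def is_relevant(self, topic_id: str, doc_id: str) -> bool:
        return self.judgments.get((topic_id, doc_id), 0) >= 1

    def topics(self) -> set[str]:
        return {t for (t, _) in self.judgments}


@dataclass(frozen=True)
class EvalRecord:
    topic_id: str
    ap: float
    k_docs: int | None = None
    n_terms: int | None = None
    metric: str | None = None
    stemmed: bool | None = None


def read_qrels(path: str | Path) -> Qrels:
    """Parse TREC qrels lines ``topic 0 doc_id grade``."""
    judgments: dict[tuple[str, str], int] = {}
    for lineno, line in enumerate(Path(path).read_text().splitlines(), 1):
        if not line.strip():
            continue
        parts = line.split()
        if len(parts) != 4:
            raise ValueError(f"{path}:{lineno}: expected 'topic 0 doc grade'")
        topic_id, _, doc_id, grade_s = parts
        try:
            grade = int(grade_s)
        except ValueError as exc:
            raise ValueError(f"{path}:{lineno}: non-integer grade {grade_s!r}") from exc
        key = (topic_id, doc_id)
        if key in judgments and judgments[key] != grade:
            raise ValueError(
                f"{path}:{lineno}: conflicting grades for topic {topic_id} doc {doc_id}"
            )
        judgments[key] = grade
    return Qrels(judgments=judgments)


def average_precision(ranking: RankedList, qrels: Qrels) -> float:
    """AP of one ranked list against the judged relevant set.

    Unretrieved relevant documents contribute zero, so AP lies in [0, 1].
    Raises on a topic with no judged relevant document.
    """
    crt = qrels.relevant_count(ranking.topic_id)
    if crt == 0:
        raise ValueError(f"topic {ranking.topic_id!r} has no judged relevant documents")
    hits = 0
    total = 0.0
    for rank, (doc_id, _) in enumerate(ranking.entries, 1):
        if qrels.is_relevant(ranking.topic_id, doc_id):
            hits += 1
            total += hits / rank
    return total / crt


def mean_average_precision(records: Iterable[EvalRecord]) -> float:
    aps = [r.ap for r in records]
    if not aps:
        raise ValueError("no evaluation records")
    return sum(aps) / len(aps)


def evaluate_run(rankings: Iterable[RankedList], qrels: Qrels) -> tuple[list[EvalRecord], float]:
    """Per-topic AP plus the MAP over all topics in the run."""
    records = [
        EvalRecord(topic_id=rl.topic_id, ap=average_precision(rl, qrels))
        for rl in rankings
    ]
    return records, mean_average_precision(records)


@dataclass(frozen=True)
class GridResult:
    """MAP per (metric, k_docs, n_terms, stemming flag) plus stemming deltas.

    ``map_table`` is indexed by (metric, k_docs, n_terms) with columns
    ``unstemmed`` and ``stemmed``; ``deltas`` is unstemmed - stemmed
    cellwise.
    """

    map_table: pd.DataFrame

    @property
    def deltas(self) -> pd.Series:
        return self.map_table["unstemmed"] - self.map_table["stemmed"]

    def to_tsv(self, path: str | Path) -> None:
        out = self.map_table.copy()
        out["delta"] = self.deltas
        out.to_csv(path, sep="\t")


def run_grid(
    topics: Sequence[tuple[Topic, Topic]],
    indexes: tuple[Index, Index],
    qrels: Qrels,
    metrics: Sequence[str],
    doc_points: Sequence[int],
    term_points: Sequence[int],
    base_cfg: PRFConfig = PRFConfig(),
) -> GridResult:
    """Evaluate every (metric, k_docs, n_terms) test point on both indexes.

    *topics* pairs each topic's unstemmed and stemmed form; *indexes* is the
    (unstemmed, stemmed) index pair built from the same raw corpus.
    """
    rows = []
    for metric in metrics:
        for k_docs in doc_points:
            for n_terms in term_points:
                cell = {"metric": metric, "k_docs": k_docs, "n_terms": n_terms}
                for label, index, pick in (
                    ("unstemmed", indexes[0], 0),
                    ("stemmed", indexes[1], 1),
                ):
                    cfg = replace(
                        base_cfg,
                        metric=metric,
                        k_docs=k_docs,
                        n_terms=n_terms,
                        use_stemming=(label == "stemmed"),
                    )
                    records = []
                    for pair in topics:
                        topic = pair[pick]
                        result = run_prf(topic, index, cfg)
                        records.append(
                            EvalRecord(
                                topic_id=topic.topic_id,
                                ap=average_precision(result.final_ranking, qrels),
                            )
                        )
                    cell[label] = mean_average_precision(records)
                rows.append(cell)
    table = pd.DataFrame(rows).set_index(["metric", "k_docs", "n_terms"])
    return GridResult(map_table=table)
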