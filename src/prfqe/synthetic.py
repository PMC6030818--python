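"""Synthetic test collections with PRF-relevant statistical structure.

Real PRF benchmarks pit a tiny (pseudo-)relevant class against a very large
non-relevant class, with topical terms whose document frequency and term
frequency can disagree: a term may occur many times but concentrated in one
feedback document (a "burst" term) or once each across most relevant
documents (a "spread" term).  tf-based metrics reward the former, df-based
metrics the latter.  The generator plants both patterns under seed control,
plus Zipf-distributed background vocabulary, so every pipeline stage is
testable at desk scale without any external collection.

Also provided: an exact constructor for the canonical 10-document burst
illustration (term t1 with tf 10 concentrated in one pseudo-relevant
document), and the printed 18-term score-table rows for queries 201/207 of
the TREC 2006 Genomics study (|R| = 40, N = 162 259), used as frozen
fixtures for score reproduction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .corpus_io import Document, Topic
from .evaluation import Qrels
from .term_selection import ContingencyStats

__all__ = [
    "SynthSpec",
    "SynthBundle",
    "TableRow",
    "TABLE_N",
    "TABLE_R",
    "generate",
    "worked_example_corpus",
    "table_fixture",
]


@dataclass(frozen=True)
class SynthSpec:
    """Generator controls; generation is a pure function of (spec, seed).

    df_concentration in (0, 1]: fraction of a topic's relevant documents
    carrying each spread term.  tf_burst in [0, 1]: fraction of a topic's
    planted terms that follow the burst pattern (all occurrences in one
    relevant document plus a small leak into non-relevant documents).
    """

    n_docs: int = 1000
    n_topics: int = 5
    relevant_per_topic: int = 10
    distractors_per_topic: int = 20
    vocab_size: int = 2000
    topical_terms_per_topic: int = 8
    df_concentration: float = 0.9
    tf_burst: float = 0.0
    burst_tf: int = 10
    doc_len_mean: float = 60.0
    zipf_exponent: float = 1.1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.relevant_per_topic >= self.n_docs:
            raise ValueError("relevant_per_topic must be smaller than n_docs")
        for name in ("n_docs", "n_topics", "relevant_per_topic", "vocab_size",
                     "topical_terms_per_topic"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be positive")
        if not (0.0 < self.df_concentration <= 1.0):
            raise ValueError("df_concentration must lie in (0, 1]")
        if not (0.0 <= self.tf_burst <= 1.0):
            raise ValueError("tf_burst must lie in [0, 1]")
        if self.n_topics * (self.topical_terms_per_topic + 2) > self.vocab_size:
            raise ValueError("more planted terms than the vocabulary can hold")
        need = self.n_topics * (self.relevant_per_topic + self.distractors_per_topic)
        if need > self.n_docs:
            raise ValueError("n_docs too small for the requested topic blocks")


@dataclass(frozen=True)
class SynthBundle:
    documents: tuple[Document, ...]
    topics: tuple[Topic, ...]
    qrels: Qrels
    truth: dict[str, tuple[str, ...]]


def generate(spec: SynthSpec) -> SynthBundle:
    """Generate a corpus, topics, qrels and planted-term truth from *spec*.

    Per topic: two dedicated query terms occur at the same rate in the
    relevant and the distractor documents (so unexpanded retrieval cannot
    separate them), while the planted topical terms occur only in relevant
    documents (spread terms) or in one relevant document plus a small
    non-relevant leak (burst terms).  Background tokens are drawn from a
    Zipf distribution over the vocabulary.
    """
    rng = np.random.default_rng(spec.seed)

    ranks = np.arange(1, spec.vocab_size + 1, dtype=float)
    probs = ranks ** (-spec.zipf_exponent)
    probs /= probs.sum()
    vocab = np.array([f"w{k:05d}" for k in range(spec.vocab_size)])

    doc_ids = [f"d{i:05d}" for i in range(spec.n_docs)]
    tokens: dict[str, list[str]] = {}
    for d in doc_ids:
        length = max(5, int(rng.poisson(spec.doc_len_mean)))
        tokens[d] = [str(w) for w in rng.choice(vocab, size=length, p=probs)]

    judgments: dict[tuple[str, str], int] = {}
    topics: list[Topic] = []
    truth: dict[str, tuple[str, ...]] = {}
    block = spec.relevant_per_topic + spec.distractors_per_topic
    n_bursty = round(spec.tf_burst * spec.topical_terms_per_topic)

    for ti in range(spec.n_topics):
        topic_id = f"{ti + 1:03d}"
        rel_docs = doc_ids[ti * block : ti * block + spec.relevant_per_topic]
        distractors = doc_ids[ti * block + spec.relevant_per_topic : (ti + 1) * block]
        nonrel_docs = [d for d in doc_ids if d not in set(rel_docs)]

        query_terms = (f"t{ti}q0", f"t{ti}q1")
        for d in rel_docs + distractors:
            for q in query_terms:
                tokens[d].extend([q] * (1 + int(rng.poisson(0.7))))

        topical = [f"t{ti}x{j:02d}" for j in range(spec.topical_terms_per_topic)]
        for j, term in enumerate(topical):
            if j < n_bursty:
                # burst pattern: all mass in one relevant doc + small leak
                host = rel_docs[int(rng.integers(len(rel_docs)))]
                tokens[host].extend([term] * spec.burst_tf)
                leak = rng.choice(len(nonrel_docs), size=2, replace=False)
                tokens[nonrel_docs[leak[0]]].extend([term] * 2)
                tokens[nonrel_docs[leak[1]]].append(term)
            else:
                n_carriers = max(1, round(spec.df_concentration * len(rel_docs)))
                carriers = rng.choice(len(rel_docs), size=n_carriers, replace=False)
                for ci in carriers:
                    tokens[rel_docs[ci]].append(term)

        for d in rel_docs:
            judgments[(topic_id, d)] = 1
        topics.append(Topic(topic_id=topic_id, terms=query_terms))
        truth[topic_id] = tuple(topical)

    documents = []
    for d in doc_ids:
        toks = tokens[d]
        rng.shuffle(toks)
        documents.append(Document(doc_id=d, text=" ".join(toks), tokens=tuple(toks)))
    return SynthBundle(
        documents=tuple(documents),
        topics=tuple(topics),
        qrels=Qrels(judgments=judgments),
        truth=truth,
    )


def worked_example_corpus() -> SynthBundle:
    """The canonical 10-document burst illustration, exactly.

    Documents D1..D10; the feedback threshold is meant to fall after D4, so
    the pseudo-relevant class is {D1..D4} and the rest is non-relevant
    (the judged relevant documents are D1, D2, D3 — D4 is a thresholding
    mistake).  Term t1 occurs 10 times in D4, twice in D5 and once in D6 and
    nowhere else: total tf 10 in the feedback class but document frequency
    only 1 there versus 2 outside.  Spread terms t2..t5 each sit once in
    three of the four feedback documents; t6..t29 are background terms in
    one feedback and one non-relevant document each; t30..t50 occur only
    outside the feedback set.  The query term "genes" occurs only in D1..D4,
    so retrieval at depth 4 yields exactly the intended feedback set.
    """
    layout: dict[str, list[str]] = {
        "D01": ["genes"] * 3 + ["t2", "t3", "t4"],
        "D02": ["genes"] * 3 + ["t2", "t3", "t5"],
        "D03": ["genes"] * 2 + ["t2", "t4", "t5"],
        "D04": ["genes"] * 2 + ["t1"] * 10 + ["t3", "t4", "t5"],
        "D05": ["t1"] * 2,
        "D06": ["t1"],
        "D07": [],
        "D08": [],
        "D09": [],
        "D10": [],
    }
    rel_ids = ["D01", "D02", "D03", "D04"]
    nr_ids = ["D05", "D06", "D07", "D08", "D09", "D10"]
    for i in range(6, 30):  # background pool terms: one feedback + one other doc
        layout[rel_ids[(i - 6) % 4]].append(f"t{i}")
        layout[nr_ids[(i - 6) % 6]].append(f"t{i}")
    for i in range(30, 51):  # background terms outside the feedback set
        layout[nr_ids[(i - 30) % 6]].append(f"t{i}")

    documents = tuple(
        Document(doc_id=d, text=" ".join(toks), tokens=tuple(toks))
        for d, toks in layout.items()
    )
    topic = Topic(topic_id="1", terms=("genes",))
    qrels = Qrels(judgments={("1", d): 1 for d in ("D01", "D02", "D03")})
    return SynthBundle(
        documents=documents,
        topics=(topic,),
        qrels=qrels,
        truth={"1": ("t2", "t3", "t4", "t5")},
    )


#: Corpus size and feedback-class size of the printed score tables.
TABLE_N = 162259
TABLE_R = 40


@dataclass(frozen=True)
class TableRow:
    """One printed score-table row: probabilities, df cells, printed scores."""

    term: str
    p_rel: float
    p_corpus: float
    tdfr: int
    tdfnr_bar: int
    tdfnr: int
    tdfr_bar: int
    cs: float
    dfc: float

    def contingency(self) -> ContingencyStats:
        return ContingencyStats(
            tdfr=self.tdfr,
            tdfr_bar=self.tdfr_bar,
            tdfnr=self.tdfnr,
            tdfnr_bar=self.tdfnr_bar,
        )


# Printed rows for query 201 (18 unique terms, 40 feedback docs).  Where the
# table's typesetting ran columns together, readings were disambiguated by
# recomputing the statistic from the df cells; such values match the printed
# digits to the table's precision.
_TABLE4 = (
    ("braf",        0.00082, 3.39e-07, 14, 162150,    69, 26, 1.9978,  9558.41),
    ("ras",         0.01085, 9.00e-05, 38, 149277, 12942,  2, 1.2877,  411.485),
    ("raf",         0.00652, 3.36e-05, 40, 157245,  4974,  0, 1.2516, 1254.757),
    ("transgelin",  0.00035, 1.26e-07,  1, 162197,    22, 39, 0.9541,  174.442),
    ("cref",        0.00037, 1.64e-07,  1, 162203,    16, 39, 0.8312,  236.704),
    ("9nc",         0.00015, 4.31e-08,  1, 162216,     3, 39, 0.5542, 1012.394),
    ("vmm12",       0.00012, 3.27e-08,  1, 162219,     0, 39, 0.4639,  4055.51),
    ("v600e",       0.00012, 3.34e-08,  5, 162217,     2, 35, 0.4351, 14481.607),
    ("uveal",       0.00031, 2.44e-07,  3, 162144,    75, 37, 0.3911,  462.411),
    ("kras",        0.00043, 4.81e-07,  6, 162130,    89, 34, 0.3783, 1526.484),
    ("calipel",     0.00002, 5.57e-09,  5, 162219,     0, 35, 0.0791,    20278.0),
    ("v599e",       0.00011, 4.80e-08,  8, 162214,     5, 32, 0.2523, 19960.86),
    ("nature00766", 0.00003, 2.23e-08, 12, 162199,    20, 28, 0.0444, 18238.237),
    ("mouriaux",    0.00003, 9.04e-09,  5, 162217,     2, 35, 0.0759, 14481.607),
    ("trovisco",    0.00001, 3.48e-09,  3, 162219,     0, 37, 0.0494, 12166.656),
    ("18934a",      0.00001, 7.65e-09,  5, 162213,     6, 35, 0.0224,  9212.159),
    ("shieldsj",    0.00001, 2.09e-09,  2, 162219,     0, 38, 0.0296,  8111.05),
    ("klintenas",   0.00001, 1.39e-09,  2, 162219,     0, 38, 0.0197,  8111.05),
)

# Printed rows for query 207.
_TABLE5 = (
    ("etidronate",           0.0019,  3.10e-07, 40, 162186,  33,  0, 11.641, 88891.0),
    ("fetuin",               0.0029,  1.70e-06,  4, 161944, 275, 36,  4.941,  225.14),
    ("bisphosphonates",      0.0017,  9.03e-07, 32, 161948, 271,  8,  3.208, 13674.0),
    ("incadronate",          0.0003,  5.90e-08,  4, 162214,   5, 36, 1.5254,  7205.69),
    ("paget's",              0.0008,  3.70e-07,  6, 162119, 100, 34, 1.7285,  1366.93),
    ("pamidronate",          0.0012,  7.50e-07, 18, 162081, 138, 22, 1.9186,  8399.17),
    ("aminobisphosphonates", 0.0003,  7.60e-08,  6, 162202,  17, 34, 1.1847,  6339.73),
    ("ibandronate",          0.0006,  3.60e-07, 12, 162184,  35, 28, 0.9998,  12411.6),
    ("bisphosphonate",       0.0007,  4.80e-07, 26, 162023, 196, 14, 1.0199,  12320.1),
    ("tiludronate",          0.0001,  3.40e-08,  5, 162206,  13, 35,  0.294,  5626.01),
    ("alendronate",          0.0005,  6.40e-07, 24, 162096, 123, 16,  0.391,  15865.1),
    ("didronel",             1.80e-05, 5.50e-09, 4, 162218,   1, 36,  0.059,  12976.3),
    ("risedronate",          0.0003,  1.90e-07, 12, 162186,  33, 28,  0.473,  12963.5),
    ("art271",               1.40e-05, 2.08e-09, 3, 162219,   0, 37,  0.098,  12166.7),
    ("int1999",              1.40e-05, 2.08e-09, 3, 162219,   0, 37,  0.098,  12166.7),
    ("pprice",               3.20e-05, 7.60e-09, 4, 162217,   2, 36,  0.135,  10812.3),
)


def table_fixture(which: str) -> list[TableRow]:
    """The printed 18-/16-row score tables as :class:`TableRow` fixtures."""
    if which == "table4":
        rows = _TABLE4
    elif which == "table5":
        rows = _TABLE5
    else:
        raise ValueError(f"unknown table name {which!r}; expected 'table4' or 'table5'")
    return [TableRow(*r) for r in rows]
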