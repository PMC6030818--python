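"""Expansion-term scoring: DFC and eight comparator metrics.

In pseudo relevance feedback the top-k retrieved documents form a tiny
"relevant" class and the rest of the corpus a huge "non-relevant" class.
Every candidate term from the feedback documents is scored under one of
nine metrics:

``dfc``
    Document-frequency chi-square: a Pearson chi-square over the 2x2 table
    of term presence/absence vs. (pseudo-)relevant/non-relevant class, with
    expected counts taken as the corpus document frequency apportioned by
    class size.  Because it uses binary document presence rather than raw
    term frequency, a term whose occurrences are concentrated in a single
    feedback document is not mistaken for a discriminative term.
``chi_square`` / ``chi``
    Term-frequency-based chi-square (and its un-squared, signed variant)
    over the term's probability in the feedback set vs. the whole corpus.
``kld``
    Kullback-Leibler contribution p_rel * log(p_rel / p_corpus).
``codice``
    Co-occurrence with the query terms (Jaccard-type CoDice, IDF-damped
    codegree, product over query terms).
``ig``
    Information gain of the term's presence w.r.t. the two classes.
``prf``
    Ratio of the term's (smoothed) probability in the relevant vs.
    non-relevant class.
``lrf``
    Relevance-model (language-model) score with mixing weight lambda.
``rsv``
    Robertson offer weight rt x RSJ (the canonical "Robertson selection
    value"; the literature leaves room on the exact form, so this choice is
    documented in docs/methods.md).

Logarithms are natural throughout except codegree/IDF, which are defined
with log10.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

from .corpus_io import Index, Topic
from .retrieval import RelevanceCounts, rsj_weight

__all__ = [
    "METRICS",
    "ContingencyStats",
    "TermDistribution",
    "CoocStats",
    "ClassModel",
    "TermScore",
    "compute_contingency",
    "dfc_score",
    "chi_square_score",
    "chi_one_score",
    "kld_score",
    "codice",
    "codegree",
    "cooccurrence_final",
    "ig_score",
    "prf_metric_score",
    "lrf_score",
    "rsv_score",
    "rank_terms",
]

#: The nine supported metric identifiers.
METRICS = ("dfc", "chi_square", "chi", "kld", "rsv", "codice", "ig", "lrf", "prf")

#: Default relevance-model mixing weight (best-performing setting).
DEFAULT_LAMBDA = 0.6


@dataclass(frozen=True)
class ContingencyStats:
    """2x2 document-frequency table of a term against the two PRF classes.

    tdfr / tdfr_bar: relevant-class docs containing / lacking the term;
    tdfnr / tdfnr_bar: same for the non-relevant class; tdfc / tdfc_bar the
    corpus totals; ratio_r / ratio_nr the class-size fractions of the corpus.
    """

    tdfr: int
    tdfr_bar: int
    tdfnr: int
    tdfnr_bar: int

    @property
    def n_relevant(self) -> int:
        return self.tdfr + self.tdfr_bar

    @property
    def n_nonrelevant(self) -> int:
        return self.tdfnr + self.tdfnr_bar

    @property
    def n_docs(self) -> int:
        return self.n_relevant + self.n_nonrelevant

    @property
    def tdfc(self) -> int:
        return self.tdfr + self.tdfnr

    @property
    def tdfc_bar(self) -> int:
        return self.tdfr_bar + self.tdfnr_bar

    @property
    def ratio_r(self) -> float:
        return self.n_relevant / self.n_docs

    @property
    def ratio_nr(self) -> float:
        return self.n_nonrelevant / self.n_docs


@dataclass(frozen=True)
class TermDistribution:
    """Term-frequency-based probabilities of a term.

    p_rel: probability in the feedback (pseudo-relevant) set; p_corpus:
    probability in the whole corpus; p_nonrel: probability in the
    non-relevant class (smoothed where required by the consuming metric).
    """

    p_rel: float
    p_corpus: float
    p_nonrel: float = 0.0


@dataclass(frozen=True)
class CoocStats:
    """Document co-occurrence counts of a query term i and candidate term j."""

    df_i: int
    df_j: int
    df_ij: int
    N: int
    Nc: int
    D: int

    def __post_init__(self) -> None:
        if self.df_ij > min(self.df_i, self.df_j):
            raise ValueError("df_ij cannot exceed min(df_i, df_j)")


@dataclass(frozen=True)
class ClassModel:
    """Probabilities for information gain over the two PRF classes."""

    p_class: tuple[float, float]
    p_term: float
    cond_given_t: tuple[float, float]
    cond_given_not_t: tuple[float, float]


@dataclass(frozen=True)
class TermScore:
    term: str
    score: float
    rank: int


def compute_contingency(term: str, feedback_doc_ids: set[str], index: Index) -> ContingencyStats:
    """Document-frequency 2x2 table of *term* for feedback set vs. rest of corpus."""
    if not feedback_doc_ids:
        raise ValueError("feedback set is empty")
    df_total = index.df(term)
    if df_total == 0:
        raise KeyError(f"term {term!r} does not occur in the corpus")
    plist = index.postings[term]
    tdfr = sum(1 for d in feedback_doc_ids if d in plist)
    n_rel = len(feedback_doc_ids)
    n_nonrel = index.n_docs - n_rel
    tdfnr = df_total - tdfr
    return ContingencyStats(
        tdfr=tdfr,
        tdfr_bar=n_rel - tdfr,
        tdfnr=tdfnr,
        tdfnr_bar=n_nonrel - tdfnr,
    )


def dfc_score(c: ContingencyStats) -> float:
    """Document-frequency chi-square.

    Sum of four (observed - expected)^2 / expected cells, where the expected
    counts apportion the term's corpus document frequency (and its
    complement) by the class-size ratios:

        (tdfr  - tdfc    * ratio_r )^2 / (tdfc     * ratio_r )
      + (tdfr_bar - tdfc_bar * ratio_r )^2 / (tdfc_bar * ratio_r )
      + (tdfnr - tdfc    * ratio_nr)^2 / (tdfc     * ratio_nr)
      + (tdfnr_bar - tdfc_bar * ratio_nr)^2 / (tdfc_bar * ratio_nr)

    Algebraically this is the textbook Pearson chi-square statistic of the
    2x2 presence/class table, so it is nonnegative, zero iff every observed
    cell equals its expected cell, and symmetric under swapping the class
    labels.
    """
    if c.tdfc == 0:
        raise ValueError("term occurs in no document (tdfc = 0)")
    if c.tdfc_bar == 0:
        raise ValueError("term occurs in every document (tdfc_bar = 0)")
    if c.ratio_r <= 0.0 or c.ratio_r >= 1.0:
        raise ValueError("degenerate class split (ratio_r must lie in (0, 1))")
    total = 0.0
    for observed, margin, ratio in (
        (c.tdfr, c.tdfc, c.ratio_r),
        (c.tdfr_bar, c.tdfc_bar, c.ratio_r),
        (c.tdfnr, c.tdfc, c.ratio_nr),
        (c.tdfnr_bar, c.tdfc_bar, c.ratio_nr),
    ):
        expected = margin * ratio
        total += (observed - expected) ** 2 / expected
    return total


def chi_square_score(d: TermDistribution) -> float:
    """tf-based chi-square: (p_rel - p_corpus)^2 / p_corpus."""
    if d.p_corpus <= 0:
        raise ValueError("p_corpus must be positive")
    return (d.p_rel - d.p_corpus) ** 2 / d.p_corpus


def chi_one_score(d: TermDistribution) -> float:
    """Signed, un-squared chi variant: (p_rel - p_corpus) / p_corpus."""
    if d.p_corpus <= 0:
        raise ValueError("p_corpus must be positive")
    return (d.p_rel - d.p_corpus) / d.p_corpus


def kld_score(d: TermDistribution) -> float:
    """Per-term Kullback-Leibler contribution p_rel * log(p_rel / p_corpus)."""
    if d.p_rel <= 0 or d.p_corpus <= 0:
        raise ValueError("p_rel and p_corpus must be positive")
    return d.p_rel * math.log(d.p_rel / d.p_corpus)


def codice(s: CoocStats) -> float:
    """Jaccard-form co-occurrence coefficient df_ij / (df_i + df_j - df_ij)."""
    if s.df_i < 1 or s.df_j < 1:
        raise ValueError("df_i and df_j must be >= 1")
    return s.df_ij / (s.df_i + s.df_j - s.df_ij)


def codegree(s: CoocStats) -> float:
    """IDF-damped co-occurrence: log10(CoDice + 1) * IDF(ct) / log10(D)."""
    if s.D < 2:
        raise ValueError("need at least 2 feedback documents (log10 D > 0)")
    if s.Nc < 1:
        raise ValueError("candidate term must occur in the corpus")
    idf = math.log10(s.N / s.Nc)
    return math.log10(codice(s) + 1.0) * idf / math.log10(s.D)


def cooccurrence_final(stats_per_query_term: Sequence[CoocStats]) -> float:
    """Product of codegree over all query terms."""
    if not stats_per_query_term:
        raise ValueError("no query-term co-occurrence statistics supplied")
    prod = 1.0
    for s in stats_per_query_term:
        prod *= codegree(s)
    return prod


def _xlogx(p: float) -> float:
    # 0 * log 0 = 0 convention
    return p * math.log(p) if p > 0 else 0.0


def ig_score(m: ClassModel) -> float:
    """Information gain of term presence w.r.t. the two classes (natural log).

    Class entropy plus the P(t)- and P(not-t)-weighted conditional terms;
    zero when presence is independent of class, and equal to the class
    entropy for a perfect predictor.
    """
    entropy = -sum(_xlogx(p) for p in m.p_class)
    p_t = m.p_term
    p_not_t = 1.0 - p_t
    cond_t = sum(_xlogx(p) for p in m.cond_given_t)
    cond_not_t = sum(_xlogx(p) for p in m.cond_given_not_t)
    return entropy + p_t * cond_t + p_not_t * cond_not_t


def prf_metric_score(d: TermDistribution) -> float:
    """Probabilistic relevance feedback ratio p_rel / p_nonrel.

    Callers must supply smoothed probabilities (rank_terms applies add-one
    smoothing on document counts) so the ratio is always finite.
    """
    if d.p_nonrel <= 0:
        raise ValueError("p_nonrel must be positive (apply smoothing upstream)")
    return d.p_rel / d.p_nonrel


def lrf_score(
    term: str,
    feedback_docs: Iterable[str],
    index: Index,
    lambda_mix: float = DEFAULT_LAMBDA,
    p_collection: float | None = None,
) -> float:
    """Relevance-model score: sum over feedback docs of log(P(t|M_R)/P(t|G)).

    P(t|M_R) mixes the per-document maximum-likelihood tf ratio with the
    collection model: lambda * tf(t,R)/|R| + (1 - lambda) * P(t|G).
    """
    if not (0.0 < lambda_mix < 1.0):
        raise ValueError("lambda_mix must lie in (0, 1)")
    if p_collection is None:
        p_collection = index.corpus_tf(term) / index.total_tokens
    if p_collection <= 0:
        raise ValueError(f"term {term!r} has zero collection probability")
    score = 0.0
    for doc_id in feedback_docs:
        tf_ratio = index.tf(term, doc_id) / index.doc_len[doc_id]
        p_mr = lambda_mix * tf_ratio + (1.0 - lambda_mix) * p_collection
        score += math.log(p_mr / p_collection)
    return score


def rsv_score(c: ContingencyStats) -> float:
    """Robertson offer weight: tdfr x RSJ(R, rt=tdfr, N, n=tdfc)."""
    if c.tdfr == 0:
        return 0.0
    counts = RelevanceCounts(R=c.n_relevant, rt=c.tdfr, N=c.n_docs, n=c.tdfc)
    return c.tdfr * rsj_weight(counts)


class _FeedbackContext:
    """Shared statistics for scoring one term pool against one feedback set."""

    def __init__(self, index: Index, feedback_doc_ids: set[str], query: Topic):
        self.index = index
        self.feedback = feedback_doc_ids
        self.query = query
        self.n_rel = len(feedback_doc_ids)
        self.n_nonrel = index.n_docs - self.n_rel
        self.rel_tokens = sum(index.doc_len[d] for d in feedback_doc_ids)
        self.total_tokens = index.total_tokens
        self.nonrel_tokens = self.total_tokens - self.rel_tokens
        self._query_docsets = {
            q: set(index.postings.get(q, ())) for q in set(query.terms)
        }

    def tf_in_feedback(self, term: str) -> int:
        plist = self.index.postings[term]
        return sum(plist.get(d, 0) for d in self.feedback)

    def distribution(self, term: str, smoothed: bool = False) -> TermDistribution:
        tf_rel = self.tf_in_feedback(term)
        tf_all = self.index.corpus_tf(term)
        p_rel = tf_rel / self.rel_tokens
        p_corpus = tf_all / self.total_tokens
        if smoothed:
            # add-one smoothing on document counts for the PRF ratio
            c = compute_contingency(term, self.feedback, self.index)
            p_rel = (c.tdfr + 1) / (self.n_rel + 2)
            p_nonrel = (c.tdfnr + 1) / (self.n_nonrel + 2)
        else:
            p_nonrel = (tf_all - tf_rel) / self.nonrel_tokens if self.nonrel_tokens else 0.0
        return TermDistribution(p_rel=p_rel, p_corpus=p_corpus, p_nonrel=p_nonrel)

    def class_model(self, term: str) -> ClassModel:
        # document-frequency-based estimation over the two PRF classes
        c = compute_contingency(term, self.feedback, self.index)
        N = self.index.n_docs
        p_c1 = self.n_rel / N
        p_t = c.tdfc / N
        if c.tdfc > 0:
            cond_t = (c.tdfr / c.tdfc, c.tdfnr / c.tdfc)
        else:
            cond_t = (0.0, 0.0)
        if c.tdfc_bar > 0:
            cond_not_t = (c.tdfr_bar / c.tdfc_bar, c.tdfnr_bar / c.tdfc_bar)
        else:
            cond_not_t = (0.0, 0.0)
        return ClassModel(
            p_class=(p_c1, 1.0 - p_c1),
            p_term=p_t,
            cond_given_t=cond_t,
            cond_given_not_t=cond_not_t,
        )

    def cooc_score(self, term: str) -> float:
        ct_docs = set(self.index.postings[term])
        stats = []
        for q, q_docs in sorted(self._query_docsets.items()):
            if not q_docs:
                # query term absent from the corpus cannot co-occur; skip it
                continue
            stats.append(
                CoocStats(
                    df_i=len(q_docs),
                    df_j=len(ct_docs),
                    df_ij=len(q_docs & ct_docs),
                    N=self.index.n_docs,
                    Nc=len(ct_docs),
                    D=self.n_rel,
                )
            )
        if not stats:
            return 0.0
        return cooccurrence_final(stats)

    def score(self, metric: str, term: str, lambda_mix: float) -> float:
        if metric == "dfc":
            c = compute_contingency(term, self.feedback, self.index)
            # a term present in every document carries no class information
            return 0.0 if c.tdfc_bar == 0 else dfc_score(c)
        if metric == "chi_square":
            return chi_square_score(self.distribution(term))
        if metric == "chi":
            return chi_one_score(self.distribution(term))
        if metric == "kld":
            return kld_score(self.distribution(term))
        if metric == "rsv":
            return rsv_score(compute_contingency(term, self.feedback, self.index))
        if metric == "codice":
            return self.cooc_score(term)
        if metric == "ig":
            return ig_score(self.class_model(term))
        if metric == "lrf":
            return lrf_score(term, self.feedback, self.index, lambda_mix)
        if metric == "prf":
            return prf_metric_score(self.distribution(term, smoothed=True))
        raise ValueError(f"unknown metric {metric!r}; valid names: {', '.join(METRICS)}")


def rank_terms(
    metric: str,
    pool: Iterable[str],
    index: Index,
    feedback_doc_ids: set[str],
    query: Topic,
    lambda_mix: float = DEFAULT_LAMBDA,
) -> list[TermScore]:
    """Score and rank every pool term under *metric*.

    Original query terms are excluded from the pool; ranks run 1..K by score
    descending, ties broken lexicographically by term (reproducibility —
    random tie-breaking is deliberately impossible).
    """
    if metric not in METRICS:
        raise ValueError(f"unknown metric {metric!r}; valid names: {', '.join(METRICS)}")
    terms = sorted(set(pool) - set(query.terms))
    if not terms:
        raise ValueError("term pool is empty")
    ctx = _FeedbackContext(index, set(feedback_doc_ids), query)
    scored = [(term, ctx.score(metric, term, lambda_mix)) for term in terms]
    scored.sort(key=lambda e: (-e[1], e[0]))
    return [TermScore(term=t, score=s, rank=i) for i, (t, s) in enumerate(scored, 1)]


def write_term_scores(
    scores: Sequence[TermScore],
    metric: str,
    index: Index,
    feedback_doc_ids: set[str],
    path,
) -> None:
    """TSV mirror of the score tables: term, metric, score, rank + df cells."""
    from pathlib import Path

    lines = ["term\tmetric\tscore\trank\ttdfr\ttdfr_bar\ttdfnr\ttdfnr_bar"]
    for ts in scores:
        c = compute_contingency(ts.term, set(feedback_doc_ids), index)
        lines.append(
            f"{ts.term}\t{metric}\t{ts.score:.6g}\t{ts.rank}\t"
            f"{c.tdfr}\t{c.tdfr_bar}\t{c.tdfnr}\t{c.tdfnr_bar}"
        )
    Path(path).write_text("\n".join(lines) + "\n")
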