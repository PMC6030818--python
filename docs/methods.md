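# Methods

## The PRF loop

One PRF run is a deterministic function of (corpus, topic, configuration):

1. Blind retrieval: BM25 ranks every document containing at least one query
   term; documents with non-positive score are dropped (a term occurring in
   more than half the corpus has a non-positive RSJ weight and contributes
   nothing useful).  Ties are broken by doc id, ascending.
2. The top `k_docs` documents form the pseudo-relevant class; the remainder
   of the corpus is the non-relevant class.  If fewer than `k_docs`
   documents match, the feedback set is every matching document and a
   warning is logged.
3. The term pool is the union of the feedback documents' vocabularies minus
   the query terms (stopwords were already removed at indexing).
4. The chosen metric scores every pool term; ranks are assigned by score
   descending with lexicographic tie-breaking.  Random tie-breaking is
   deliberately impossible.
5. The top `n_terms` terms are appended to the query unweighted (query term
   frequency 1), first occurrence kept on duplicates; with `n_terms = 0`
   the final ranking is the baseline ranking.
6. Final retrieval re-scores the full corpus with the expanded query, again
   blind (no relevance counts are fed back into the RSJ weight; both passes
   of the loop are pseudo, not judged, feedback).

`incremental_expansion` re-retrieves with every prefix of the ranked
expansion terms and records average precision per prefix — the one-term-at-
a-time diagnostic that makes query drift visible term by term.

## Retrieval model

BM25 with parameters `k1` (document tf saturation, default 1.2), `b`
(length normalization in [0, 1], default 0.75) and `k3` (query tf
saturation, default 7) — the canonical Okapi settings, all overridable.
The score of document *d* is

    sum over query terms t of
      RSJ(t) · (k1+1)·f_td / (K + f_td) · (k3+1)·f_tq / (k3 + f_tq),
    K = k1·((1−b) + b·dl/avdl).

The RSJ weight uses the classic 0.5-corrected contingency form including
the `+rt` term in the complement cell,

    log [ (rt+0.5)(N−n−R+rt+0.5) ] / [ (R−rt+0.5)(n−rt+0.5) ].

For any consistent class partition the cell `N−n−R+rt` equals the number of
non-relevant documents lacking the term, so every corrected cell is
positive and the weight is finite even when a term occurs in every
document of an all-relevant corpus.  A variant sometimes written without
`+rt` is identical in the blind case R = rt = 0 (the only case the default
pipeline exercises) but is undefined at that boundary, which is why the
full form was adopted.  Logarithms are natural; the base rescales all
scores by a constant and cannot change a ranking.

## Term-selection metrics

Let `p_rel` and `p_corpus` be tf-based probabilities of a term in the
feedback set and in the whole corpus (occurrences over total tokens), and
let (tdfr, tdfr̄, tdfnr, tdfnr̄) be the document-frequency 2×2 table of
presence/absence against the two classes.

* **dfc** — sum of four (obs − exp)²/exp cells with expected counts
  `tdfc·ratio_r` etc.  Since the expected counts are exactly the
  margin products of the 2×2 table divided by N, DFC *is* the textbook
  Pearson chi-square of that table; the test suite verifies agreement with
  an independent generic implementation to 1e-9 relative error on random
  tables.  Consequences used as test invariants: DFC ≥ 0, zero iff the
  table is exactly proportional, symmetric under class-label swap.
* **chi_square** — `(p_rel − p_corpus)²/p_corpus`; **chi** — the un-squared
  signed variant `(p_rel − p_corpus)/p_corpus`.  The un-squared form is the
  minimal reading of "chi-square without the square"; its exact historical
  form is not nailed down in the literature we follow, so the choice is a
  documented convention, not an assertion.
* **kld** — `p_rel · log(p_rel/p_corpus)`.  Note this per-term statistic is
  signed and unbounded; claims that it lives in [0, 1] hold only for
  particular normalizations and are not enforced here.
* **codice / codegree / co-occurrence** — Jaccard-form CoDice
  `df_ij/(df_i + df_j − df_ij)` (the union-size denominator is the only
  standard reading of the coefficient), damped as
  `log10(CoDice+1) · IDF(ct)/log10(D)` with `IDF = log10(N/Nc)`, and
  multiplied over all query terms.  These two formulas are defined with
  base-10 logarithms and keep them; query terms absent from the corpus
  cannot co-occur and are skipped.
* **ig** — information gain of term presence w.r.t. the two classes, with
  document-frequency probability estimates (P(t) = tdfc/N,
  P(c₁) = |R|/N, conditionals from the table cells) and the 0·log 0 = 0
  convention.  Algebraically the mutual information I(class; presence);
  the tests check it against a brute-force MI computation.
* **prf** — ratio of class probabilities with add-one smoothing on document
  counts, `p = (tdf + 1)/(class size + 2)`, so the ratio is finite for
  terms absent from the non-relevant class.
* **lrf** — relevance-model score `Σ_d log(P(t|M_d)/P(t|G))` over feedback
  documents, `P(t|M_d) = λ·tf(t,d)/dl(d) + (1−λ)·P(t|G)`, collection model
  `P(t|G)` tf-based.  Default λ = 0.6, the setting reported to work best;
  λ → 0 collapses every score to 0.
* **rsv** — the Robertson offer weight `tdfr · RSJ(R, rt=tdfr, N, n=tdfc)`.
  The name "Robertson selection value" is attached to more than one formula
  in the literature; the offer weight is the canonical choice and is used
  here as a documented substitute.

Degenerate inputs: the scoring primitives raise on empty corpora, zero
denominators and degenerate tables (a term in no or in every document).
The ranking layer, which must survive arbitrary pools, maps one such case
to a neutral score instead: a term present in *every* document carries no
class information and receives DFC 0.

## Evaluation

Average precision is `Σ_r P(r)·rel(r) / Crt` with `Crt` the *judged*
relevant count for the topic — unretrieved relevant documents drag AP down,
which is the standard TREC convention.  Graded judgments binarize at
grade ≥ 1.  Default ranking depth is 1000 (TREC convention), configurable.
MAP is the unweighted mean of per-topic AP.  The grid runner evaluates
every (metric, k_docs, n_terms) cell on an unstemmed and a stemmed index of
the same raw corpus and reports the cellwise stemming delta
MAP(unstemmed) − MAP(stemmed).

## Synthetic collections

The generator emulates the statistical structure that makes term selection
hard, not the linguistic content of any real corpus:

* a tiny relevant class (default 10 documents per topic) against a large
  non-relevant remainder (default 1000 documents);
* per topic, two dedicated query terms planted at the *same* rate in
  relevant documents and in a block of distractor documents (default 20),
  so the unexpanded query cannot separate the two groups;
* planted topical terms in two flavours: *spread* terms occurring once in
  a `df_concentration` fraction of the relevant documents and nowhere
  else, and *burst* terms carrying all their occurrences (default 10) in
  one relevant document plus a small leak (tf 2 and 1) into two
  non-relevant documents — the worked-example pattern.  `tf_burst` sets
  the fraction of planted terms that are bursty
  (`round(tf_burst · topical_terms_per_topic)` of them, deterministically);
* background tokens drawn from a Zipf distribution (exponent 1.1) over a
  2000-word vocabulary, document lengths Poisson around 60 with floor 5.

All randomness flows from one `numpy` generator seeded by the spec, so a
bundle is a pure function of (spec, seed).  What passing tests on these
bundles show is that the pipeline recovers planted co-topical structure
and that tf- and df-based metrics disagree in the designed direction; they
do not show anything about morphology, phrase structure, topic drift
between near-duplicate documents, or judged-pool incompleteness in real
collections.

The 10-document worked example is constructed exactly (no randomness):
feedback class D01–D04 via retrieval at depth 4, burst term t1 with tf
10/2/1 in D04/D05/D06, spread terms t2–t5 in three feedback documents
each, 24 background terms spanning one feedback and one outside document,
and 21 terms confined to the non-feedback documents.

The printed 18- and 16-row benchmark score tables (N = 162 259, |R| = 40)
ship as frozen fixtures.  Their typesetting runs columns together; rows
were disambiguated by recomputing each statistic from its own
document-frequency cells, and every stored value agrees with that
recomputation to the printed precision.

## Problem sizes and numerics

The acceptance script uses 1000-document bundles, 5 topics, 20 seeds for
recovery; 10 000 random tables for the chi-square oracle; 1 000 random
rankings for the AP oracle — sizes chosen so the whole suite runs in
seconds on one core while keeping the binomial win-count test meaningful.
All score comparisons in tests use relative tolerances (1e-3 against
printed 6-significant-digit values, 1e-9 against the independent oracle,
1e-12 against closed forms).  No floating-point accumulation tricks are
needed at these scales; sums are plain Python/numpy arithmetic.

## Known limitations

* Re-retrieval re-scores the whole corpus rather than re-ranking the first
  pass's list; on corpora where expansion terms match many new documents
  the two differ.
* Expansion terms are unweighted; no Rocchio-style weighting or relevance-
  model interpolation of the final query.
* Single feedback iteration; no judged (interactive) feedback.
* The index is an in-memory Python structure suitable for desk-scale
  corpora (up to roughly 10⁵ short documents), not a compressed
  production index; co-occurrence statistics intersect posting sets
  eagerly.
* HTML/boilerplate stripping is out of scope — the readers consume clean
  text.
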