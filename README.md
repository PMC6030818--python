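# prfqe — pseudo-relevance-feedback query expansion with DFC term selection

Biomedical literature retrieval suffers badly from vocabulary mismatch: a
query about a "medical practitioner" misses every document that only says
"physician", and genes, drugs and diseases carry many synonyms.  Pseudo
relevance feedback (PRF) mitigates this without any thesaurus: retrieve with
the raw query, assume the top *k* documents are relevant, mine their
vocabulary for expansion terms, append the best *n* of them, and retrieve
again.  Everything hinges on how "the best" terms are scored.

`prfqe` implements this loop end to end for researchers studying expansion
term selection:

* **Okapi BM25** retrieval over an inverted index built from plain-text or
  TREC-tagged corpora, with the Robertson–Sparck-Jones (RSJ) term weight

  ```
  w(t) = log [ (rt+0.5)/(R−rt+0.5) ] / [ (n−rt+0.5)/(N−n−R+rt+0.5) ]
  ```

  which reduces to the familiar IDF-like `log((N−n+0.5)/(n+0.5))` in the
  blind first pass (R = rt = 0).

* **Nine term-selection metrics**: KLD, tf-based chi-square and its
  un-squared variant, co-occurrence (CoDice/codegree), information gain,
  the probabilistic relevance-feedback ratio, the Lavrenko relevance-model
  score, the Robertson selection value — and **document-frequency
  chi-square (DFC)**, a Pearson chi-square on the 2×2 table of term
  presence/absence against the pseudo-relevant/non-relevant split:

  ```
  DFC(t) =  (tdfr − tdfc·ratio_r)² / (tdfc·ratio_r)
          + (tdfr̄ − tdfc̄·ratio_r)² / (tdfc̄·ratio_r)
          + (tdfnr − tdfc·ratio_nr)² / (tdfc·ratio_nr)
          + (tdfnr̄ − tdfc̄·ratio_nr)² / (tdfc̄·ratio_nr)
  ```

  where `tdfr`/`tdfnr` count *documents* in the relevant/non-relevant class
  containing `t`, `tdfc = tdfr + tdfnr`, bars denote absence counts, and
  `ratio_r`, `ratio_nr` are the class-size fractions of the corpus.
  Because DFC sees binary document presence instead of raw term frequency,
  a term whose occurrences pile up inside a single feedback document cannot
  masquerade as discriminative — the failure mode of tf-based chi-square
  when the feedback threshold misclassifies documents.

* **Evaluation**: TREC qrels and run files, average precision and MAP,
  (k docs × n terms × metric) test-point grids over stemmed and unstemmed
  indexes, and the per-cell stemming delta MAP(unstemmed) − MAP(stemmed).

* **Synthetic collections**: a seeded generator that plants topical terms
  with controllable document-frequency concentration and term-frequency
  burstiness into a Zipf background, so tf- and df-based metrics disagree
  on demand and every pipeline stage is testable at desk scale.

Pre-processing is lowercasing, splitting on non-alphanumerics (gene
variants like `v600e` survive intact), the classic 33-word Solr English
stoplist, and optionally the original 1980 Porter stemmer (implemented in
`prfqe.stemming`).

## Worked example

The canonical burst illustration: ten documents, feedback threshold after
D04, and a term `t1` occurring 10 times in the single feedback document D04,
twice in D05 and once in D06.

```python
from prfqe import *
from prfqe.synthetic import worked_example_corpus

bundle = worked_example_corpus()
index = build_index(bundle.documents)
topic = bundle.topics[0]

feedback = set(retrieve(topic, index, depth=4).doc_ids())
c = compute_contingency("t1", feedback, index)
print(f"t1 table: tdfr={c.tdfr} tdfr_bar={c.tdfr_bar} "
      f"tdfnr={c.tdfnr} tdfnr_bar={c.tdfnr_bar}")
print(f"dfc(t1) = {dfc_score(c):.4f}")

pool = build_term_pool(feedback, index, topic)
for metric in ("chi_square", "dfc"):
    ranked = rank_terms(metric, pool, index, feedback, topic)
    t1 = next(ts.rank for ts in ranked if ts.term == "t1")
    print(f"{metric:>10}: t1 rank {t1}/{len(ranked)}")
```

prints

```
t1 table: tdfr=1 tdfr_bar=3 tdfnr=2 tdfnr_bar=4
dfc(t1) = 0.0794
chi_square: t1 rank 1/29
       dfc: t1 rank 29/29
```

tf-based chi-square crowns the burst term; DFC, seeing that `t1` is in one
feedback document but two non-relevant ones, puts it dead last — the
behaviour that motivates the metric.

## Command line

```sh
prf simulate --out sim --seed 7 --n-docs 1000          # synthetic collection
prf run --topics sim/topics.tsv --corpus sim/corpus \
        --metric dfc --k-docs 10 --n-terms 5 --out run.trec
prf eval --run run.trec --qrels sim/qrels.txt          # per-topic AP + MAP
```

Runs are fully deterministic: identical inputs yield byte-identical run
files.

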