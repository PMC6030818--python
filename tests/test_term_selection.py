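import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from prfqe.corpus_io import Document, Topic, build_index
from prfqe.retrieval import RelevanceCounts, rsj_weight
from prfqe.synthetic import table_fixture
from prfqe.term_selection import (
    METRICS,
    ClassModel,
    ContingencyStats,
    CoocStats,
    TermDistribution,
    chi_one_score,
    chi_square_score,
    codegree,
    codice,
    compute_contingency,
    cooccurrence_final,
    dfc_score,
    ig_score,
    kld_score,
    lrf_score,
    prf_metric_score,
    rank_terms,
    rsv_score,
)


# ---------------------------------------------------------------- contingency

def test_contingency_worked_example(worked_index, worked_feedback):
    c = compute_contingency("t1", worked_feedback, worked_index)
    assert (c.tdfr, c.tdfr_bar, c.tdfnr, c.tdfnr_bar) == (1, 3, 2, 4)
    assert c.tdfc == 3 and c.tdfc_bar == 7
    assert c.ratio_r + c.ratio_nr == pytest.approx(1.0)


def test_contingency_term_only_in_feedback():
    docs = [Document(f"d{i}", "x filler" if i < 3 else "filler pad") for i in range(8)]
    idx = build_index(docs)
    c = compute_contingency("x", {"d0", "d1", "d2"}, idx)
    assert (c.tdfr, c.tdfr_bar, c.tdfnr, c.tdfnr_bar) == (3, 0, 0, 5)


def test_contingency_unknown_term_raises(worked_index, worked_feedback):
    with pytest.raises(KeyError):
        compute_contingency("absent", worked_feedback, worked_index)


# ------------------------------------------------------------------------ DFC

def _table_stats():
    return [(row.term, row.contingency(), row.dfc) for row in
            table_fixture("table4") + table_fixture("table5")]


@pytest.mark.parametrize("term, stats, printed", _table_stats(),
                         ids=[r[0] for r in _table_stats()])
def test_dfc_reproduces_every_printed_table_row(term, stats, printed):
    """All 34 printed DFC scores reproduce from their printed df cells."""
    assert dfc_score(stats) == pytest.approx(printed, rel=1e-3)


def test_dfc_zero_under_perfect_proportionality():
    # 10 docs, 5 relevant, term in 1 relevant + 1 non-relevant: obs == exp
    c = ContingencyStats(tdfr=1, tdfr_bar=4, tdfnr=1, tdfnr_bar=4)
    assert dfc_score(c) == pytest.approx(0.0, abs=1e-12)


def test_dfc_errors_on_degenerate_tables():
    with pytest.raises(ValueError):
        dfc_score(ContingencyStats(tdfr=0, tdfr_bar=4, tdfnr=0, tdfnr_bar=6))
    with pytest.raises(ValueError):
        dfc_score(ContingencyStats(tdfr=4, tdfr_bar=0, tdfnr=6, tdfnr_bar=0))


contingency_tables = st.tuples(
    st.integers(0, 50), st.integers(0, 50), st.integers(0, 500), st.integers(0, 500)
).filter(
    lambda t: 0 < t[0] + t[2] and 0 < t[1] + t[3]  # tdfc >= 1 and tdfc_bar >= 1
    and t[0] + t[1] > 0 and t[2] + t[3] > 0        # both classes non-empty
)


@settings(deadline=None, max_examples=300)
@given(contingency_tables)
def test_dfc_equals_generic_pearson_chi_square(cells):
    """Margin-product expected counts: DFC == textbook Pearson chi-square."""
    from scipy.stats import chi2_contingency

    tdfr, tdfr_bar, tdfnr, tdfnr_bar = cells
    c = ContingencyStats(tdfr=tdfr, tdfr_bar=tdfr_bar, tdfnr=tdfnr, tdfnr_bar=tdfnr_bar)
    ours = dfc_score(c)
    ref = chi2_contingency(
        np.array([[tdfr, tdfnr], [tdfr_bar, tdfnr_bar]]), correction=False
    ).statistic
    assert ours == pytest.approx(ref, rel=1e-9, abs=1e-9)
    assert ours >= 0


@settings(deadline=None, max_examples=100)
@given(contingency_tables)
def test_dfc_symmetric_under_class_swap(cells):
    tdfr, tdfr_bar, tdfnr, tdfnr_bar = cells
    a = ContingencyStats(tdfr, tdfr_bar, tdfnr, tdfnr_bar)
    b = ContingencyStats(tdfnr, tdfnr_bar, tdfr, tdfr_bar)
    assert dfc_score(a) == pytest.approx(dfc_score(b), rel=1e-12)


# ---------------------------------------------------------------- chi-square

def test_chi_square_reproduces_printed_probability_rows():
    rows = {r.term: r for r in table_fixture("table5")}
    for term in ("fetuin", "etidronate"):
        r = rows[term]
        got = chi_square_score(TermDistribution(p_rel=r.p_rel, p_corpus=r.p_corpus))
        assert got == pytest.approx(r.cs, rel=1e-3)


def test_chi_square_zero_when_distributions_agree():
    assert chi_square_score(TermDistribution(0.01, 0.01)) == 0.0
    with pytest.raises(ValueError):
        chi_square_score(TermDistribution(0.01, 0.0))


def test_chi_one_is_signed_relative_lift():
    assert chi_one_score(TermDistribution(0.01, 0.01)) == 0.0
    assert chi_one_score(TermDistribution(0.02, 0.01)) == pytest.approx(1.0)
    assert chi_one_score(TermDistribution(0.0029, 1.7e-6)) == pytest.approx(1704.88, rel=1e-4)
    assert chi_one_score(TermDistribution(0.001, 0.002)) < 0


# ----------------------------------------------------------------------- KLD

def test_kld_values_and_sign():
    assert kld_score(TermDistribution(0.01, 0.01)) == 0.0
    expected = 0.0029 * math.log(0.0029 / 1.7e-6)
    assert kld_score(TermDistribution(0.0029, 1.7e-6)) == pytest.approx(expected, rel=1e-12)
    assert expected == pytest.approx(0.02158, abs=2e-4)
    assert kld_score(TermDistribution(0.001, 0.002)) < 0
    with pytest.raises(ValueError):
        kld_score(TermDistribution(0.0, 0.01))


# -------------------------------------------------------------- co-occurrence

def test_codice_jaccard_form():
    assert codice(CoocStats(10, 5, 0, 100, 5, 10)) == 0.0
    assert codice(CoocStats(4, 4, 4, 100, 4, 10)) == 1.0
    assert codice(CoocStats(10, 5, 3, 100, 5, 10)) == pytest.approx(0.25)
    with pytest.raises(ValueError):
        CoocStats(2, 2, 3, 100, 2, 10)  # df_ij > min(df_i, df_j)


def test_codegree_values():
    assert codegree(CoocStats(10, 5, 0, 100, 5, 10)) == 0.0
    assert codegree(CoocStats(10, 5, 3, 100, 100, 10)) == 0.0  # Nc == N -> IDF 0
    got = codegree(CoocStats(10, 5, 3, 1000, 10, 10))
    assert got == pytest.approx(math.log10(1.25) * 2.0 / 1.0, rel=1e-12)
    assert got == pytest.approx(0.19382, abs=1e-5)
    with pytest.raises(ValueError):
        codegree(CoocStats(10, 5, 3, 1000, 10, 1))  # D < 2


def test_cooccurrence_final_is_a_product():
    s1 = CoocStats(10, 5, 3, 1000, 10, 10)
    s0 = CoocStats(10, 5, 0, 1000, 10, 10)
    assert cooccurrence_final([s1]) == codegree(s1)
    assert cooccurrence_final([s1, s0]) == 0.0
    assert cooccurrence_final([s1, s1]) == pytest.approx(codegree(s1) ** 2)


# ------------------------------------------------------------------------- IG

def test_ig_zero_for_class_independent_term():
    m = ClassModel(p_class=(0.3, 0.7), p_term=0.4,
                   cond_given_t=(0.3, 0.7), cond_given_not_t=(0.3, 0.7))
    assert ig_score(m) == pytest.approx(0.0, abs=1e-12)


def test_ig_perfect_predictor_equals_class_entropy():
    m = ClassModel(p_class=(0.5, 0.5), p_term=0.5,
                   cond_given_t=(1.0, 0.0), cond_given_not_t=(0.0, 1.0))
    assert ig_score(m) == pytest.approx(math.log(2), rel=1e-12)


def test_ig_matches_mutual_information_oracle():
    """Brute-force mutual information of the joint (term, class) table."""
    p_c1, p_t, c1_t, c1_nt = 0.5, 0.5, 0.8, 0.2
    joint = {
        ("t", "c1"): p_t * c1_t,
        ("t", "c2"): p_t * (1 - c1_t),
        ("nt", "c1"): (1 - p_t) * c1_nt,
        ("nt", "c2"): (1 - p_t) * (1 - c1_nt),
    }
    pt = {"t": p_t, "nt": 1 - p_t}
    pc = {"c1": p_c1, "c2": 1 - p_c1}
    mi = sum(p * math.log(p / (pt[a] * pc[b])) for (a, b), p in joint.items() if p > 0)
    m = ClassModel(p_class=(p_c1, 1 - p_c1), p_term=p_t,
                   cond_given_t=(c1_t, 1 - c1_t), cond_given_not_t=(c1_nt, 1 - c1_nt))
    got = ig_score(m)
    assert got == pytest.approx(mi, rel=1e-12)
    assert got == pytest.approx(0.19274, abs=1e-5)


# ------------------------------------------------------------------ PRF ratio

def test_prf_ratio():
    assert prf_metric_score(TermDistribution(0.01, 0.5, p_nonrel=0.002)) == pytest.approx(5.0)
    assert prf_metric_score(TermDistribution(0.01, 0.5, p_nonrel=0.01)) == pytest.approx(1.0)
    with pytest.raises(ValueError):
        prf_metric_score(TermDistribution(0.01, 0.5, p_nonrel=0.0))


# ----------------------------------------------------------------------- LRF

def test_lrf_single_doc_closed_form():
    idx = build_index([Document("d", "t " + "pad " * 9)])  # tf ratio 0.1
    got = lrf_score("t", ["d"], idx, lambda_mix=0.6, p_collection=0.01)
    assert got == pytest.approx(math.log((0.6 * 0.1 + 0.4 * 0.01) / 0.01), rel=1e-12)
    assert got == pytest.approx(math.log(6.4), rel=1e-12)


def test_lrf_zero_when_doc_model_equals_collection_model():
    idx = build_index([Document("d", "t pad pad pad")])  # tf ratio 0.25
    assert lrf_score("t", ["d"], idx, 0.6, p_collection=0.25) == pytest.approx(0.0)


def test_lrf_vanishes_as_lambda_goes_to_zero():
    idx = build_index([Document("d", "t " + "pad " * 9), Document("e", "pad other")])
    big = abs(lrf_score("t", ["d"], idx, 0.5))
    tiny = abs(lrf_score("t", ["d"], idx, 1e-9))
    assert tiny < 1e-6 < big


# ----------------------------------------------------------------------- RSV

def test_rsv_zero_and_linear_in_tdfr():
    c0 = ContingencyStats(tdfr=0, tdfr_bar=10, tdfnr=20, tdfnr_bar=970)
    assert rsv_score(c0) == 0.0
    c = ContingencyStats(tdfr=5, tdfr_bar=5, tdfnr=15, tdfnr_bar=975)
    expected = 5 * rsj_weight(RelevanceCounts(R=10, rt=5, N=1000, n=20))
    assert rsv_score(c) == pytest.approx(expected, rel=1e-12)


# ----------------------------------------------------------------- rank_terms

def test_rank_terms_single_term(worked_index, worked_feedback, worked_bundle):
    out = rank_terms("dfc", {"t1"}, worked_index, worked_feedback, worked_bundle.topics[0])
    assert len(out) == 1 and out[0].rank == 1 and out[0].term == "t1"


def test_rank_terms_ties_broken_lexicographically(worked_index, worked_feedback, worked_bundle):
    # t2..t5 share the identical df pattern, hence identical DFC scores
    out = rank_terms("dfc", {"t2", "t5", "t3", "t4"}, worked_index,
                     worked_feedback, worked_bundle.topics[0])
    assert [ts.term for ts in out] == ["t2", "t3", "t4", "t5"]
    assert [ts.rank for ts in out] == [1, 2, 3, 4]
    assert len({ts.score for ts in out}) == 1


def test_rank_terms_excludes_query_terms(worked_index, worked_feedback, worked_bundle):
    out = rank_terms("dfc", {"genes", "t1"}, worked_index, worked_feedback,
                     worked_bundle.topics[0])
    assert [ts.term for ts in out] == ["t1"]


def test_rank_terms_unknown_metric_lists_names(worked_index, worked_feedback, worked_bundle):
    with pytest.raises(ValueError, match="dfc"):
        rank_terms("bogus", {"t1"}, worked_index, worked_feedback, worked_bundle.topics[0])


def test_calipel_tops_table4_under_dfc():
    rows = table_fixture("table4")
    assert len(rows) == 18
    ranked = sorted(rows, key=lambda r: (-dfc_score(r.contingency()), r.term))
    assert ranked[0].term == "calipel"


@pytest.mark.parametrize("metric", METRICS)
def test_every_metric_ranks_the_worked_pool(metric, worked_index, worked_feedback,
                                            worked_bundle, worked_pool):
    out = rank_terms(metric, worked_pool, worked_index, worked_feedback,
                     worked_bundle.topics[0])
    assert [ts.rank for ts in out] == list(range(1, len(out) + 1))
    scores = [ts.score for ts in out]
    assert scores == sorted(scores, reverse=True)
    assert all(math.isfinite(s) for s in scores)
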