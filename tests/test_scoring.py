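"""Publication-centric and term-centric similarity scoring."""

from __future__ import annotations

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from gota.indexing import PublicationIndex, TermIndex, index_publication
from gota.ontology import AnnotationSet
from gota.pubcentric import (
    Neighbor,
    Params,
    phi_P,
    pub_features,
    rank_neighbors,
    score_terms_pubcentric,
    year_similarity,
)
from gota.termcentric import phi_T, phrase_occurrences, term_features
from gota.textprep import WeightedVector

unit = st.floats(min_value=0.0, max_value=1.0, allow_nan=False)


def _pub_index(w=None, t=None, r=None, y=None, raw=""):
    return PublicationIndex(
        W=WeightedVector(w or {}),
        T=WeightedVector(t or {}),
        R=WeightedVector(r or {}),
        Y=y,
        raw_text=raw,
    )


def _term_index(w=None, t=None, y=None, phrases=("x",), stems=frozenset({"x"})):
    return TermIndex(
        W=WeightedVector(w or {}), T=WeightedVector(t or {}),
        Y=y, phrases=phrases, title_stems=stems,
    )


class TestPubFeatures:
    def test_identical_publications(self):
        a = _pub_index(w={"k": 1.0}, t={"k": 1.0}, r={"9": 2.0}, y=2000)
        assert pub_features(a, a) == (1.0, 1.0, 1.0, 1.0)

    def test_identical_without_references(self):
        a = _pub_index(w={"k": 1.0}, t={"k": 1.0}, y=2000)
        assert pub_features(a, a) == (1.0, 1.0, 0.0, 1.0)

    @pytest.mark.parametrize(("dy", "expected"), [
        (60, 0.0), (51, 0.0), (50, 0.0), (25, 0.5), (0, 1.0),
    ])
    def test_year_window(self, dy, expected):
        assert year_similarity(2000, 2000 + dy) == pytest.approx(expected)

    def test_missing_year_gives_zero(self):
        assert year_similarity(None, 2000) == 0.0
        assert year_similarity(2000, None) == 0.0


class TestPhiP:
    def test_all_zero_features_give_one(self):
        a = _pub_index(w={"k": 1.0})
        b = _pub_index(w={"z": 1.0})
        assert phi_P(a, b, Params()) == 1.0

    def test_single_feature_power(self):
        a = _pub_index(w={"k": 1.0})
        assert phi_P(a, a, Params(m=(4, 0, 0, 0))) == pytest.approx(16.0)

    def test_default_param_product(self):
        # f1 = 0.5 and f3 = 0.5 with m = (4,1,3,1): 1.5^4 * 1.5^3
        a = _pub_index(w={"k": 1.0, "z": 1.0}, r={"1": 1.0, "2": 1.0})
        b = _pub_index(w={"k": 1.0, "q": 1.0}, r={"1": 1.0, "3": 1.0})
        assert phi_P(a, b, Params()) == pytest.approx(1.5**4 * 1.5**3)

    def test_missing_feature_equals_zero_feature(self):
        # absent year vs identical-structure pair with year similarity 0
        a = _pub_index(w={"k": 1.0}, y=None)
        b1 = _pub_index(w={"k": 1.0}, y=None)
        b2 = _pub_index(w={"k": 1.0}, y=None)
        a_with = _pub_index(w={"k": 1.0}, y=2000)
        b_far = _pub_index(w={"k": 1.0}, y=2100)  # dy > 50 -> f4 = 0
        assert phi_P(a, b1, Params()) == phi_P(a_with, b_far, Params())
        assert phi_P(a, b2, Params()) >= 1.0

    @settings(deadline=None, derandomize=True)
    @given(f=st.tuples(unit, unit, unit, unit))
    def test_always_at_least_one(self, f):
        score = 1.0
        for fi, mi in zip(f, Params().m):
            score *= (1.0 + fi) ** mi
        assert score >= 1.0


class TestRankNeighbors:
    def test_single_publication_kb(self):
        q = _pub_index(w={"k": 1.0})
        kb = {"10": _pub_index(w={"k": 1.0})}
        nbs = rank_neighbors(q, kb, Params(K=150))
        assert [n.pmid for n in nbs] == ["10"]

    def test_tie_broken_by_ascending_pmid(self):
        q = _pub_index(w={"k": 1.0})
        kb = {"20": _pub_index(w={"z": 1.0}), "10": _pub_index(w={"z": 1.0})}
        assert [n.pmid for n in rank_neighbors(q, kb, Params())] == ["10", "20"]

    def test_matches_exhaustive_sort(self, small_bundle, small_index):
        params = Params(K=5)
        query = small_bundle.queries[0]
        q = index_publication(query, small_index.model)
        scored = sorted(
            (-phi_P(q, p, params), pmid)
            for pmid, p in small_index.publications.items()
        )
        expected = [pmid for _, pmid in scored[:5]]
        got = [n.pmid for n in rank_neighbors(q, small_index.publications, params)]
        assert got == expected

    def test_leave_one_out_excludes_query(self, small_index):
        pmid = next(iter(small_index.publications))
        q = small_index.publications[pmid]
        nbs = rank_neighbors(q, small_index.publications, Params(),
                             exclude_pmid=pmid)
        assert pmid not in {n.pmid for n in nbs}

    def test_empty_kb_is_error(self):
        with pytest.raises(ValueError, match="empty"):
            rank_neighbors(_pub_index(w={"k": 1.0}), {}, Params())


class TestScoreTermsPubcentric:
    def test_single_neighbor_transfers_weight(self):
        gold = AnnotationSet({"10": frozenset({"GO:0000001"})})
        scores = score_terms_pubcentric([Neighbor("10", 2.5)], gold)
        assert scores == {"GO:0000001": 2.5}

    def test_weights_sum_over_neighbors(self):
        gold = AnnotationSet({
            "10": frozenset({"GO:0000001"}),
            "20": frozenset({"GO:0000001", "GO:0000002"}),
        })
        scores = score_terms_pubcentric(
            [Neighbor("10", 2.0), Neighbor("20", 3.0)], gold
        )
        assert scores["GO:0000001"] == pytest.approx(5.0)
        assert scores["GO:0000002"] == pytest.approx(3.0)

    def test_unannotated_terms_absent(self):
        gold = AnnotationSet({"10": frozenset({"GO:0000001"})})
        scores = score_terms_pubcentric([Neighbor("10", 2.0)], gold)
        assert "GO:0000002" not in scores

    def test_adding_annotated_neighbor_never_decreases_score(self):
        gold = AnnotationSet({
            "10": frozenset({"GO:0000001"}),
            "20": frozenset({"GO:0000001"}),
        })
        one = score_terms_pubcentric([Neighbor("10", 2.0)], gold)
        two = score_terms_pubcentric(
            [Neighbor("10", 2.0), Neighbor("20", 1.0)], gold
        )
        assert two["GO:0000001"] >= one["GO:0000001"]


class TestTermFeatures:
    def test_g3_fraction_of_title_stems_present(self):
        q = _pub_index(w={"a": 1.0, "z": 1.0})
        t = _term_index(stems=frozenset({"a", "b"}))
        assert term_features(q, t)[2] == pytest.approx(0.5)

    @pytest.mark.parametrize(("count", "expected"), [
        (0, 0.0), (2, 0.5), (4, 1.0), (7, 1.0),
    ])
    def test_g4_normalization(self, count, expected):
        raw = " ".join(["signal phrase"] * count) or "nothing here"
        q = _pub_index(w={"a": 1.0}, raw=raw)
        t = _term_index(phrases=("signal phrase",))
        assert term_features(q, t)[3] == pytest.approx(expected)

    def test_g4_case_insensitive_whitespace_normalized(self):
        q = _pub_index(w={"a": 1.0}, raw="The  Signal   Phrase appears")
        t = _term_index(phrases=("signal phrase",))
        assert term_features(q, t)[3] == pytest.approx(0.25)

    def test_g4_sums_over_synonyms(self):
        q = _pub_index(w={"a": 1.0}, raw="alpha beta alpha")
        t = _term_index(phrases=("alpha", "beta"))
        assert term_features(q, t)[3] == pytest.approx(3 / 4)

    def test_overlapping_occurrences_counted_by_offset(self):
        assert phrase_occurrences("aaaa", ("aa",)) == 3

    def test_empty_title_stems_is_error(self):
        q = _pub_index(w={"a": 1.0})
        with pytest.raises(ValueError, match="title stems"):
            term_features(q, _term_index(stems=frozenset()))

    def test_self_retrieval_saturates_g3_g4(self):
        # query literally contains the term name and all its title stems
        q = _pub_index(
            w={"signal": 1.0, "phrase": 1.0},
            raw="signal phrase signal phrase signal phrase signal phrase",
        )
        t = _term_index(phrases=("signal phrase",),
                        stems=frozenset({"signal", "phrase"}))
        g = term_features(q, t)
        assert g[2] == 1.0 and g[3] == 1.0


class TestPhiT:
    def test_all_zero_features_give_one(self):
        q = _pub_index(w={"q": 1.0}, raw="nothing matches")
        t = _term_index(w={"z": 1.0}, stems=frozenset({"x"}))
        assert phi_T(q, t, Params()) == 1.0

    def test_single_feature_power(self):
        q = _pub_index(w={"k": 1.0}, raw="")
        t = _term_index(w={"k": 1.0}, stems=frozenset({"zz"}))
        assert phi_T(q, t, Params(n=(4, 0, 0, 0, 0))) == pytest.approx(16.0)

    def test_default_param_product(self):
        # g1=0.5, g3=1, g4=0.25 with n=(4,1,2,1,1): 1.5^4 * 2^2 * 1.25
        q = _pub_index(w={"k": 1.0, "z": 1.0}, raw="signal phrase here")
        t = _term_index(w={"k": 1.0, "q": 1.0},
                        phrases=("signal phrase",), stems=frozenset({"k", "z"}))
        assert phi_T(q, t, Params()) == pytest.approx(1.5**4 * 4 * 1.25)

    def test_unstructured_query_disables_g2_g5(self):
        # no title vector and no year: only g1/g3/g4 can contribute
        q = _pub_index(w={"k": 1.0}, raw="")
        t = _term_index(w={"k": 1.0}, t={"k": 1.0}, y=2000,
                        stems=frozenset({"zz"}))
        assert phi_T(q, t, Params()) == pytest.approx(
            phi_T(q, t, Params(n=(4, 0, 2, 1, 0)))
        )

    @settings(deadline=None, derandomize=True)
    @given(g=st.tuples(unit, unit, unit, unit, unit),
           i=st.integers(min_value=0, max_value=4),
           eps=st.floats(min_value=0.001, max_value=0.2))
    def test_monotone_in_each_feature(self, g, i, eps):
        def product(gs):
            out = 1.0
            for gi, ni in zip(gs, Params().n):
                out *= (1.0 + gi) ** ni
            return out

        bumped = list(g)
        bumped[i] = min(1.0, bumped[i] + eps)
        assert product(bumped) >= product(g)
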