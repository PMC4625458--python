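"""The combined classifier and the two naive baselines.

A query's relatedness to a GO term multiplies the two scores:

    Phi(q, t) = Phi_P(q, t) * Phi_T(q, t)

The publication-centric score acts as candidate generator (only terms
annotated to at least one top-K neighbor can be predicted); the
term-centric score re-weights those candidates. Predictions are ranked
by descending Phi with deterministic ascending-accession tie-breaks.

Baselines (identical output for every query):

    RandFR  ranks terms by their direct-annotation frequency in the KB
    RandIC  ranks each term by its mean information-theoretic precision
            against the KB publications' gold sets
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .corpus import Publication
from .indexing import KBIndex, PublicationIndex, index_publication
from .ontology import leaves, lin
from .pubcentric import Params, rank_neighbors, score_terms_pubcentric
from .termcentric import phi_T
from .textprep import EMPTY_VECTOR, tfidf_vector


@dataclass(frozen=True)
class Prediction:
    """Score-ranked GO term predictions for one query."""

    query_id: str
    ranked: tuple[tuple[str, float], ...]

    def __post_init__(self) -> None:
        seen = set()
        for term, score in self.ranked:
            if term in seen:
                raise ValueError(f"duplicate predicted term {term}")
            seen.add(term)
            if not (math.isfinite(score) and score > 0):
                raise ValueError(f"non-finite or non-positive score for {term}")

    @property
    def terms(self) -> tuple[str, ...]:
        return tuple(t for t, _ in self.ranked)

    def top_k(self, k: int) -> tuple[str, ...]:
        """P_k: the top-k ranked terms."""
        return self.terms[:k]

    def above(self, s: float) -> tuple[str, ...]:
        """P_s: predicted terms with score >= threshold s."""
        return tuple(t for t, score in self.ranked if score >= s)


def _rank(scores: dict[str, float], top_n: int | None) -> tuple[tuple[str, float], ...]:
    items = sorted(scores.items(), key=lambda kv: (-kv[1], kv[0]))
    if top_n is not None:
        items = items[:top_n]
    return tuple(items)


def index_query(
    query: Publication | str,
    index: KBIndex,
    text_is_title: bool = False,
) -> tuple[str, PublicationIndex]:
    """Turn a structured record or raw text into a query feature bundle.

    Raw text yields W only — the classifier cannot know whether free
    text is a title or an abstract, so T stays empty unless the caller
    marks the text as a title.
    """
    if isinstance(query, Publication):
        return query.pmid, index_publication(query, index.model)
    w = tfidf_vector(query, index.model)
    if w.is_empty():
        raise ValueError("no usable text: query has no in-vocabulary tokens")
    return "query", PublicationIndex(
        W=w,
        T=w if text_is_title else EMPTY_VECTOR,
        R=EMPTY_VECTOR,
        Y=None,
        raw_text=query,
    )


def predict(
    query: Publication | str,
    index: KBIndex,
    params: Params = Params(),
    top_n: int | None = 10,
    leave_one_out: bool = True,
    text_is_title: bool = False,
    rescore_all_terms: bool = False,
) -> Prediction:
    """Rank GO terms for a query by Phi = Phi_P * Phi_T.

    ``leave_one_out`` excludes the query's own PMID from neighbor
    ranking when it is present in the KB. ``rescore_all_terms`` is a
    diagnostic mode scoring Phi_T for the whole annotated vocabulary
    instead of only the Phi_P > 0 candidates.
    """
    query_id, q = index_query(query, index, text_is_title=text_is_title)
    exclude = query_id if leave_one_out and query_id in index.publications else None
    neighbors = rank_neighbors(q, index.publications, params, exclude_pmid=exclude)
    phi_p = score_terms_pubcentric(neighbors, index.gold)
    if rescore_all_terms:
        # diagnostic mode: Phi_P = 0 terms get Phi_T alone
        scores = {
            t: (phi_p.get(t, 0.0) or 1.0) * phi_T(q, index.terms[t], params)
            for t in set(phi_p) | set(index.annotated_terms)
        }
    else:
        scores = {t: w * phi_T(q, index.terms[t], params) for t, w in phi_p.items()}
    return Prediction(query_id=query_id, ranked=_rank(scores, top_n))


def baseline_randfr(index: KBIndex, top_n: int | None = 10) -> Prediction:
    """Rank terms by direct-annotation frequency in the KB (same for all queries)."""
    counts: dict[str, float] = {}
    for term_set in index.gold.assignments.values():
        for t in term_set:
            counts[t] = counts.get(t, 0.0) + 1.0
    if not counts:
        raise ValueError("knowledge base has no annotations")
    return Prediction(query_id="RandFR", ranked=_rank(counts, top_n))


def baseline_randic(index: KBIndex, top_n: int | None = 10) -> Prediction:
    """Rank each term by its mean information-theoretic precision over the KB.

    For a single-term prediction {t}, the information-theoretic
    precision against a gold set T is max over the leaf reduction L(T)
    of sim_Lin(t, .); RandIC averages that over all KB publications.
    Terms with zero score everywhere (e.g. roots) are excluded.
    """
    gold_leaves = [
        leaves(index.ontology, ts) for ts in index.gold.assignments.values()
    ]
    scores: dict[str, float] = {}
    for t in index.annotated_terms:
        total = 0.0
        for leaf_set in gold_leaves:
            total += max(lin(index.ontology, index.ic, t, g) for g in leaf_set)
        if total > 0:
            scores[t] = total / len(gold_leaves)
    if not scores:
        raise ValueError("no term has positive mean similarity")
    return Prediction(query_id="RandIC", ranked=_rank(scores, top_n))
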