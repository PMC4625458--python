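"""Publication-centric score: k-NN over the knowledge base.

A query q is compared with every KB publication p through four
similarity features in [0, 1]:

    f1  cosine(W(q), W(p))   text
    f2  cosine(T(q), T(p))   title
    f3  cosine(R(q), R(p))   shared weighted references
    f4  year proximity: 0 if |dY| > 50 or a year is absent,
        else (50 - |dY|) / 50

combined multiplicatively with integer exponents m_i acting as feature
weights:

    phi_P(q, p) = prod_i (1 + f_i)^{m_i}   >= 1

A feature that is missing or zero contributes a factor of 1, so absent
information never penalizes a pair. The gold annotations of the top-K
ranked publications are transferred to the query, each weighted by its
neighbor's phi_P:

    Phi_P(q, t) = sum over top-K neighbors p annotated with t of phi_P(q, p)
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

from .indexing import PublicationIndex
from .ontology import AnnotationSet
from .textprep import cosine

YEAR_WINDOW = 50


@dataclass(frozen=True)
class Params:
    """Scoring exponents and neighbor count.

    Defaults are the shipped operating point: m = (4, 1, 3, 1) for the
    publication features, n = (4, 1, 2, 1, 1) for the term features, and
    K = 150 neighbors (sensible range roughly 50-300).
    """

    m: tuple[int, int, int, int] = (4, 1, 3, 1)
    n: tuple[int, int, int, int, int] = (4, 1, 2, 1, 1)
    K: int = 150

    def __post_init__(self) -> None:
        if self.K < 1:
            raise ValueError("K must be >= 1")
        if len(self.m) != 4 or len(self.n) != 5:
            raise ValueError("expected 4 publication and 5 term exponents")
        if any(e < 0 for e in (*self.m, *self.n)):
            raise ValueError("exponents must be non-negative")
        if any(e > 4 for e in (*self.m, *self.n)):
            warnings.warn("exponents above 4 are outside the tuned range", stacklevel=2)


@dataclass(frozen=True)
class Neighbor:
    pmid: str
    score: float  # phi_P value, always >= 1


def year_similarity(y1: int | None, y2: int | None) -> float:
    """Year proximity on a 50-year window; 0 when either year is absent."""
    if y1 is None or y2 is None:
        return 0.0
    dy = abs(y1 - y2)
    if dy > YEAR_WINDOW:
        return 0.0
    return (YEAR_WINDOW - dy) / YEAR_WINDOW


def pub_features(q: PublicationIndex, p: PublicationIndex) -> tuple[float, float, float, float]:
    """The four query-publication similarity features (f1..f4), each in [0, 1]."""
    return (
        cosine(q.W, p.W),
        cosine(q.T, p.T),
        cosine(q.R, p.R),
        year_similarity(q.Y, p.Y),
    )


def phi_P(q: PublicationIndex, p: PublicationIndex, params: Params) -> float:
    """phi_P(q, p) = prod (1 + f_i)^{m_i}; missing features contribute 1."""
    score = 1.0
    for f, m in zip(pub_features(q, p), params.m):
        if m and f:
            score *= (1.0 + f) ** m
    return score


def rank_neighbors(
    q: PublicationIndex,
    kb_index: dict[str, PublicationIndex],
    params: Params,
    exclude_pmid: str | None = None,
) -> list[Neighbor]:
    """Rank KB publications by phi_P, descending; return the top K.

    Ties break by ascending PMID string for determinism. When
    ``exclude_pmid`` is given (leave-one-out), that publication is
    skipped.
    """
    if not kb_index:
        raise ValueError("empty knowledge base")
    scored = [
        (-phi_P(q, p, params), pmid)
        for pmid, p in kb_index.items()
        if pmid != exclude_pmid
    ]
    if not scored:
        raise ValueError("no candidate neighbors (KB held only the query)")
    scored.sort()
    return [Neighbor(pmid=pmid, score=-neg) for neg, pmid in scored[: params.K]]


def score_terms_pubcentric(
    neighbors: list[Neighbor], gold: AnnotationSet
) -> dict[str, float]:
    """Phi_P(q, t): phi_P-weighted vote of the neighbors' direct gold terms."""
    if not neighbors:
        raise ValueError("no neighbors to transfer annotations from")
    scores: dict[str, float] = {}
    for nb in neighbors:
        for t in gold.assignments.get(nb.pmid, ()):
            scores[t] = scores.get(t, 0.0) + nb.score
    return scores
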