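"""Term-centric score: direct comparison between a query and a GO term.

Five features in [0, 1]:

    g1  cosine(W(q), W(t))             text
    g2  cosine(T(q), T(t))             title vs term name
    g3  fraction of the term's title stems present in the query BoW
    g4  occurrences of the term's full name / synonyms in the raw query
        text, capped and normalized to 4 (1 if more than 4)
    g5  year proximity (as f4)

combined as Phi_T(q, t) = prod_i (1 + g_i)^{n_i} >= 1. With unstructured
text queries only g1, g3 and g4 can be non-zero: there is no separate
title (unless the caller marks the text as one) and no year, so g2 and
g5 vanish automatically.

The g4 phrase match is a case-insensitive, whitespace-normalized
substring scan of the raw (unstemmed) text: stemming would destroy the
multi-word names it looks for. Occurrence counts are summed over the
name and all synonyms.
"""

from __future__ import annotations

from .indexing import PublicationIndex, TermIndex
from .pubcentric import Params, year_similarity
from .textprep import cosine

G4_CAP = 4


def _count_occurrences(haystack: str, needle: str) -> int:
    """Occurrences at distinct start offsets (overlap allowed)."""
    count = start = 0
    while True:
        i = haystack.find(needle, start)
        if i < 0:
            return count
        count += 1
        start = i + 1


def phrase_occurrences(raw_text: str, phrases: tuple[str, ...]) -> int:
    """Total occurrences of the (already normalized) phrases in raw text."""
    hay = " ".join(raw_text.lower().split())
    return sum(_count_occurrences(hay, p) for p in phrases if p)


def term_features(
    q: PublicationIndex, t: TermIndex
) -> tuple[float, float, float, float, float]:
    """The five query-term similarity features (g1..g5), each in [0, 1]."""
    if not t.title_stems:
        raise ValueError("term index has no title stems")
    g1 = cosine(q.W, t.W)
    g2 = cosine(q.T, t.T)
    g3 = len(t.title_stems & q.W.support) / len(t.title_stems)
    c = phrase_occurrences(q.raw_text, t.phrases)
    g4 = 1.0 if c > G4_CAP else c / G4_CAP
    g5 = year_similarity(q.Y, t.Y)
    return (g1, g2, g3, g4, g5)


def phi_T(q: PublicationIndex, t: TermIndex, params: Params) -> float:
    """Phi_T(q, t) = prod (1 + g_i)^{n_i}; missing features contribute 1."""
    score = 1.0
    for g, n in zip(term_features(q, t), params.n):
        if n and g:
            score *= (1.0 + g) ** n
    return score
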