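"""Text preprocessing: tokenization, tf-idf weighting, and cosine similarity.

Publications and ontology terms are represented as sparse bags of words
(BoW). Tokens are lowercased, split on non-alphanumeric characters,
stopword-filtered, and Porter-stemmed; weights follow the tf-idf scheme

    tf(w, x)  = count of w in x / total tokens in x
    idf(w)    = ln(N / df(w)),  N = number of publications + ontology terms

where document frequency df counts each publication (title + abstract) and
each ontology term (name + synonyms + description) once. Cited references
are weighted with an analogous idf over bibliographies:

    idf_ref(r) = ln(B / c(r)),  B = publications with a bibliography,
                                c(r) = publications citing r.

All logs are natural. Vectors are compared with cosine similarity, which
is non-negative because all weights are non-negative.
"""

from __future__ import annotations

import math
import re
from collections import Counter
from collections.abc import Iterable, Iterator, Mapping
from dataclasses import dataclass, field
from typing import TYPE_CHECKING

from ._porter import stem
from ._stopwords import STOPWORDS

if TYPE_CHECKING:  # pragma: no cover
    from .corpus import KnowledgeBase
    from .ontology import Ontology

_TOKEN_RE = re.compile(r"[a-z0-9]+")


class WeightedVector(Mapping[str, float]):
    """Sparse non-negative feature->weight map with a cached L2 norm.

    Zero entries are dropped at construction; negative weights are
    rejected. Instances are immutable and hashable by identity.
    """

    __slots__ = ("_entries", "_norm")

    def __init__(self, entries: Mapping[str, float] | Iterable[tuple[str, float]] = ()):
        items = dict(entries)
        for k, v in items.items():
            if v < 0:
                raise ValueError(f"negative weight for feature {k!r}: {v}")
        self._entries: dict[str, float] = {k: v for k, v in items.items() if v > 0}
        self._norm: float = math.sqrt(sum(v * v for v in self._entries.values()))

    def __getitem__(self, key: str) -> float:
        return self._entries[key]

    def __iter__(self) -> Iterator[str]:
        return iter(self._entries)

    def __len__(self) -> int:
        return len(self._entries)

    def __repr__(self) -> str:
        return f"WeightedVector({self._entries!r})"

    def __eq__(self, other: object) -> bool:
        if isinstance(other, WeightedVector):
            return self._entries == other._entries
        return NotImplemented

    @property
    def norm(self) -> float:
        return self._norm

    @property
    def support(self) -> frozenset[str]:
        return frozenset(self._entries)

    def is_empty(self) -> bool:
        return not self._entries


EMPTY_VECTOR = WeightedVector()


def tokenize(text: str, stopwords: frozenset[str] = STOPWORDS) -> list[str]:
    """Lowercase, split on non-alphanumerics, filter, and stem.

    Stopwords and single-character tokens are dropped before stemming;
    order is preserved and duplicates are kept (term frequency needs
    them). Pure-digit tokens survive: gene symbols such as "p53" stay
    intact because splitting is on non-alphanumerics only.
    """
    out = []
    for token in _TOKEN_RE.findall(text.lower()):
        if len(token) < 2 or token in stopwords:
            continue
        out.append(stem(token))
    return out


@dataclass
class IdfModel:
    """Fitted idf tables for words and cited references."""

    word_idf: dict[str, float]
    ref_idf: dict[str, float]
    n_docs_and_terms: int
    n_docs_with_bibliography: int
    stopwords: frozenset[str] = field(default=STOPWORDS, repr=False)

    @property
    def vocabulary(self) -> frozenset[str]:
        return frozenset(self.word_idf)


def fit_idf(
    kb: "KnowledgeBase",
    ontology: "Ontology",
    stopwords: frozenset[str] = STOPWORDS,
) -> IdfModel:
    """Fit word and reference idf tables over a knowledge base + ontology.

    Each publication (title + abstract) and each ontology term (name +
    synonyms + description) counts as one document for word document
    frequency. Reference idf counts how many publications with a
    bibliography cite each PMID.
    """
    df: Counter[str] = Counter()
    n_units = 0
    for pub in kb.publications.values():
        stems = set(tokenize(pub.title + " " + pub.abstract, stopwords))
        df.update(stems)
        n_units += 1
    for term in ontology.terms.values():
        text = " ".join([term.name, *term.synonyms, term.description])
        df.update(set(tokenize(text, stopwords)))
        n_units += 1
    if n_units == 0:
        raise ValueError("cannot fit idf on zero documents")

    cite_count: Counter[str] = Counter()
    n_with_bib = 0
    for pub in kb.publications.values():
        if pub.references:
            n_with_bib += 1
            cite_count.update(set(pub.references))

    word_idf = {w: math.log(n_units / c) for w, c in df.items()}
    ref_idf = {r: math.log(n_with_bib / c) for r, c in cite_count.items()}
    return IdfModel(
        word_idf=word_idf,
        ref_idf=ref_idf,
        n_docs_and_terms=n_units,
        n_docs_with_bibliography=n_with_bib,
        stopwords=stopwords,
    )


def tfidf_vector(text: str, model: IdfModel) -> WeightedVector:
    """Weight ``text`` by tf-idf under a fitted model.

    The tf denominator is the token count after stopword removal and
    stemming; out-of-vocabulary tokens count toward that denominator but
    produce no entry (they cannot match any indexed dimension).
    """
    tokens = tokenize(text, model.stopwords)
    if not tokens:
        return EMPTY_VECTOR
    n = len(tokens)
    counts = Counter(tokens)
    entries = {}
    for w, c in counts.items():
        idf = model.word_idf.get(w)
        if idf is not None and idf > 0:
            entries[w] = (c / n) * idf
    return WeightedVector(entries)


def ref_vector(references: Iterable[str], model: IdfModel) -> WeightedVector:
    """idf-weighted vector over a publication's distinct cited PMIDs."""
    entries = {}
    for r in set(references):
        idf = model.ref_idf.get(r)
        if idf is not None and idf > 0:
            entries[r] = idf
    return WeightedVector(entries)


def cosine(x: WeightedVector, y: WeightedVector) -> float:
    """Cosine similarity in [0, 1]; 0 when either vector is empty."""
    if x.norm == 0 or y.norm == 0:
        return 0.0
    if len(y) < len(x):
        x, y = y, x
    dot = sum(w * y.get(f, 0.0) for f, w in x.items())
    if dot == 0.0:
        return 0.0
    return min(1.0, dot / (x.norm * y.norm))
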