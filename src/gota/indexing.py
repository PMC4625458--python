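"""Feature bundles for publications and GO terms, and the serialized index.

Each publication p carries four features:

    W(p)  tf-idf BoW over title + abstract
    T(p)  tf-idf BoW over the title alone
    R(p)  idf-weighted vector of cited PMIDs
    Y(p)  publication year (may be absent)

and each GO term t:

    W(t)  tf-idf BoW over name + synonyms + description plus the title
          and abstract of every KB publication directly annotated with t
    T(t)  tf-idf BoW over name + synonyms
    Y(t)  mean year of the directly annotated publications (absent if none)

plus the normalized name/synonym phrases and title stems the term-centric
features need. Annotations are NOT propagated up the DAG at indexing time
(a term's text is the text directly associated with it); pass
``propagate_annotations=True`` to change that.

A :class:`KBIndex` bundles everything predict/evaluate need and can be
serialized to a directory of JSON files (an internal versioned schema)
that round-trips byte-identically.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

from .corpus import KnowledgeBase, Publication
from .ontology import (
    AnnotationSet,
    ICTable,
    Ontology,
    Term,
    ancestors,
    information_content,
)
from .textprep import (
    IdfModel,
    WeightedVector,
    fit_idf,
    ref_vector,
    tfidf_vector,
    tokenize,
)

SCHEMA_VERSION = 1


def _normalize_phrase(text: str) -> str:
    return " ".join(text.lower().split())


@dataclass
class PublicationIndex:
    W: WeightedVector
    T: WeightedVector
    R: WeightedVector
    Y: int | None
    raw_text: str = ""


@dataclass
class TermIndex:
    W: WeightedVector
    T: WeightedVector
    Y: int | None
    phrases: tuple[str, ...]
    title_stems: frozenset[str]


def index_publication(pub: Publication, model: IdfModel) -> PublicationIndex:
    """Build the W/T/R/Y feature bundle for one publication.

    Raises if the publication's text yields an empty W vector — every
    indexed publication must have at least some in-vocabulary text.
    """
    w = tfidf_vector(pub.text, model)
    if w.is_empty():
        raise ValueError(f"publication {pub.pmid} has no in-vocabulary text")
    t = tfidf_vector(pub.title, model)
    r = ref_vector(pub.references, model)
    return PublicationIndex(W=w, T=t, R=r, Y=pub.year, raw_text=pub.text)


def index_term(
    term: Term,
    kb: KnowledgeBase,
    model: IdfModel,
    annotated_pmids: frozenset[str] | None = None,
) -> TermIndex:
    """Build the W/T/Y bundle for one GO term.

    ``annotated_pmids`` defaults to the PMIDs directly annotated with the
    term in the KB's gold set; callers opting into DAG propagation pass
    the propagated set instead.
    """
    if not term.name:
        raise ValueError(f"term {term.id} has an empty name")
    if annotated_pmids is None:
        annotated_pmids = frozenset(
            p for p, ts in kb.gold.assignments.items() if term.id in ts
        )
    own_text = " ".join([term.name, *term.synonyms, term.description])
    pub_texts = [kb.publications[p].text for p in sorted(annotated_pmids)]
    w = tfidf_vector(" ".join([own_text, *pub_texts]), model)
    name_text = " ".join([term.name, *term.synonyms])
    t = tfidf_vector(name_text, model)
    years = [
        kb.publications[p].year
        for p in annotated_pmids
        if kb.publications[p].year is not None
    ]
    y = round(sum(years) / len(years)) if years else None
    phrases = tuple(
        dict.fromkeys(_normalize_phrase(s) for s in [term.name, *term.synonyms] if s.strip())
    )
    title_stems = frozenset(tokenize(name_text, model.stopwords))
    return TermIndex(W=w, T=t, Y=y, phrases=phrases, title_stems=title_stems)


@dataclass
class KBIndex:
    """Everything the classifier needs: fitted model, feature bundles, IC."""

    ontology: Ontology
    gold: AnnotationSet
    model: IdfModel
    publications: dict[str, PublicationIndex]
    terms: dict[str, TermIndex]
    ic: ICTable
    annotated_terms: frozenset[str] = field(init=False)

    def __post_init__(self) -> None:
        self.annotated_terms = self.gold.terms_used()

    @classmethod
    def build(
        cls,
        kb: KnowledgeBase,
        ontology: Ontology,
        propagate_annotations: bool = False,
        propagate_ic: bool = True,
    ) -> "KBIndex":
        model = fit_idf(kb, ontology)
        pubs = {pmid: index_publication(p, model) for pmid, p in kb.publications.items()}
        direct: dict[str, set[str]] = {t: set() for t in ontology.terms}
        for pmid, term_set in kb.gold.assignments.items():
            effective = (
                ancestors(ontology, term_set) if propagate_annotations else term_set
            )
            for t in effective:
                direct.setdefault(t, set()).add(pmid)
        terms = {
            acc: index_term(term, kb, model, frozenset(direct.get(acc, ())))
            for acc, term in ontology.terms.items()
        }
        ic = information_content(ontology, kb.gold, propagate=propagate_ic)
        return cls(
            ontology=ontology,
            gold=kb.gold,
            model=model,
            publications=pubs,
            terms=terms,
            ic=ic,
        )

    # -- serialization (versioned JSON directory schema) ------------------

    def save(self, directory: str | Path) -> None:
        """Write the index as deterministic JSON files under ``directory``."""
        d = Path(directory)
        d.mkdir(parents=True, exist_ok=True)

        def dump(name: str, obj: object) -> None:
            with open(d / name, "w") as fh:
                json.dump(obj, fh, sort_keys=True, separators=(",", ":"))

        dump("meta.json", {
            "schema_version": SCHEMA_VERSION,
            "n_docs_and_terms": self.model.n_docs_and_terms,
            "n_docs_with_bibliography": self.model.n_docs_with_bibliography,
        })
        dump("idf.json", {
            "word_idf": self.model.word_idf,
            "ref_idf": self.model.ref_idf,
            "stopwords": sorted(self.model.stopwords),
        })
        dump("ontology.json", {
            "roots": sorted(self.ontology.roots),
            "terms": {
                acc: {
                    "name": t.name,
                    "synonyms": t.synonyms,
                    "namespace": t.namespace,
                    "parents": sorted(t.parents),
                    "description": t.description,
                }
                for acc, t in self.ontology.terms.items()
            },
        })
        dump("gold.json", {p: sorted(ts) for p, ts in self.gold.assignments.items()})
        dump("publications.json", {
            pmid: {
                "W": dict(idx.W), "T": dict(idx.T), "R": dict(idx.R),
                "Y": idx.Y, "raw_text": idx.raw_text,
            }
            for pmid, idx in self.publications.items()
        })
        dump("terms.json", {
            acc: {
                "W": dict(idx.W), "T": dict(idx.T), "Y": idx.Y,
                "phrases": list(idx.phrases),
                "title_stems": sorted(idx.title_stems),
            }
            for acc, idx in self.terms.items()
        })
        dump("ic.json", {"ic": self.ic.ic, "ic_max": self.ic.ic_max})

    @classmethod
    def load(cls, directory: str | Path) -> "KBIndex":
        d = Path(directory)
        meta = json.loads((d / "meta.json").read_text())
        if meta["schema_version"] != SCHEMA_VERSION:
            raise ValueError(
                f"index schema version {meta['schema_version']} "
                f"not supported (expected {SCHEMA_VERSION})"
            )
        idf = json.loads((d / "idf.json").read_text())
        model = IdfModel(
            word_idf=idf["word_idf"],
            ref_idf=idf["ref_idf"],
            n_docs_and_terms=meta["n_docs_and_terms"],
            n_docs_with_bibliography=meta["n_docs_with_bibliography"],
            stopwords=frozenset(idf["stopwords"]),
        )
        onto_raw = json.loads((d / "ontology.json").read_text())
        terms = {
            acc: Term(
                id=acc,
                name=rec["name"],
                synonyms=list(rec["synonyms"]),
                namespace=rec["namespace"],
                parents=frozenset(rec["parents"]),
                description=rec["description"],
            )
            for acc, rec in onto_raw["terms"].items()
        }
        ontology = Ontology(terms=terms, roots=frozenset(onto_raw["roots"]))
        gold = AnnotationSet({
            p: frozenset(ts)
            for p, ts in json.loads((d / "gold.json").read_text()).items()
        })
        pubs = {
            pmid: PublicationIndex(
                W=WeightedVector(rec["W"]),
                T=WeightedVector(rec["T"]),
                R=WeightedVector(rec["R"]),
                Y=rec["Y"],
                raw_text=rec["raw_text"],
            )
            for pmid, rec in json.loads((d / "publications.json").read_text()).items()
        }
        term_idx = {
            acc: TermIndex(
                W=WeightedVector(rec["W"]),
                T=WeightedVector(rec["T"]),
                Y=rec["Y"],
                phrases=tuple(rec["phrases"]),
                title_stems=frozenset(rec["title_stems"]),
            )
            for acc, rec in json.loads((d / "terms.json").read_text()).items()
        }
        ic_raw = json.loads((d / "ic.json").read_text())
        return cls(
            ontology=ontology,
            gold=gold,
            model=model,
            publications=pubs,
            terms=term_idx,
            ic=ICTable(ic=ic_raw["ic"], ic_max=ic_raw["ic_max"]),
        )
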