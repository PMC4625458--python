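from __future__ import annotations

import pytest

from gota.corpus import KnowledgeBase, Publication
from gota.indexing import KBIndex
from gota.ontology import AnnotationSet, Ontology, Term, parse_obo
from gota.synthdata import SynthConfig, generate

CHAIN_OBO = """\
format-version: 1.2
ontology: test

[Term]
id: GO:0000001
name: root node

[Term]
id: GO:0000002
name: middle node
is_a: GO:0000001

[Term]
id: GO:0000003
name: leaf node
is_a: GO:0000002
"""


@pytest.fixture(scope="session")
def chain_ontology() -> Ontology:
    """Three-term chain: root -> middle -> leaf."""
    return parse_obo(CHAIN_OBO)


@pytest.fixture(scope="session")
def diamond_ontology() -> Ontology:
    """root with two children a, b; leaf below both (diamond)."""
    terms = {
        "GO:0000001": Term(id="GO:0000001", name="root"),
        "GO:0000002": Term(id="GO:0000002", name="branch a",
                           parents=frozenset({"GO:0000001"})),
        "GO:0000003": Term(id="GO:0000003", name="branch b",
                           parents=frozenset({"GO:0000001"})),
        "GO:0000004": Term(id="GO:0000004", name="diamond leaf",
                           parents=frozenset({"GO:0000002", "GO:0000003"})),
    }
    return Ontology(terms=terms, roots=frozenset({"GO:0000001"}))


@pytest.fixture(scope="session")
def tiny_kb(chain_ontology: Ontology) -> KnowledgeBase:
    """Four hand-written publications annotated on the chain ontology."""
    pubs = [
        Publication(pmid="1", title="kinase binding study",
                    abstract="the kinase binds substrate", year=2000,
                    references=("2",)),
        Publication(pmid="2", title="membrane transport analysis",
                    abstract="transport across the membrane barrier", year=2005),
        Publication(pmid="3", title="kinase membrane interplay",
                    abstract="kinase located at the membrane", year=2010,
                    references=("1", "2")),
        Publication(pmid="4", title="unrelated botany fieldwork",
                    abstract="flowering phenology observations", year=1990),
    ]
    gold = AnnotationSet({
        "1": frozenset({"GO:0000003"}),
        "2": frozenset({"GO:0000002"}),
        "3": frozenset({"GO:0000002", "GO:0000003"}),
        "4": frozenset({"GO:0000001"}),
    })
    return KnowledgeBase(publications={p.pmid: p for p in pubs}, gold=gold)


@pytest.fixture(scope="session")
def small_bundle():
    """Small synthetic bundle for fast pipeline tests."""
    return generate(SynthConfig(seed=42, n_pubs=120, n_queries=15, n_terms=30))


@pytest.fixture(scope="session")
def small_index(small_bundle) -> KBIndex:
    return KBIndex.build(small_bundle.kb, small_bundle.ontology)
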