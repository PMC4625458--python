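"""Gene Ontology parsing, DAG traversal, and semantic similarity.

The ontology is a DAG over terms in up to three namespaces (biological
process, molecular function, cellular component), each with a unique
root. Parent edges come from ``is_a`` and, by default, ``part_of``
relationships. The module provides ancestor closure A(X), leaf reduction
L(X) (the maximal antichain of X), information content from a background
annotation set, and Resnik / Lin term similarity:

    ic(t)            = -ln Pr(t)
    sim_Resnik(t, p) = max ic(a) over common ancestors a of t and p
    sim_Lin(t, p)    = 2 * sim_Resnik(t, p) / (ic(t) + ic(p))

Pr(t) is, by default, the fraction of background publications whose
ancestor-propagated annotation set contains t, which makes ic monotone
non-decreasing from root to leaves (the convention Resnik's
max-over-ancestors presupposes).
"""

from __future__ import annotations

import io
import math
from dataclasses import dataclass, field
from typing import IO

import networkx as nx
import obonet


class OntologyError(ValueError):
    """Raised for malformed or inconsistent ontology input."""


@dataclass
class Term:
    id: str
    name: str
    synonyms: list[str] = field(default_factory=list)
    namespace: str = ""
    parents: frozenset[str] = frozenset()
    description: str = ""
    obsolete: bool = False


@dataclass
class Ontology:
    """Immutable DAG of terms keyed by accession."""

    terms: dict[str, Term]
    roots: frozenset[str]
    _ancestor_cache: dict[str, frozenset[str]] = field(
        default_factory=dict, repr=False, compare=False
    )

    def __contains__(self, accession: str) -> bool:
        return accession in self.terms

    def __len__(self) -> int:
        return len(self.terms)

    def _ancestors_of(self, accession: str) -> frozenset[str]:
        """Ancestor closure of a single term, including itself (memoized)."""
        cached = self._ancestor_cache.get(accession)
        if cached is not None:
            return cached
        # iterative DFS; memoization keeps total work linear in edges
        closure = {accession}
        stack = list(self.terms[accession].parents)
        while stack:
            acc = stack.pop()
            cached = self._ancestor_cache.get(acc)
            if cached is not None:
                closure |= cached
                continue
            if acc not in closure:
                closure.add(acc)
                stack.extend(self.terms[acc].parents)
        result = frozenset(closure)
        self._ancestor_cache[accession] = result
        return result


@dataclass
class AnnotationSet:
    """Gold-standard publication -> GO term assignments."""

    assignments: dict[str, frozenset[str]]

    def __post_init__(self) -> None:
        empties = [p for p, ts in self.assignments.items() if not ts]
        if empties:
            raise ValueError(f"empty annotation sets for: {sorted(empties)[:5]}")

    def __len__(self) -> int:
        return len(self.assignments)

    def terms_used(self) -> frozenset[str]:
        out: set[str] = set()
        for ts in self.assignments.values():
            out |= ts
        return frozenset(out)


@dataclass
class ICTable:
    """Per-term information content in nats."""

    ic: dict[str, float]
    ic_max: float

    def __getitem__(self, accession: str) -> float:
        return self.ic.get(accession, self.ic_max)


def _extract_synonyms(raw: list[str]) -> list[str]:
    # OBO synonym lines look like: "text" SCOPE [xrefs]
    out = []
    for line in raw:
        if line.startswith('"') and '"' in line[1:]:
            out.append(line[1 : line.index('"', 1)])
        else:
            out.append(line)
    return out


def _extract_description(raw: str) -> str:
    if raw.startswith('"') and '"' in raw[1:]:
        return raw[1 : raw.index('"', 1)]
    return raw


def parse_obo(source: str | IO[str], include_part_of: bool = True) -> Ontology:
    """Parse an OBO 1.2/1.4 document into an :class:`Ontology`.

    Obsolete terms are excluded. Parent edges come from ``is_a`` and,
    unless ``include_part_of=False``, from ``relationship: part_of``.
    Roots are terms with no parents.

    Raises :class:`OntologyError` on malformed input, on ``is_a`` /
    ``part_of`` targets that are not declared as terms, and on cyclic
    parent graphs.
    """
    if isinstance(source, str):
        source = io.StringIO(source)
    try:
        graph = obonet.read_obo(source, ignore_obsolete=True)
    except Exception as exc:  # obonet raises assorted ValueError subclasses
        raise OntologyError(f"OBO parse error: {exc}") from exc

    terms: dict[str, Term] = {}
    for node, data in graph.nodes(data=True):
        if not data:
            # node created only as an edge target -> undeclared term
            continue
        parents = set(data.get("is_a", []))
        if include_part_of:
            for rel in data.get("relationship", []):
                parts = rel.split()
                if len(parts) == 2 and parts[0] == "part_of":
                    parents.add(parts[1])
        terms[node] = Term(
            id=node,
            name=data.get("name", ""),
            synonyms=_extract_synonyms(data.get("synonym", [])),
            namespace=data.get("namespace", ""),
            parents=frozenset(parents),
            description=_extract_description(data.get("def", "")),
        )

    for term in terms.values():
        missing = [p for p in term.parents if p not in terms]
        if missing:
            raise OntologyError(
                f"term {term.id} has undeclared parent(s): {sorted(missing)}"
            )

    dag = nx.DiGraph()
    dag.add_nodes_from(terms)
    for term in terms.values():
        for p in term.parents:
            dag.add_edge(term.id, p)
    if not nx.is_directed_acyclic_graph(dag):
        cycle = nx.find_cycle(dag)
        raise OntologyError(f"cyclic parent graph: {cycle}")

    roots = frozenset(t for t, term in terms.items() if not term.parents)
    if terms and not roots:
        raise OntologyError("ontology has terms but no root")
    return Ontology(terms=terms, roots=roots)


def ancestors(ontology: Ontology, accessions: set[str] | frozenset[str]) -> frozenset[str]:
    """Ancestor closure A(X): X plus everything reachable via parent edges.

    X is contained in the result and the result is closed under
    parent-taking.
    """
    out: set[str] = set()
    for acc in accessions:
        if acc not in ontology.terms:
            raise KeyError(f"unknown accession: {acc}")
        out |= ontology._ancestors_of(acc)
    return frozenset(out)


def leaves(ontology: Ontology, accessions: set[str] | frozenset[str]) -> frozenset[str]:
    """Leaf reduction L(X): the maximal antichain of X.

    Removes every member of X that is a proper ancestor of another
    member. Raises on empty X (downstream metrics divide by |L(X)|).
    """
    if not accessions:
        raise ValueError("leaf reduction of an empty set is undefined")
    proper_ancestors: set[str] = set()
    for acc in accessions:
        if acc not in ontology.terms:
            raise KeyError(f"unknown accession: {acc}")
        proper_ancestors |= ontology._ancestors_of(acc) - {acc}
    return frozenset(acc for acc in accessions if acc not in proper_ancestors)


def information_content(
    ontology: Ontology, gold: AnnotationSet, propagate: bool = True
) -> ICTable:
    """Information content ic(t) = -ln Pr(t) from a background annotation set.

    With ``propagate=True`` (default) Pr(t) is the fraction of
    publications whose ancestor-propagated gold set contains t; every
    root then has Pr = 1 and ic = 0, and ic is monotone along parent
    edges. ``propagate=False`` uses raw direct-annotation frequencies.

    Terms never observed in the background get ic equal to the maximum
    observed ic (so logs of zero never occur downstream).
    """
    if not gold.assignments:
        raise ValueError("background annotation set is empty")
    n = len(gold.assignments)
    counts: dict[str, int] = {}
    for term_set in gold.assignments.values():
        observed = ancestors(ontology, term_set) if propagate else term_set
        for t in observed:
            counts[t] = counts.get(t, 0) + 1
    ic = {t: math.log(n / c) for t, c in counts.items()}
    ic_max = max(ic.values(), default=0.0)
    return ICTable(ic=ic, ic_max=ic_max)


def resnik(ontology: Ontology, ict: ICTable, t: str, p: str) -> float:
    """Maximum information content over the common ancestors of t and p.

    0 when the only common ancestor is a root, and 0 by convention when
    the terms share no ancestor at all (different namespaces in a
    multi-root ontology).
    """
    common = ontology._ancestors_of(t) & ontology._ancestors_of(p)
    if not common:
        return 0.0
    return max(ict[a] for a in common)


def lin(ontology: Ontology, ict: ICTable, t: str, p: str) -> float:
    """Lin similarity: Resnik normalized to [0, 1] by the terms' own ic."""
    denom = ict[t] + ict[p]
    if denom == 0:
        return 0.0
    return min(1.0, 2.0 * resnik(ontology, ict, t, p) / denom)
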