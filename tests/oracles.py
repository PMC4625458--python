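"""Independent brute-force oracles used to cross-check the implementation.

Everything here is written from the mathematical definitions with the
slowest, most transparent strategy available (pairwise scans, exhaustive
enumeration, double loops) and deliberately shares no code with the
package internals it is checking.
"""

from __future__ import annotations

import math
import random

from gota.corpus import Publication
from gota.ontology import Ontology, Term


# -- DAG / similarity oracles ---------------------------------------------

def ancestors_bf(parents: dict[str, set[str]], xs: set[str]) -> set[str]:
    """Ancestor closure by plain recursive DFS over a parent map."""
    out: set[str] = set()

    def visit(node: str) -> None:
        if node in out:
            return
        out.add(node)
        for p in parents[node]:
            visit(p)

    for x in xs:
        visit(x)
    return out


def leaves_bf(parents: dict[str, set[str]], xs: set[str]) -> set[str]:
    """Antichain by pairwise check: drop u that is an ancestor of some v != u."""
    return {
        u for u in xs
        if not any(v != u and u in ancestors_bf(parents, {v}) for v in xs)
    }


def ic_bf(parents: dict[str, set[str]], gold: dict[str, set[str]]) -> dict[str, float]:
    """Propagated-count information content by direct counting."""
    n = len(gold)
    counts: dict[str, int] = {}
    for terms in gold.values():
        for t in ancestors_bf(parents, set(terms)):
            counts[t] = counts.get(t, 0) + 1
    return {t: -math.log(c / n) for t, c in counts.items()}


def resnik_bf(parents: dict[str, set[str]], ic: dict[str, float], ic_max: float,
              t: str, p: str) -> float:
    common = ancestors_bf(parents, {t}) & ancestors_bf(parents, {p})
    if not common:
        return 0.0
    return max(ic.get(a, ic_max) for a in common)


def lin_bf(parents: dict[str, set[str]], ic: dict[str, float], ic_max: float,
           t: str, p: str) -> float:
    denom = ic.get(t, ic_max) + ic.get(p, ic_max)
    if denom == 0:
        return 0.0
    return min(1.0, 2.0 * resnik_bf(parents, ic, ic_max, t, p) / denom)


# -- metric oracles --------------------------------------------------------

def hier_bf(parents: dict[str, set[str]], gold: set[str], pred: set[str]
            ) -> tuple[float, float, float]:
    if not pred:
        return 0.0, 0.0, 0.0
    at, ap = ancestors_bf(parents, gold), ancestors_bf(parents, pred)
    hp = len(at & ap) / len(ap)
    hr = len(at & ap) / len(at)
    hf = 2 * hp * hr / (hp + hr) if hp + hr else 0.0
    return hp, hr, hf


def hfmax_bf(parents: dict[str, set[str]],
             pairs: list[tuple[set[str], list[tuple[str, float]]]]) -> float:
    """Exhaustive threshold sweep over every observed score."""
    scores = sorted({s for _, ranked in pairs for _, s in ranked})
    best = 0.0
    for s in scores:
        hps, hrs = [], []
        for gold, ranked in pairs:
            pred = {t for t, sc in ranked if sc >= s}
            hp, hr, _ = hier_bf(parents, gold, pred)
            if pred:
                hps.append(hp)
            hrs.append(hr)
        if not hps:
            continue
        hp_d, hr_d = sum(hps) / len(hps), sum(hrs) / len(hrs)
        if hp_d + hr_d:
            best = max(best, 2 * hp_d * hr_d / (hp_d + hr_d))
    return best


def ip_bf(parents: dict[str, set[str]], ic: dict[str, float], ic_max: float,
          gold: set[str], pred: set[str]) -> float:
    lp = leaves_bf(parents, pred)
    lt = leaves_bf(parents, gold)
    return sum(
        max(lin_bf(parents, ic, ic_max, p, t) for t in lt) for p in lp
    ) / len(lp)


def ir_bf(parents: dict[str, set[str]], ic: dict[str, float], ic_max: float,
          gold: set[str], pred: set[str]) -> float:
    return ip_bf(parents, ic, ic_max, pred, gold)


# -- random structures -----------------------------------------------------

def random_dag(rng: random.Random, n_terms: int) -> dict[str, set[str]]:
    """Random single-root DAG as a parent map: node i may only point to j < i."""
    parents: dict[str, set[str]] = {"T000": set()}
    for i in range(1, n_terms):
        k = rng.randint(1, min(2, i))
        parents[f"T{i:03d}"] = {
            f"T{j:03d}" for j in rng.sample(range(i), k)
        }
    return parents


def parent_map_to_ontology(parents: dict[str, set[str]]) -> Ontology:
    terms = {
        acc: Term(id=acc, name=f"name {acc}", parents=frozenset(ps))
        for acc, ps in parents.items()
    }
    return Ontology(
        terms=terms, roots=frozenset(a for a, ps in parents.items() if not ps)
    )


# -- full-scan classifier oracle ------------------------------------------

def predict_bf(query: Publication, kb_pubs: dict[str, Publication],
               kb_gold: dict[str, frozenset[str]], index, params,
               leave_one_out: bool = True) -> list[tuple[str, float]]:
    """Recompute the combined score from the formula, end to end.

    phi_P(q,p) = prod (1+f_i)^{m_i}; Phi_P(q,t) sums phi_P over the
    top-K neighbors annotated with t; Phi_T(q,t) = prod (1+g_i)^{n_i};
    final score Phi = Phi_P * Phi_T over Phi_P > 0 candidates. Uses the
    index only for the fitted vectors, never for scoring.
    """
    from gota.indexing import index_publication
    from gota.pubcentric import year_similarity
    from gota.termcentric import phrase_occurrences
    from gota.textprep import cosine

    q = index_publication(query, index.model)
    scored = []
    for pmid, pub in kb_pubs.items():
        if leave_one_out and pmid == query.pmid:
            continue
        p = index.publications[pmid]
        fs = (cosine(q.W, p.W), cosine(q.T, p.T), cosine(q.R, p.R),
              year_similarity(q.Y, p.Y))
        phi = 1.0
        for f, m in zip(fs, params.m):
            phi *= (1.0 + f) ** m
        scored.append((-phi, pmid))
    scored.sort()
    top = scored[: params.K]

    phi_p: dict[str, float] = {}
    for neg, pmid in top:
        for t in kb_gold[pmid]:
            phi_p[t] = phi_p.get(t, 0.0) + (-neg)

    out = []
    for t, wp in phi_p.items():
        ti = index.terms[t]
        gs = (
            cosine(q.W, ti.W),
            cosine(q.T, ti.T),
            len(ti.title_stems & q.W.support) / len(ti.title_stems),
            min(phrase_occurrences(q.raw_text, ti.phrases), 4) / 4,
            year_similarity(q.Y, ti.Y),
        )
        wt = 1.0
        for g, n in zip(gs, params.n):
            wt *= (1.0 + g) ** n
        out.append((t, wp * wt))
    out.sort(key=lambda kv: (-kv[1], kv[0]))
    return out
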