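"""Seeded synthetic ontologies, corpora, and gold annotations.

The generator plants a recoverable signal with the statistical shape the
classifier assumes, so the whole pipeline is testable offline:

* a layered random DAG ontology (each non-root term draws 1-2 parents
  from the layer above) with a synthetic name, synonym, and description
  per term;
* a disjoint signal vocabulary per term, so a document's words identify
  its gold terms unambiguously up to noise — failures then indicate a
  method defect, not dataset ambiguity;
* per-document gold terms drawn from a skewed annotations-per-document
  distribution (most documents carry a single term, 99% at most 10,
  matching curated literature annotation sets);
* titles composed mostly of signal words (titles are the strongest
  signal in practice), abstracts mixing signal and background noise at
  ``noise_rate``, years, and citations preferring same-term documents;
* a held-out query set disjoint from the knowledge base.

Everything is reproducible from a single integer seed through one
numpy Generator; the same seed yields byte-identical fixtures.

Synthetic words are letter+digit hybrids (e.g. ``sig012x03``) chosen to
be invariant under Porter stemming, keeping planted vocabularies exactly
recoverable after text preprocessing.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .corpus import KnowledgeBase, Publication, build_kb, read_annotations, read_corpus_jsonl
from .ontology import AnnotationSet, Ontology, Term, parse_obo

# annotations-per-document distribution over 1..10 gold terms:
# ~39% single-term documents, 99% with at most 10
DEFAULT_ANN_DIST: tuple[float, ...] = (
    0.39, 0.20, 0.13, 0.09, 0.06, 0.045, 0.035, 0.025, 0.015, 0.01,
)


@dataclass(frozen=True)
class SynthConfig:
    seed: int = 0
    n_terms: int = 50
    depth: int = 4
    branching: int = 3
    n_pubs: int = 500
    n_queries: int = 100
    words_per_term: int = 8
    noise_vocab: int = 500
    noise_rate: float = 0.5
    ann_per_pub_dist: tuple[float, ...] = DEFAULT_ANN_DIST
    ref_prob: float = 0.3
    year_range: tuple[int, int] = (1990, 2015)
    title_words: int = 8
    abstract_words: int = 60

    def __post_init__(self) -> None:
        if min(self.n_terms, self.depth, self.branching, self.n_pubs,
               self.n_queries, self.words_per_term, self.noise_vocab) < 1:
            raise ValueError("all counts must be >= 1")
        if not 0.0 <= self.noise_rate <= 1.0 or not 0.0 <= self.ref_prob <= 1.0:
            raise ValueError("probabilities must lie in [0, 1]")
        if abs(sum(self.ann_per_pub_dist) - 1.0) > 1e-9:
            raise ValueError("ann_per_pub_dist must sum to 1")


@dataclass
class SynthBundle:
    """A generated ontology + knowledge base + held-out query set."""

    ontology: Ontology
    kb: KnowledgeBase
    queries: list[Publication]
    query_gold: AnnotationSet
    config: SynthConfig = field(repr=False)


def _accession(i: int) -> str:
    return f"GO:{i + 1:07d}"


def _build_dag(rng: np.random.Generator, cfg: SynthConfig) -> dict[str, Term]:
    """Layered random DAG: layer 0 is the root; sizes grow by ``branching``."""
    layer_sizes = [1]
    remaining = cfg.n_terms - 1
    for d in range(1, cfg.depth):
        size = min(remaining, layer_sizes[-1] * cfg.branching)
        if d == cfg.depth - 1:
            size = remaining
        layer_sizes.append(size)
        remaining -= size
        if remaining <= 0:
            break
    layers: list[list[str]] = []
    counter = 0
    terms: dict[str, Term] = {}
    for depth, size in enumerate(layer_sizes):
        layer = []
        for _ in range(size):
            acc = _accession(counter)
            counter += 1
            if depth == 0:
                parents: frozenset[str] = frozenset()
            else:
                n_parents = int(rng.integers(1, min(2, len(layers[depth - 1])) + 1))
                parents = frozenset(
                    str(p)
                    for p in rng.choice(layers[depth - 1], size=n_parents, replace=False)
                )
            idx = counter - 1
            # names/synonyms reuse the term's own signal words (cf.
            # _signal_vocab) so query text can plausibly mention them,
            # as real GO names appear in abstracts; vocabularies stay
            # disjoint across terms
            terms[acc] = Term(
                id=acc,
                name=f"sig{idx:03d}x00 sig{idx:03d}x01 pathway",
                synonyms=[f"sig{idx:03d}x02 sig{idx:03d}x03 process"],
                namespace="biological_process",
                parents=parents,
                description=(
                    f"synthetic process involving sig{idx:03d}x04 "
                    f"and sig{idx:03d}x05 regulation"
                ),
            )
            layer.append(acc)
        layers.append(layer)
    return terms


def _signal_vocab(cfg: SynthConfig, term_order: list[str]) -> dict[str, list[str]]:
    return {
        acc: [f"sig{i:03d}x{j:02d}" for j in range(cfg.words_per_term)]
        for i, acc in enumerate(term_order)
    }


def generate(cfg: SynthConfig) -> SynthBundle:
    """Generate a full seeded bundle (ontology, KB, held-out queries)."""
    rng = np.random.default_rng(cfg.seed)
    terms = _build_dag(rng, cfg)
    ontology = Ontology(
        terms=terms, roots=frozenset(a for a, t in terms.items() if not t.parents)
    )
    term_order = sorted(terms)
    vocab = _signal_vocab(cfg, term_order)
    flat_signal = {w for ws in vocab.values() for w in ws}
    noise_words = [f"noise{j:04d}" for j in range(cfg.noise_vocab)]
    if flat_signal & set(noise_words):
        raise ValueError("signal and noise vocabularies collide; loosen the config")

    ann_sizes = np.arange(1, len(cfg.ann_per_pub_dist) + 1)
    by_term: dict[str, list[str]] = {acc: [] for acc in term_order}

    def make_pub(pmid: str) -> tuple[Publication, frozenset[str]]:
        n_ann = min(
            int(rng.choice(ann_sizes, p=cfg.ann_per_pub_dist)), len(term_order)
        )
        gold = frozenset(
            str(t) for t in rng.choice(term_order, size=n_ann, replace=False)
        )
        signal_pool = [w for t in sorted(gold) for w in vocab[t]]
        # titles carry the strongest signal: a fifth of the abstract noise
        title_sig = rng.random(cfg.title_words) >= 0.2 * cfg.noise_rate
        title = " ".join(
            str(rng.choice(signal_pool)) if is_sig else str(rng.choice(noise_words))
            for is_sig in title_sig
        )
        abs_sig = rng.random(cfg.abstract_words) >= cfg.noise_rate
        abstract = " ".join(
            str(rng.choice(signal_pool)) if is_sig else str(rng.choice(noise_words))
            for is_sig in abs_sig
        )
        year = int(rng.integers(cfg.year_range[0], cfg.year_range[1] + 1))
        refs: list[str] = []
        if rng.random() < cfg.ref_prob:
            same_topic = sorted({p for t in gold for p in by_term[t]})
            if same_topic:
                n_refs = int(rng.integers(1, min(5, len(same_topic)) + 1))
                refs = [str(r) for r in rng.choice(same_topic, size=n_refs, replace=False)]
        return (
            Publication(pmid=pmid, title=title, abstract=abstract,
                        references=tuple(refs), year=year),
            gold,
        )

    kb_pubs: list[Publication] = []
    kb_gold: dict[str, frozenset[str]] = {}
    for i in range(cfg.n_pubs):
        pub, gold = make_pub(f"{100000 + i}")
        kb_pubs.append(pub)
        kb_gold[pub.pmid] = gold
        for t in gold:
            by_term[t].append(pub.pmid)

    queries: list[Publication] = []
    query_gold: dict[str, frozenset[str]] = {}
    for i in range(cfg.n_queries):
        pub, gold = make_pub(f"{900000 + i}")
        queries.append(pub)
        query_gold[pub.pmid] = gold

    kb = build_kb(kb_pubs, AnnotationSet(kb_gold), ontology)
    return SynthBundle(
        ontology=ontology,
        kb=kb,
        queries=queries,
        query_gold=AnnotationSet(query_gold),
        config=cfg,
    )


# -- fixture serialization -------------------------------------------------

def _obo_text(ontology: Ontology) -> str:
    lines = ["format-version: 1.2", "ontology: synthetic-go", ""]
    for acc in sorted(ontology.terms):
        t = ontology.terms[acc]
        lines.append("[Term]")
        lines.append(f"id: {t.id}")
        lines.append(f"name: {t.name}")
        if t.namespace:
            lines.append(f"namespace: {t.namespace}")
        if t.description:
            lines.append(f'def: "{t.description}" []')
        for syn in t.synonyms:
            lines.append(f'synonym: "{syn}" EXACT []')
        for p in sorted(t.parents):
            lines.append(f"is_a: {p}")
        lines.append("")
    return "\n".join(lines)


def _jsonl_text(pubs: list[Publication]) -> str:
    return "".join(
        json.dumps(
            {
                "pmid": p.pmid, "title": p.title, "abstract": p.abstract,
                "year": p.year, "references": list(p.references),
            },
            sort_keys=True,
        ) + "\n"
        for p in pubs
    )


def _tsv_text(annotations: AnnotationSet) -> str:
    return "".join(
        f"{pmid}\t{t}\n"
        for pmid in sorted(annotations.assignments)
        for t in sorted(annotations.assignments[pmid])
    )


def write_fixture(bundle: SynthBundle, directory: str | Path, force: bool = False) -> None:
    """Write a bundle as OBO + JSONL corpus + TSV annotations.

    Emits ``ontology.obo``, ``corpus.jsonl``, ``annotations.tsv``,
    ``queries.jsonl`` and ``query_annotations.tsv`` — exactly the
    formats the ontology/corpus readers accept (round-trip tested).
    """
    if not bundle.kb.publications:
        raise ValueError("empty bundle")
    d = Path(directory)
    if d.exists() and any(d.iterdir()) and not force:
        raise FileExistsError(f"{d} is not empty (pass force=True to overwrite)")
    d.mkdir(parents=True, exist_ok=True)
    (d / "ontology.obo").write_text(_obo_text(bundle.ontology))
    (d / "corpus.jsonl").write_text(
        _jsonl_text(sorted(bundle.kb.publications.values(), key=lambda p: p.pmid))
    )
    (d / "annotations.tsv").write_text(_tsv_text(bundle.kb.gold))
    (d / "queries.jsonl").write_text(_jsonl_text(bundle.queries))
    (d / "query_annotations.tsv").write_text(_tsv_text(bundle.query_gold))


def read_fixture(directory: str | Path) -> SynthBundle:
    """Read a written fixture back into a bundle (config not recovered)."""
    d = Path(directory)
    ontology = parse_obo((d / "ontology.obo").read_text())
    pubs = read_corpus_jsonl(d / "corpus.jsonl")
    gold = read_annotations(d / "annotations.tsv", format="tsv")
    kb = build_kb(pubs, gold, ontology)
    queries = read_corpus_jsonl(d / "queries.jsonl")
    query_gold = read_annotations(d / "query_annotations.tsv", format="tsv")
    return SynthBundle(
        ontology=ontology, kb=kb, queries=queries, query_gold=query_gold,
        config=SynthConfig(),
    )
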