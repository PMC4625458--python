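"""Publication records, gold annotations, and knowledge-base assembly.

Readers cover the offline formats a curation pipeline produces: PubMed
efetch XML, GAF 2.x association files (keeping only ``PMID:`` references
and discarding the gene-product columns), a two-column ``pmid<TAB>go_id``
TSV, and a JSONL corpus dialect. All readers transparently accept gzip.

A :class:`KnowledgeBase` couples publication records with their gold GO
annotations; :func:`build_kb` cross-validates the two against an ontology
(dropping unknown/obsolete terms and orphan records) and
:func:`filter_kb` restricts to a PMID subset, e.g. a species-specific
slice of the associations.
"""

from __future__ import annotations

import gzip
import io
import json
import logging
import re
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import IO, TYPE_CHECKING

from lxml import etree

from .ontology import AnnotationSet

if TYPE_CHECKING:  # pragma: no cover
    from .ontology import Ontology

logger = logging.getLogger(__name__)

_GO_ACC_RE = re.compile(r"^GO:\d{7}$")


@dataclass
class Publication:
    """A publication record: at least one of title/abstract is non-empty."""

    pmid: str
    title: str = ""
    abstract: str = ""
    references: tuple[str, ...] = ()
    year: int | None = None

    def __post_init__(self) -> None:
        if not self.pmid:
            raise ValueError("publication requires a non-empty pmid")
        if not self.title and not self.abstract:
            raise ValueError(f"publication {self.pmid} has neither title nor abstract")

    @property
    def text(self) -> str:
        """Title and abstract concatenated (the W feature source)."""
        return (self.title + " " + self.abstract).strip()


@dataclass
class KnowledgeBase:
    publications: dict[str, Publication]
    gold: AnnotationSet

    def __post_init__(self) -> None:
        missing = set(self.gold.assignments) - set(self.publications)
        if missing:
            raise ValueError(f"annotated pmids without records: {sorted(missing)[:5]}")
        unannotated = set(self.publications) - set(self.gold.assignments)
        if unannotated:
            raise ValueError(f"publications without gold terms: {sorted(unannotated)[:5]}")

    def __len__(self) -> int:
        return len(self.publications)


def _open_maybe_gzip(source: str | Path | IO) -> IO:
    if isinstance(source, (str, Path)):
        path = Path(source)
        if path.suffix == ".gz":
            return gzip.open(path, "rt")
        return open(path, "rt")
    if hasattr(source, "read"):
        head = source.read(0)
        if isinstance(head, bytes):  # binary handle: sniff gzip magic
            pos = source.tell()
            magic = source.read(2)
            source.seek(pos)
            if magic == b"\x1f\x8b":
                return io.TextIOWrapper(gzip.GzipFile(fileobj=source))
            return io.TextIOWrapper(source)
        return source
    raise TypeError(f"cannot read from {type(source)!r}")


def read_pubmed_xml(source: str | Path | IO) -> list[Publication]:
    """Parse PubMed efetch XML (PubmedArticleSet) into publications.

    Extracts PMID, ArticleTitle, the concatenation of AbstractText
    segments, the PubDate year, and cited PMIDs from both ReferenceList
    and CommentsCorrections[@RefType="Cites"] (reference availability in
    PubMed exports is patchy, so both sources are used). Records without
    a PMID are skipped with a warning.
    """
    if isinstance(source, (str, Path)):
        path = Path(source)
        data = gzip.open(path, "rb").read() if path.suffix == ".gz" else path.read_bytes()
    else:
        data = source.read()
        if isinstance(data, str):
            data = data.encode()
    try:
        root = etree.fromstring(data)
    except etree.XMLSyntaxError as exc:
        raise ValueError(f"PubMed XML parse failure: {exc}") from exc

    pubs = []
    for article in root.iter("PubmedArticle"):
        pmid_el = article.find(".//MedlineCitation/PMID")
        if pmid_el is None or not (pmid_el.text or "").strip():
            warnings.warn("PubmedArticle without PMID skipped", stacklevel=2)
            continue
        pmid = pmid_el.text.strip()
        title = "".join(article.find(".//ArticleTitle").itertext()).strip() \
            if article.find(".//ArticleTitle") is not None else ""
        abstract = " ".join(
            "".join(seg.itertext()).strip()
            for seg in article.findall(".//Abstract/AbstractText")
        ).strip()
        year = None
        year_el = article.find(".//Article/Journal/JournalIssue/PubDate/Year")
        if year_el is not None and (year_el.text or "").strip().isdigit():
            year = int(year_el.text.strip())
        refs: list[str] = []
        for ref_pmid in article.findall(".//ReferenceList//ArticleId[@IdType='pubmed']"):
            if (ref_pmid.text or "").strip():
                refs.append(ref_pmid.text.strip())
        for cc in article.findall(".//CommentsCorrections[@RefType='Cites']/PMID"):
            if (cc.text or "").strip():
                refs.append(cc.text.strip())
        seen: dict[str, None] = dict.fromkeys(refs)
        pubs.append(
            Publication(
                pmid=pmid,
                title=title,
                abstract=abstract,
                references=tuple(seen),
                year=year,
            )
        )
    return pubs


def read_corpus_jsonl(source: str | Path | IO) -> list[Publication]:
    """Read publications from JSONL with keys pmid/title/abstract/year/references."""
    handle = _open_maybe_gzip(source)
    pubs = []
    for line in handle:
        line = line.strip()
        if not line:
            continue
        rec = json.loads(line)
        pubs.append(
            Publication(
                pmid=str(rec["pmid"]),
                title=rec.get("title", "") or "",
                abstract=rec.get("abstract", "") or "",
                references=tuple(str(r) for r in rec.get("references", []) or []),
                year=rec.get("year"),
            )
        )
    return pubs


def read_annotations(source: str | Path | IO, format: str = "tsv") -> AnnotationSet:
    """Read PMID <-> GO-term pairs from GAF 2.x or two-column TSV.

    For GAF, only rows whose reference column contains a ``PMID:``
    reference yield pairs; gene-product columns are ignored and
    duplicate pairs (from different gene rows) collapse. Malformed GO
    accessions are skipped with a warning; zero surviving pairs is an
    error.
    """
    handle = _open_maybe_gzip(source)
    pairs: dict[str, set[str]] = {}

    def add(pmid: str, go_id: str) -> None:
        if not _GO_ACC_RE.match(go_id):
            warnings.warn(f"malformed GO accession skipped: {go_id!r}", stacklevel=3)
            return
        pairs.setdefault(pmid, set()).add(go_id)

    if format == "gaf":
        for line in handle:
            if not line.strip() or line.startswith("!"):
                continue
            cols = line.rstrip("\n").split("\t")
            if len(cols) < 6:
                continue
            go_id = cols[4].strip()
            for ref in cols[5].split("|"):
                ref = ref.strip()
                if ref.startswith("PMID:"):
                    add(ref[len("PMID:"):], go_id)
    elif format == "tsv":
        for line in handle:
            if not line.strip() or line.startswith("#"):
                continue
            cols = line.rstrip("\n").split("\t")
            if len(cols) < 2:
                continue
            add(cols[0].strip(), cols[1].strip())
    else:
        raise ValueError(f"unknown annotation format: {format!r}")

    if not pairs:
        raise ValueError("no PMID-GO pairs parsed")
    return AnnotationSet({p: frozenset(ts) for p, ts in pairs.items()})


def build_kb(
    pubs: list[Publication],
    gold: AnnotationSet,
    ontology: "Ontology",
) -> KnowledgeBase:
    """Assemble a validated knowledge base.

    Drops annotation pairs whose PMID has no publication record or whose
    term is unknown to the ontology, then drops publications left
    without annotations. Empty result is an error.
    """
    by_pmid = {p.pmid: p for p in pubs}
    kept: dict[str, frozenset[str]] = {}
    n_dropped_pairs = 0
    for pmid, terms in gold.assignments.items():
        if pmid not in by_pmid:
            n_dropped_pairs += len(terms)
            continue
        valid = frozenset(t for t in terms if t in ontology.terms)
        n_dropped_pairs += len(terms) - len(valid)
        if valid:
            kept[pmid] = valid
    if not kept:
        raise ValueError("knowledge base is empty after validation")
    if n_dropped_pairs:
        logger.info("build_kb: dropped %d invalid annotation pairs", n_dropped_pairs)
    publications = {pmid: by_pmid[pmid] for pmid in kept}
    logger.info(
        "build_kb: %d publications, %d pairs",
        len(publications),
        sum(len(ts) for ts in kept.values()),
    )
    return KnowledgeBase(publications=publications, gold=AnnotationSet(kept))


def filter_kb(kb: KnowledgeBase, pmid_subset: set[str] | frozenset[str]) -> KnowledgeBase:
    """Restrict a knowledge base to a subset of PMIDs (e.g. one species)."""
    keep = set(pmid_subset) & set(kb.publications)
    if not keep:
        raise ValueError("pmid subset is disjoint from the knowledge base")
    return KnowledgeBase(
        publications={p: kb.publications[p] for p in keep},
        gold=AnnotationSet({p: kb.gold.assignments[p] for p in keep}),
    )
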