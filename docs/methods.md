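# Methods

This note documents the model, its parameters, the numerical and design
choices behind the implementation, and what the synthetic benchmark does
and does not demonstrate.

## Problem setting

The task is hierarchical multi-label classification: given a biomedical
publication, rank terms from the Gene Ontology — a directed acyclic
graph of ~tens of thousands of terms in three namespaces (biological
process, molecular function, cellular component), each with a unique
root — by their relatedness to the publication's content. Supervision
comes from a knowledge base (KB) of publications with curated GO
annotations (PMID ↔ GO-term pairs, e.g. extracted from GOA association
files with the gene-product columns discarded). Queries may be full
PubMed records or unstructured text.

## Text representation

Publications and terms are bags of words. Tokens are lowercased, split
on non-alphanumeric characters (so gene symbols like `p53` survive
intact), stopword-filtered, stripped of single-character tokens, and
Porter-stemmed. The stemmer is an in-package implementation of the
classic suffix-stripping algorithm, verified against its published
example pairs; the stopword list is a standard general-English list and
is caller-replaceable.

Weights follow tf-idf. The idf denominator pools publications and
ontology terms: each publication (title + abstract) and each term
(name + synonyms + description) counts as one document. Cited
references get their own idf over the subset of publications that have
a bibliography. Three conventions are fixed and documented because the
usual definitions leave them open:

* **Log base.** Natural log everywhere. Cosine similarity is invariant
  to a global rescaling of one vector, but idf is per-dimension, so the
  base does affect relative weights; it must simply be consistent.
* **tf denominator.** Token count *after* stopword removal and
  stemming. Out-of-vocabulary tokens still count toward the
  denominator but produce no entry — they cannot match any indexed
  dimension, so assigning them a default idf would only distort norms.
* **Zero-idf words.** A word occurring in every document has idf 0 and
  is dropped from vectors (sparse vectors store no explicit zeros).

Feature bundles: a publication carries W (title+abstract BoW), T (title
BoW), R (reference vector), Y (year). A term carries W (name, synonyms,
description, plus title+abstract of every KB publication *directly*
annotated with it), T (name + synonyms), Y (mean year of those
publications, rounded to the nearest integer), its normalized
name/synonym phrases, and the stem set of its name. Annotations are not
propagated up the DAG at indexing time — a term's text is what is
directly associated with it; a flag enables propagation for
experimentation.

## Scoring

Both scores multiply per-feature factors `(1 + feature)^exponent` with
features in [0, 1], so every score is ≥ 1 and a missing feature
(empty vector, absent year) contributes exactly factor 1: absent
information never penalizes a pair, which matters because reference
lists and years are patchy in real exports and absent entirely for
free-text queries.

* Publication-centric: φ_P(q,p) over f₁ (text cosine), f₂ (title
  cosine), f₃ (reference cosine), f₄ (year proximity,
  `(50 − |ΔY|)/50` clamped to 0 beyond 50 years), exponents
  m = (4, 1, 3, 1). The K = 150 top-ranked KB publications vote for
  their gold terms with weight φ_P; the sensible range for K is
  roughly 50–300. Ranking ties break by ascending PMID for
  determinism, and a query whose PMID exists in the KB is excluded
  from its own neighbor list (leave-one-out), keeping evaluation
  honest.
* Term-centric: Φ_T(q,t) over g₁ (text cosine), g₂ (title-name
  cosine), g₃ (fraction of the term's name stems present in the query
  BoW), g₄ (phrase occurrences of name/synonyms in the raw text,
  capped and normalized to 4), g₅ (year proximity), exponents
  n = (4, 1, 2, 1, 1). g₄ matches case-insensitively on
  whitespace-normalized *unstemmed* text — stemming would destroy the
  multi-word phrases it looks for — counts occurrences at distinct
  start offsets, and sums over the name and all synonyms. For raw-text
  queries g₂ and g₅ vanish automatically (no title vector, no year);
  the caller can mark a text as a title to populate T.

The exponents act as feature weights on very differently distributed
features rather than importance statements. Candidate terms are those
with Φ_P > 0 (the k-NN stage is the candidate generator); a diagnostic
flag scores Φ_T for the whole annotated vocabulary instead. Final
ranking is by Φ = Φ_P · Φ_T, descending, ties by ascending accession,
truncated to the top 10 by default (real annotation sets rarely exceed
10 terms).

## Ontology, information content, similarity

OBO parsing is delegated to `obonet`, with validation on top: obsolete
terms are dropped, `is_a` and (by default) `part_of` relationships both
populate parent edges — standard GO practice, restrictable to `is_a` —
undeclared edge targets and cyclic parent graphs are rejected.

Information content is ic(t) = −ln Pr(t), with Pr(t) the fraction of
background publications whose *ancestor-propagated* gold set contains
t. Propagation guarantees Pr(root) = 1 (ic 0) and makes ic monotone
non-decreasing from root to leaves, which Resnik's
max-over-common-ancestors construction presupposes; a raw-frequency
mode exists behind a flag. Terms never observed in the background get
ic equal to the maximum observed ic — a cap that avoids logs of zero
while keeping them maximally specific (unrepresented test terms are a
real phenomenon at realistic KB sizes). Resnik similarity across
namespaces (no common ancestor) is defined as 0, and Lin similarity is
0 when both terms have ic 0.

## Metrics

Per query with gold set T and ranked prediction P: RR/MRR and recall at
k = 10; hierarchical precision/recall/F on ancestor closures A(·)
(which include the sets themselves); information-theoretic iP/iR,
which first reduce both sets to their leaf antichains L(·) and then
average best-match Lin similarities. Dataset-level hF_max sweeps a
score threshold: precision at threshold s averages only over
predictions with non-empty P_s, recall over all pairs. The sweep visits
every observed prediction score, which attains the exact maximum with
finite work (a fixed grid would only approximate it). The hierarchical
F-measure is the harmonic mean 2·hP·hR/(hP + hR).

Hierarchical precision has a known failure mode — predicting only a
root scores hP = 1 — which the test suite asserts explicitly; iP does
not share it (a root has ic 0, hence Lin similarity 0 to everything).

Baselines: RandFR ranks terms by direct-annotation frequency in the
KB; RandIC ranks each term by its mean single-term information-
theoretic precision against all KB gold sets. Both produce the same
prediction for every query.

## Synthetic benchmark

The generator builds a layered random DAG (each non-root term draws 1–2
parents from the previous layer), assigns each term a disjoint signal
vocabulary of 8 words, and writes documents whose titles are mostly
signal words of their gold terms (titles carry the strongest signal;
title noise is a fifth of the abstract's) and whose abstracts mix
signal and background noise at `noise_rate` (default 0.5, 60 words
from a 500-word noise vocabulary). Gold terms per document follow a
skewed distribution over 1..10 (39% single-term, 99% ≤ 10, mirroring
curated literature annotation sets); citations prefer same-term
documents at probability 0.3; years are uniform on 1990–2015. Term
names and synonyms reuse the term's own signal words so that the
term-centric features have signal, while vocabularies stay disjoint
across terms. Synthetic words are letter+digit hybrids invariant under
Porter stemming, keeping planted vocabularies exactly recoverable
after preprocessing. A held-out query set is generated identically
with disjoint PMIDs. One numpy Generator seeded from a single integer
drives everything; identical seeds give byte-identical fixtures.

Disjoint vocabularies make recovery *easier* than real literature:
passing the planted-recovery benchmark shows the pipeline is correctly
wired and that the classifier separates planted topics from noise and
from both baselines, not that it matches curation-grade accuracy on
real text, where vocabularies overlap heavily, annotation is noisy,
and the vocabulary is three orders of magnitude larger. The benchmark
sizes used by the acceptance script (500 KB documents, 100 queries, 50
terms) are the package's standard desk-scale operating point; the
library itself has no such limits, only an exhaustive (non-
approximate) neighbor scan whose cost grows linearly with the KB.

## Numerical and engineering choices

* Cosine clamps to [0, 1] against last-ulp float drift; empty or zero
  vectors give 0.
* Year averaging for terms rounds to the nearest integer before the
  year-distance feature.
* All tie-breaks (neighbor ranking, prediction ranking, baseline
  rankings) are lexicographic on identifiers, making every artifact
  byte-reproducible.
* The serialized index is a directory of JSON files with sorted keys
  and a schema version; loading a foreign version fails loudly.
* Readers accept gzip transparently; PubMed reference extraction uses
  both ReferenceList and `CommentsCorrections[@RefType="Cites"]`
  because reference availability differs across export vintages.

## Known limitations

* No confidence calibration of the raw Φ scores (they are
  KB-size- and parameter-dependent); downstream users should rank, not
  threshold across KBs.
* Exhaustive k-NN scan; no approximate-neighbor acceleration.
* No n-grams, embeddings, or feature selection in the text model, and
  no fuzzy matching for the phrase-occurrence feature.
* Gene–product linking (which gene a GO assertion is about) is out of
  scope by design — the classifier annotates publications, not genes.
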