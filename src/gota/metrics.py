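"""Evaluation metrics: rank-based, hierarchical, and information-theoretic.

For one query with gold set T and ranked prediction P (P_k = top-k
terms, P_s = terms scoring >= s):

    RR_k   reciprocal rank of the first correct term within the top k
    R_k    |T intersect P_k| / |T|                      (recall at k)
    hP_k   |A(T) intersect A(P_k)| / |A(P_k)|           (hierarchical precision)
    hR_k   |A(T) intersect A(P_k)| / |A(T)|             (hierarchical recall)
    hF_k   harmonic mean of hP_k and hR_k
    iP_k   mean over L(P_k) of the best Lin similarity to a leaf of T
    iR_k   mean over L(T)  of the best Lin similarity to a leaf of P_k

where A is ancestor closure and L leaf reduction. Over a dataset D of
(T, P) pairs, hF_max sweeps a score threshold s: at each s the dataset
hierarchical precision averages only the pairs with a non-empty P_s
while the recall averages all pairs; hF_max is the maximum harmonic
mean over thresholds (the sweep visits every observed score, which
attains the exact maximum).

Hierarchical precision is known to reward overly generic predictions —
a prediction consisting of a root alone gets hP = 1 — which is why the
information-theoretic counterparts are reported alongside.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .classifier import Prediction
from .ontology import ICTable, Ontology, ancestors, leaves, lin


@dataclass
class EvaluationDataset:
    """Pairs of gold-standard term sets and ranked predictions."""

    pairs: list[tuple[frozenset[str], Prediction]]

    def __post_init__(self) -> None:
        if any(not gold for gold, _ in self.pairs):
            raise ValueError("every gold set must be non-empty")

    def __len__(self) -> int:
        return len(self.pairs)


def rr_at_k(gold: frozenset[str], pred: Prediction, k: int) -> float:
    """Reciprocal rank of the first gold term in the top k; 0 if none."""
    if not gold:
        raise ValueError("gold set is empty")
    for i, term in enumerate(pred.top_k(k), start=1):
        if term in gold:
            return 1.0 / i
    return 0.0


def recall_at_k(gold: frozenset[str], pred: Prediction, k: int) -> float:
    """Fraction of gold terms recovered in the top k."""
    if not gold:
        raise ValueError("gold set is empty")
    return len(gold & set(pred.top_k(k))) / len(gold)


def _hier_pr(
    ontology: Ontology, gold: frozenset[str], predicted: frozenset[str]
) -> tuple[float, float, float]:
    if not predicted:
        return 0.0, 0.0, 0.0
    a_gold = ancestors(ontology, gold)
    a_pred = ancestors(ontology, predicted)
    overlap = len(a_gold & a_pred)
    hp = overlap / len(a_pred)
    hr = overlap / len(a_gold)
    hf = 2 * hp * hr / (hp + hr) if hp + hr > 0 else 0.0
    return hp, hr, hf


def hier_pr_at_k(
    ontology: Ontology, gold: frozenset[str], pred: Prediction, k: int
) -> tuple[float, float, float]:
    """(hP_k, hR_k, hF_k) on ancestor closures; (0, 0, 0) for empty P_k."""
    if not gold:
        raise ValueError("gold set is empty")
    return _hier_pr(ontology, gold, frozenset(pred.top_k(k)))


def cafa_hf_max(ontology: Ontology, dataset: EvaluationDataset) -> tuple[float, float]:
    """Threshold-swept dataset hierarchical F-measure.

    Returns (hF_max, argmax threshold). Precision at threshold s
    averages over predictions with non-empty P_s only; recall averages
    over all pairs; pairs with empty P_s contribute hP = hR = 0.
    """
    if not dataset.pairs:
        raise ValueError("empty evaluation dataset")
    thresholds = sorted(
        {score for _, pred in dataset.pairs for _, score in pred.ranked}
    )
    if not thresholds:
        raise ValueError("no prediction carries a score")
    best = (0.0, thresholds[-1])
    for s in thresholds:
        hps, hrs = [], []
        for gold, pred in dataset.pairs:
            hp, hr, _ = _hier_pr(ontology, gold, frozenset(pred.above(s)))
            if pred.above(s):
                hps.append(hp)
            hrs.append(hr)
        if not hps:
            continue
        hp_d = sum(hps) / len(hps)
        hr_d = sum(hrs) / len(hrs)
        if hp_d + hr_d > 0:
            hf = 2 * hp_d * hr_d / (hp_d + hr_d)
            if hf > best[0]:
                best = (hf, s)
    return best


def _best_lin(
    ontology: Ontology, ict: ICTable, sources: frozenset[str], targets: frozenset[str]
) -> float:
    return sum(
        max(lin(ontology, ict, s, t) for t in targets) for s in sources
    ) / len(sources)


def it_precision_at_k(
    ontology: Ontology, ict: ICTable, gold: frozenset[str], pred: Prediction, k: int
) -> float:
    """iP_k: mean best Lin similarity of predicted leaves to gold leaves."""
    if not gold:
        raise ValueError("gold set is empty")
    p_k = frozenset(pred.top_k(k))
    if not p_k:
        raise ValueError("empty prediction")
    return _best_lin(ontology, ict, leaves(ontology, p_k), leaves(ontology, gold))


def it_recall_at_k(
    ontology: Ontology, ict: ICTable, gold: frozenset[str], pred: Prediction, k: int
) -> float:
    """iR_k: mean best Lin similarity of gold leaves to predicted leaves."""
    if not gold:
        raise ValueError("gold set is empty")
    p_k = frozenset(pred.top_k(k))
    if not p_k:
        raise ValueError("empty prediction")
    return _best_lin(ontology, ict, leaves(ontology, gold), leaves(ontology, p_k))


PER_QUERY_METRICS = ("RR_10", "R_10", "hP_10", "hR_10", "hF_10", "iP_1", "iP_10", "iR_10")


def evaluate(
    ontology: Ontology,
    ict: ICTable,
    dataset: EvaluationDataset,
    k: int = 10,
    namespace: str | None = None,
) -> pd.DataFrame:
    """Per-query metric table plus a trailing "mean" summary row.

    Columns: RR_k, R_k, hP_k, hR_k, hF_k, iP_1, iP_k, iR_k, and hF_max
    (dataset-level; repeated on the summary row only). ``namespace``
    restricts gold sets and predictions to one GO namespace before
    scoring.
    """
    if not dataset.pairs:
        raise ValueError("empty evaluation dataset")
    pairs = dataset.pairs
    if namespace is not None:
        restricted = []
        for gold, pred in pairs:
            g = frozenset(t for t in gold if ontology.terms[t].namespace == namespace)
            ranked = tuple(
                (t, s) for t, s in pred.ranked
                if ontology.terms[t].namespace == namespace
            )
            if g and ranked:
                restricted.append((g, Prediction(pred.query_id, ranked)))
        if not restricted:
            raise ValueError(f"no query has gold terms in namespace {namespace!r}")
        pairs = restricted

    rows = []
    for gold, pred in pairs:
        hp, hr, hf = hier_pr_at_k(ontology, gold, pred, k)
        rows.append({
            "query_id": pred.query_id,
            f"RR_{k}": rr_at_k(gold, pred, k),
            f"R_{k}": recall_at_k(gold, pred, k),
            f"hP_{k}": hp,
            f"hR_{k}": hr,
            f"hF_{k}": hf,
            "iP_1": it_precision_at_k(ontology, ict, gold, pred, 1),
            f"iP_{k}": it_precision_at_k(ontology, ict, gold, pred, k),
            f"iR_{k}": it_recall_at_k(ontology, ict, gold, pred, k),
        })
    table = pd.DataFrame(rows)
    hf_max, _ = cafa_hf_max(ontology, EvaluationDataset(list(pairs)))
    summary = table.drop(columns="query_id").mean().to_dict()
    summary["query_id"] = "mean"
    summary["hF_max"] = hf_max
    return pd.concat([table, pd.DataFrame([summary])], ignore_index=True)
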