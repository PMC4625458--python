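"""Compare the classifier with the two naive baselines on held-out queries.

Scores every held-out query with the combined classifier, with RandFR
(terms ranked by knowledge-base annotation frequency) and with RandIC
(terms ranked by mean information-theoretic precision over the KB), then
prints the dataset means of the standard metric suite. MRR_10 and R_10
are rank-based; hR_10 works on ancestor closures; iP_1/iR_10 measure
semantic (Lin) similarity of predictions to gold terms; hF_max is the
threshold-swept hierarchical F-measure. All lie in [0, 1], higher is
better — the classifier should dominate both baselines on every column.
"""

from gota import (
    EvaluationDataset,
    KBIndex,
    SynthConfig,
    baseline_randfr,
    baseline_randic,
    evaluate,
    generate,
    predict,
)

bundle = generate(SynthConfig(seed=7, n_pubs=300, n_queries=30))
index = KBIndex.build(bundle.kb, bundle.ontology)

methods = {
    "GOTA": lambda q: predict(q, index),
    "RandFR": lambda q, p=baseline_randfr(index): p,
    "RandIC": lambda q, p=baseline_randic(index): p,
}
for name, fn in methods.items():
    pairs = [
        (bundle.query_gold.assignments[q.pmid], fn(q)) for q in bundle.queries
    ]
    table = evaluate(bundle.ontology, index.ic, EvaluationDataset(pairs))
    mean = table[table.query_id == "mean"].iloc[0]
    print(
        f"{name:7s} MRR_10={mean['RR_10']:.3f} R_10={mean['R_10']:.3f} "
        f"hR_10={mean['hR_10']:.3f} iP_1={mean['iP_1']:.3f} "
        f"iR_10={mean['iR_10']:.3f} hF_max={mean['hF_max']:.3f}"
    )
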