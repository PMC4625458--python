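"""Generate a synthetic benchmark, index it, and annotate a held-out query.

Builds a 50-term ontology and a 300-publication knowledge base with
planted term-specific vocabularies, then asks the classifier to rank GO
terms for one held-out publication. The printed lines are the top-ranked
terms with their combined scores Phi = Phi_P * Phi_T: Phi_P is the
phi_P-weighted vote of the 150 most similar KB publications, Phi_T the
direct query-term similarity re-weighting. Higher is better; terms in
the query's gold annotation should surface near the top.
"""

from gota import KBIndex, SynthConfig, generate, predict

bundle = generate(SynthConfig(seed=7, n_pubs=300, n_queries=10))
index = KBIndex.build(bundle.kb, bundle.ontology)

query = bundle.queries[0]
gold = bundle.query_gold.assignments[query.pmid]
print(f"query {query.pmid}: title = {query.title!r}")
print(f"gold annotation: {sorted(gold)}")

prediction = predict(query, index, top_n=10)
for rank, (term, score) in enumerate(prediction.ranked, start=1):
    marker = "*" if term in gold else " "
    print(f"  {rank:2d}. {term}  score={score:10.1f} {marker}")
print("(* = term in the gold annotation)")
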