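"""Parse an OBO ontology and compute information content and Lin similarity.

Uses a hand-written five-term ontology and a toy background annotation
set. Information content ic(t) = -ln Pr(t) measures term specificity
(0 at the root, larger for rarer terms); Lin similarity normalizes the
most-informative-common-ancestor (Resnik) score to [0, 1]. Siblings
sharing a specific parent come out similar; terms whose only common
ancestor is the root score 0.
"""

from gota import AnnotationSet, information_content, lin, parse_obo

OBO = """\
format-version: 1.2
ontology: example

[Term]
id: GO:0000001
name: biological process

[Term]
id: GO:0000002
name: metabolic process
is_a: GO:0000001

[Term]
id: GO:0000003
name: signaling
is_a: GO:0000001

[Term]
id: GO:0000004
name: lipid metabolic process
is_a: GO:0000002

[Term]
id: GO:0000005
name: protein metabolic process
is_a: GO:0000002
"""

ontology = parse_obo(OBO)
background = AnnotationSet({
    "p1": frozenset({"GO:0000004"}),
    "p2": frozenset({"GO:0000005"}),
    "p3": frozenset({"GO:0000002"}),
    "p4": frozenset({"GO:0000003"}),
})
ict = information_content(ontology, background)

for acc in sorted(ontology.terms):
    print(f"ic({acc}) = {ict[acc]:.4f}   # {ontology.terms[acc].name}")

pairs = [
    ("GO:0000004", "GO:0000005"),  # siblings under metabolic process
    ("GO:0000004", "GO:0000003"),  # only the root in common
    ("GO:0000004", "GO:0000004"),  # self-similarity
]
for t, p in pairs:
    print(f"lin({t}, {p}) = {lin(ontology, ict, t, p):.4f}")
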