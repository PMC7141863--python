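"""Compile axioms into the relational-pattern graph and emit biased walks.

Axioms involving exactly two named classes become labeled edges; biased
second-order random walks over the (undirected) graph produce node-sequence
sentences — the Node2Vec-style alternative to the axiom-sentence corpus.
"""

from ontoembed import (
    AnnotationAssertion,
    WalkParams,
    build_graph,
    generate_walks,
)
from ontoembed.model import Axiom, Named, OntologySet, Some

onto = OntologySet([
    Axiom("SubClassOf", "GO:0019556", Named("GO:0006547")),
    Axiom("SubClassOf", "GO:0043606", Named("GO:0008152")),
    Axiom("SubClassOf", "GO:0006547", Named("GO:0008152")),
    Axiom("SubClassOf", "GO:0019556",
          Some("has_participant", Named("CHEBI:16397"))),
    Axiom("SubClassOf", "GO:0043606",
          Some("has_participant", Named("CHEBI:16397"))),
])
annotations = [AnnotationAssertion("P31946", "GO:0019556"),
               AnnotationAssertion("P62258", "GO:0043606")]

graph = build_graph(onto, annotations)
print(f"graph: {len(graph.nodes)} nodes, {len(graph.edges)} edges")
for src, dst, label, directed in sorted(graph.edges):
    arrow = "->" if directed else "<->"
    print(f"  {src} {arrow} {dst}   [{label}]")

walks = generate_walks(graph, WalkParams(p=1.0, q=2.0, walk_length=6,
                                         walks_per_node=2, seed=7))
print(f"\n{len(walks)} walks (q=2 keeps walks local); first five:")
for sentence in walks.sentences[:5]:
    print("  ", " -> ".join(sentence))

# Both proteins reach CHEBI:16397 within two hops through their annotated
# processes, so their walk contexts overlap — the co-occurrence signal the
# embedding turns into similarity.
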