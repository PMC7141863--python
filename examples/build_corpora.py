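"""Turn axioms, annotations and class labels into embedding corpora.

Shows the two corpus flavors: the logical corpus (one sentence per axiom,
one per entity annotation) and the meta-data corpus (class labels and
definitions, tokenized).  Both are plain token sentences, ready for the
skip-gram trainer.
"""

from ontoembed import (
    AnnotationAssertion,
    build_logical_corpus,
    build_metadata_corpus,
    saturate,
)
from ontoembed.model import (
    Axiom,
    MetadataAssertion,
    Named,
    OntologySet,
    Some,
)

onto = OntologySet(
    axioms=[
        Axiom("SubClassOf", "GO:0019556", Named("GO:0006547")),
        Axiom("SubClassOf", "GO:0019556",
              Some("has_participant", Named("CHEBI:16397"))),
    ],
    metadata=[
        MetadataAssertion(
            "GO:0019556", "label",
            "Histidine catabolic process to glutamate and formamide"),
        MetadataAssertion("CHEBI:16397", "label", "Formamide"),
    ],
)
annotations = {
    AnnotationAssertion("P31946", "GO:0019556", evidence="EXP"),
    AnnotationAssertion("P62258", "GO:0006547", evidence="IDA"),
}

logical = build_logical_corpus(saturate(onto), annotations)
print("logical corpus (axiom + annotation sentences):")
for sentence in logical:
    print("  ", " ".join(sentence))

meta = build_metadata_corpus(onto, properties=("label",))
print("\nmeta-data corpus (tokenized labels):")
for sentence in meta:
    print("  ", " ".join(sentence))

# Every class CURIE and protein ID is a corpus token, so each one receives
# a vector downstream; the label sentences let two classes become similar
# through shared natural-language words even without a logical link.
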