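import numpy as np
import pytest

from ontoembed.model import (
    And,
    Axiom,
    DISJOINT,
    EQUIV,
    Named,
    OntologySet,
    SUBCLASS,
    Some,
    make_and,
)


@pytest.fixture
def formamide_ontology() -> OntologySet:
    """Tiny ontology around the 'two distant processes share a chemical' motif."""
    return OntologySet([
        Axiom(SUBCLASS, "GO:0019556", Named("GO:0006547")),
        Axiom(SUBCLASS, "GO:0043606", Named("GO:0008152")),
        Axiom(SUBCLASS, "GO:0006547", Named("GO:0008152")),
        Axiom(SUBCLASS, "GO:0019556",
              Some("has_participant", Named("CHEBI:16397"))),
        Axiom(SUBCLASS, "GO:0043606",
              Some("has_participant", Named("CHEBI:16397"))),
    ])


def random_ontology(rng: np.random.Generator, n_classes: int = 30,
                    n_axioms: int = 60, prefixes=("GO", "CHEBI", "PATO")) -> OntologySet:
    """Random small axiom set over a few namespaces, all axiom shapes mixed."""
    classes = [
        f"{prefixes[i % len(prefixes)]}:{i:04d}" for i in range(n_classes)
    ]
    relations = ["part_of", "regulates", "has_participant"]

    def rand_named():
        return Named(classes[int(rng.integers(n_classes))])

    def rand_expr(depth=0):
        r = rng.random()
        if depth >= 2 or r < 0.5:
            return rand_named()
        if r < 0.8:
            return Some(relations[int(rng.integers(len(relations)))],
                        rand_expr(depth + 1))
        return make_and([rand_expr(depth + 1), rand_expr(depth + 1)])

    axioms = []
    for _ in range(n_axioms):
        subject = classes[int(rng.integers(n_classes))]
        kind = [SUBCLASS, SUBCLASS, SUBCLASS, EQUIV, DISJOINT][int(rng.integers(5))]
        obj = rand_named() if kind == DISJOINT else rand_expr()
        axioms.append(Axiom(kind, subject, obj))
    return OntologySet(axioms)
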