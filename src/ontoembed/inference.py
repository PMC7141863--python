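"""Structural saturation of axiom sets.

A lightweight, EL-style closure that supplies the "inferred axioms" the
corpus builder consumes.  Three rules run to fixpoint:

R1  equivalence expansion — ``A EquivalentTo E`` yields ``A SubClassOf c``
    for each conjunct c of E, and additionally ``B SubClassOf A`` when E is
    a named class B;
R2  transitivity of SubClassOf over named classes;
R3  existential filler lifting — ``A SubClassOf R some B`` with B named and
    ``B SubClassOf C`` (C named) yields ``A SubClassOf R some C``.

No rule deepens class expressions, so the closure is finite and the
operation is monotone and idempotent.  Cycles in the hierarchy are allowed:
classes on a cycle become mutual (and self-) subclasses.  Disjointness
axioms pass through untouched.
"""

from __future__ import annotations

import networkx as nx

from .model import (
    And,
    Axiom,
    EQUIV,
    INFERRED,
    Named,
    OntologySet,
    SUBCLASS,
    Some,
)

__all__ = ["saturate"]


def saturate(o: OntologySet) -> OntologySet:
    """Close an axiom set under rules R1–R3.  Output ⊇ input; idempotent."""
    out = o.copy()

    # R1: expand equivalences (one shot; produces only SubClassOf axioms)
    for ax in list(out.axioms):
        if ax.kind != EQUIV:
            continue
        conjuncts = ax.object.operands if isinstance(ax.object, And) else (ax.object,)
        for c in conjuncts:
            out.add(Axiom(SUBCLASS, ax.subject, c, origin=INFERRED, source=ax.source))
        if isinstance(ax.object, Named):
            out.add(
                Axiom(SUBCLASS, ax.object.curie, Named(ax.subject),
                      origin=INFERRED, source=ax.source)
            )

    # R2: transitive closure of the named-subclass graph.  Reachability via a
    # non-trivial path includes self-edges for classes on a cycle.
    g = nx.DiGraph()
    for ax in out.axioms:
        if ax.kind == SUBCLASS and isinstance(ax.object, Named):
            g.add_edge(ax.subject, ax.object.curie)
    closure = nx.transitive_closure(g, reflexive=False)
    for sub, sup in closure.edges:
        out.add(Axiom(SUBCLASS, sub, Named(sup), origin=INFERRED))

    # R3: lift named existential fillers along the closed hierarchy.  The
    # closure edges already include every derivable B ⊑ C, so one pass is a
    # fixpoint (lifted axioms produce nothing new under any rule).
    for ax in list(out.axioms):
        if (
            ax.kind == SUBCLASS
            and isinstance(ax.object, Some)
            and isinstance(ax.object.filler, Named)
        ):
            b = ax.object.filler.curie
            if b in closure:
                for c in closure.successors(b):
                    out.add(
                        Axiom(SUBCLASS, ax.subject, Some(ax.object.relation, Named(c)),
                              origin=INFERRED)
                    )
    return out
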