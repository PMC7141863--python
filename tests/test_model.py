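"""Parsing, serialization and set algebra of the ontology model."""

import numpy as np
import pytest

from ontoembed.model import (
    And,
    Axiom,
    DISJOINT,
    EQUIV,
    MetadataAssertion,
    Named,
    OntologyParseError,
    OntologySet,
    SUBCLASS,
    Some,
    merge_or_substitute,
    parse_axiom_line,
    parse_ontology,
    restrict_to_namespace_links,
    write_ontology,
)

from conftest import random_ontology


class TestAxiomLineParsing:
    def test_existential_bridge_axiom(self):
        ax = parse_axiom_line("GO:0019556 SubClassOf has_participant some CHEBI:16397")
        assert ax.kind == SUBCLASS
        assert ax.subject == "GO:0019556"
        assert ax.object == Some("has_participant", Named("CHEBI:16397"))

    def test_conjunction_is_sorted_and_flattened(self):
        a = parse_axiom_line("A:1 EquivalentTo B:2 and R some C:3")
        b = parse_axiom_line("A:1 EquivalentTo R some C:3 and B:2")
        assert a == b
        assert isinstance(a.object, And)

    def test_some_binds_tighter_than_and(self):
        ax = parse_axiom_line("A:1 SubClassOf R some B:2 and C:3")
        assert ax.object == And((Named("C:3"), Some("R", Named("B:2"))))

    def test_parenthesized_conjunction_filler(self):
        ax = parse_axiom_line("A:1 SubClassOf R some ( B:2 and C:3 )")
        assert ax.object == Some("R", And((Named("B:2"), Named("C:3"))))

    @pytest.mark.parametrize("bad", [
        "A:1 SubClassOf",                      # missing object
        "A:1 Equals B:2",                      # unknown kind
        "A:1 SubClassOf ( B:2",                # unbalanced paren
        "A:1 SubClassOf B:2 C:3",              # trailing tokens
        "A:1 DisjointWith R some B:2",         # disjoint object must be named
    ])
    def test_malformed_lines_rejected(self, bad):
        with pytest.raises(ValueError):
            parse_axiom_line(bad)

    def test_error_names_line_number(self, tmp_path):
        p = tmp_path / "axioms.txt"
        p.write_text("A:1 SubClassOf B:2\nA:1 BadKind B:2\n")
        with pytest.raises(OntologyParseError, match=":2"):
            parse_ontology(p, "axiom-lines")


class TestOboParsing:
    def test_term_stanza(self, tmp_path):
        p = tmp_path / "mini.obo"
        p.write_text(
            "format-version: 1.4\n\n[Term]\nid: A:1\nname: alpha\nis_a: A:2\n"
        )
        o = parse_ontology(p, "obo")
        assert o.axioms == {Axiom(SUBCLASS, "A:1", Named("A:2"))}
        assert o.metadata == {MetadataAssertion("A:1", "label", "alpha")}

    def test_full_tag_mapping(self, tmp_path):
        p = tmp_path / "mini.obo"
        p.write_text("""[Term]
id: GO:0019556
name: histidine catabolic process to glutamate and formamide
def: "A catabolic pathway." []
synonym: "histidine degradation" EXACT []
is_a: GO:0006547
relationship: has_participant CHEBI:16397
disjoint_from: GO:0043606

[Term]
id: GO:0099999
intersection_of: GO:0008152
intersection_of: has_participant CHEBI:16397
""")
        o = parse_ontology(p, "obo")
        assert Axiom(SUBCLASS, "GO:0019556", Named("GO:0006547")) in o
        assert Axiom(SUBCLASS, "GO:0019556",
                     Some("has_participant", Named("CHEBI:16397"))) in o
        assert Axiom(DISJOINT, "GO:0019556", Named("GO:0043606")) in o
        equiv = [ax for ax in o.axioms if ax.kind == EQUIV]
        assert len(equiv) == 1 and isinstance(equiv[0].object, And)
        props = {(m.property, m.text) for m in o.metadata}
        assert ("definition", "A catabolic pathway.") in props
        assert ("synonym", "histidine degradation") in props

    def test_unsupported_tag_warns_and_counts(self, tmp_path):
        p = tmp_path / "mini.obo"
        p.write_text("[Term]\nid: A:1\nunion_of: A:2\nis_a: A:3\n")
        with pytest.warns(UserWarning, match="union_of"):
            o = parse_ontology(p, "obo")
        assert o.report["skipped_unsupported"] == 1
        assert len(o) == 1

    def test_malformed_stanza_names_line(self, tmp_path):
        p = tmp_path / "mini.obo"
        p.write_text("[Term]\nid: A:1\nrelationship: part_of\n")
        with pytest.raises(OntologyParseError, match=":3"):
            parse_ontology(p, "obo")

    def test_empty_file(self, tmp_path):
        p = tmp_path / "empty.axioms"
        p.write_text("")
        o = parse_ontology(p)
        assert len(o) == 0 and len(o.metadata) == 0


@pytest.mark.parametrize("fmt,suffix", [("axiom-lines", ".axioms"), ("obo", ".obo")])
def test_roundtrip_fixpoint(tmp_path, fmt, suffix):
    """Parse → serialize → parse reproduces the identical set in both dialects."""
    rng = np.random.default_rng(42)
    for trial in range(20):
        o = random_ontology(rng, n_classes=15, n_axioms=25)
        if fmt == "obo":
            from ontoembed.model import _obo_expressible
            o = OntologySet([ax for ax in o.axioms if _obo_expressible(ax)],
                            [MetadataAssertion("GO:0001", "label", f"class {trial}")])
        p = tmp_path / f"o{trial}{suffix}"
        write_ontology(o, p, fmt)
        o2 = parse_ontology(p, fmt)
        assert o2.axioms == o.axioms
        if fmt == "obo":
            assert o2.metadata == o.metadata
        # fixpoint: a second round-trip changes nothing
        p2 = tmp_path / f"o{trial}b{suffix}"
        write_ontology(o2, p2, fmt)
        assert parse_ontology(p2, fmt) == o2


class TestRestrictToNamespaceLinks:
    def test_keeps_base_and_one_external(self):
        o = OntologySet([
            Axiom(SUBCLASS, "GO:1", Named("GO:2")),
            Axiom(SUBCLASS, "GO:1", Some("has_participant", Named("CHEBI:1"))),
            Axiom(SUBCLASS, "GO:2", Some("has_quality", Named("PATO:1"))),
        ])
        r = restrict_to_namespace_links(o, "CHEBI", "GO")
        assert {ax.serialize() for ax in r.axioms} == {
            "GO:1 SubClassOf GO:2",
            "GO:1 SubClassOf has_participant some CHEBI:1",
        }

    def test_absent_prefix_leaves_base_internal_only(self):
        o = OntologySet([
            Axiom(SUBCLASS, "GO:1", Named("GO:2")),
            Axiom(SUBCLASS, "GO:2", Some("has_quality", Named("PATO:1"))),
        ])
        r = restrict_to_namespace_links(o, "CL", "GO")
        assert {ax.serialize() for ax in r.axioms} == {"GO:1 SubClassOf GO:2"}

    def test_matches_bruteforce_prefix_scan(self):
        rng = np.random.default_rng(7)
        for _ in range(10):
            o = random_ontology(rng, n_classes=24, n_axioms=50)
            r = restrict_to_namespace_links(o, "CHEBI", "GO")
            expected = {
                ax for ax in o.axioms
                if ax.mentioned_prefixes() <= {"GO", "CHEBI"}
            }
            assert r.axioms == frozenset(expected)
            # subset of input, idempotent
            assert r.axioms <= o.axioms
            assert restrict_to_namespace_links(r, "CHEBI", "GO").axioms == r.axioms


class TestMergeOrSubstitute:
    def test_union_is_idempotent(self, formamide_ontology):
        merged = merge_or_substitute(formamide_ontology, formamide_ontology)
        assert merged == formamide_ontology

    def test_union_commutative_and_empty_identity(self, formamide_ontology):
        empty = OntologySet()
        assert merge_or_substitute(formamide_ontology, empty) == formamide_ontology
        a = OntologySet([Axiom(SUBCLASS, "A:1", Named("A:2"))])
        assert (merge_or_substitute(a, formamide_ontology)
                == merge_or_substitute(formamide_ontology, a))

    def test_substitution_replaces_internal_axioms(self):
        host = OntologySet([
            Axiom(SUBCLASS, "GO:1", Named("GO:2")),
            Axiom(SUBCLASS, "GO:2", Named("GO:3")),
            Axiom(SUBCLASS, "GO:3", Named("GO:4")),
            Axiom(SUBCLASS, "HP:1", Some("part_of", Named("GO:1"))),
            Axiom(SUBCLASS, "HP:2", Named("HP:1")),
        ])
        incoming = OntologySet([
            Axiom(SUBCLASS, "GO:1", Named("GO:9")),
            Axiom(SUBCLASS, "GO:1", Some("has_participant", Named("CHEBI:1"))),
        ])
        out = merge_or_substitute(host, incoming, replace_prefix="GO")
        # the 3 GO-internal host axioms are gone; cross and HP axioms survive
        assert out.axioms == frozenset(
            [Axiom(SUBCLASS, "HP:1", Some("part_of", Named("GO:1"))),
             Axiom(SUBCLASS, "HP:2", Named("HP:1"))] + list(incoming.axioms)
        )

    def test_asserted_wins_over_inferred_on_merge(self):
        inf = OntologySet([Axiom(SUBCLASS, "A:1", Named("A:2"), origin="inferred")])
        asrt = OntologySet([Axiom(SUBCLASS, "A:1", Named("A:2"), origin="asserted")])
        merged = merge_or_substitute(inf, asrt)
        assert next(iter(merged.axioms)).origin == "asserted"
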