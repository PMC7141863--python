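"""Ontology axiom model: class expressions, axioms, meta-data and axiom sets.

The representation is deliberately small: named classes are CURIEs
(``PREFIX:LOCALID``), and the only complex class expressions are existential
restrictions (``R some Y``) and conjunctions.  This is the fragment that the
downstream corpus, graph and embedding machinery exploits — subclass,
equivalence and disjointness structure over named classes and existentials.

Two serializations are supported: a line-based axiom text format (one axiom
per line, whitespace-tokenized, Manchester-like) and a subset of the OBO 1.4
flat-file format.  Parse → serialize → parse is a fixpoint for both.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Iterator, Optional, Union

__all__ = [
    "Named",
    "Some",
    "And",
    "ClassExpr",
    "Axiom",
    "MetadataAssertion",
    "OntologySet",
    "parse_ontology",
    "parse_axiom_line",
    "write_ontology",
    "restrict_to_namespace_links",
    "merge_or_substitute",
    "SUBCLASS",
    "EQUIV",
    "DISJOINT",
]

CURIE_RE = re.compile(r"^[A-Za-z][A-Za-z0-9_]*:[A-Za-z0-9_]+$")
BARE_RE = re.compile(r"^[A-Za-z_][A-Za-z0-9_]*$")

SUBCLASS = "SubClassOf"
EQUIV = "EquivalentTo"
DISJOINT = "DisjointWith"
KINDS = (SUBCLASS, EQUIV, DISJOINT)

ASSERTED = "asserted"
INFERRED = "inferred"


class OntologyParseError(ValueError):
    """Raised on malformed input, carrying the offending line number."""


# ---------------------------------------------------------------------------
# Class expressions


@dataclass(frozen=True)
class Named:
    """A named class, identified by its CURIE."""

    curie: str

    def __post_init__(self) -> None:
        if not CURIE_RE.match(self.curie):
            raise ValueError(f"not a valid CURIE: {self.curie!r}")


@dataclass(frozen=True)
class Some:
    """Existential restriction ``relation some filler``."""

    relation: str
    filler: "ClassExpr"

    def __post_init__(self) -> None:
        if not (CURIE_RE.match(self.relation) or BARE_RE.match(self.relation)):
            raise ValueError(f"not a valid relation identifier: {self.relation!r}")


@dataclass(frozen=True)
class And:
    """Conjunction of two or more class expressions (canonically sorted)."""

    operands: tuple["ClassExpr", ...]

    def __post_init__(self) -> None:
        if len(self.operands) < 2:
            raise ValueError("conjunction needs at least 2 operands")


ClassExpr = Union[Named, Some, And]


def make_and(operands: Iterable[ClassExpr]) -> ClassExpr:
    """Build a canonical conjunction: flattened, deduplicated, sorted.

    Collapses to the single operand if deduplication leaves only one.
    """
    flat: list[ClassExpr] = []
    for op in operands:
        if isinstance(op, And):
            flat.extend(op.operands)
        else:
            flat.append(op)
    uniq = sorted(set(flat), key=lambda e: expr_tokens(e))
    if len(uniq) == 1:
        return uniq[0]
    return And(tuple(uniq))


def expr_tokens(e: ClassExpr) -> tuple[str, ...]:
    """Canonical whitespace-token serialization of a class expression."""
    if isinstance(e, Named):
        return (e.curie,)
    if isinstance(e, Some):
        inner = expr_tokens(e.filler)
        if isinstance(e.filler, And):
            inner = ("(",) + inner + (")",)
        return (e.relation, "some") + inner
    if isinstance(e, And):
        parts: list[str] = []
        for i, op in enumerate(e.operands):
            if i:
                parts.append("and")
            parts.extend(expr_tokens(op))
        return tuple(parts)
    raise TypeError(f"not a class expression: {e!r}")


def named_classes(e: ClassExpr) -> set[str]:
    """All named-class CURIEs mentioned in an expression (relations excluded)."""
    if isinstance(e, Named):
        return {e.curie}
    if isinstance(e, Some):
        return named_classes(e.filler)
    out: set[str] = set()
    for op in e.operands:
        out |= named_classes(op)
    return out


# ---------------------------------------------------------------------------
# Axioms and meta-data


@dataclass(frozen=True)
class Axiom:
    """A normalized logical statement over a named subject class.

    Identity (equality/hash) is ``(kind, subject, canonical object tokens)``;
    ``origin`` and ``source`` are provenance and do not distinguish axioms.
    """

    kind: str
    subject: str
    object: ClassExpr
    origin: str = field(default=ASSERTED, compare=False)
    source: str = field(default="", compare=False)

    def __post_init__(self) -> None:
        if self.kind not in KINDS:
            raise ValueError(f"unknown axiom kind: {self.kind!r}")
        if not CURIE_RE.match(self.subject):
            raise ValueError(f"axiom subject must be a named class: {self.subject!r}")
        if self.kind == DISJOINT and not isinstance(self.object, Named):
            raise ValueError("DisjointWith objects must be named classes")

    def tokens(self) -> tuple[str, ...]:
        return (self.subject, self.kind) + expr_tokens(self.object)

    def mentioned_classes(self) -> set[str]:
        return {self.subject} | named_classes(self.object)

    def mentioned_prefixes(self) -> set[str]:
        return {c.split(":", 1)[0] for c in self.mentioned_classes()}

    def serialize(self) -> str:
        return " ".join(self.tokens())


METADATA_PROPERTIES = ("label", "synonym", "definition", "comment")


@dataclass(frozen=True)
class MetadataAssertion:
    """A natural-language annotation property on a class."""

    subject: str
    property: str
    text: str

    def __post_init__(self) -> None:
        if self.property not in METADATA_PROPERTIES:
            raise ValueError(f"unknown metadata property: {self.property!r}")
        if not self.text:
            raise ValueError("metadata text must be non-empty")


# ---------------------------------------------------------------------------
# Ontology sets


class OntologySet:
    """A deduplicated set of axioms plus class meta-data.

    Duplicate axioms (same identity key) collapse to one; an asserted
    duplicate wins over an inferred one.  The prefix registry records every
    CURIE prefix seen in axiom classes.
    """

    def __init__(
        self,
        axioms: Iterable[Axiom] = (),
        metadata: Iterable[MetadataAssertion] = (),
    ) -> None:
        self._axioms: dict[Axiom, Axiom] = {}
        self._metadata: set[MetadataAssertion] = set()
        self.report: dict[str, int] = {}
        for ax in axioms:
            self.add(ax)
        for m in metadata:
            self._metadata.add(m)

    # -- collection protocol -------------------------------------------------
    @property
    def axioms(self) -> frozenset[Axiom]:
        return frozenset(self._axioms.values())

    @property
    def metadata(self) -> frozenset[MetadataAssertion]:
        return frozenset(self._metadata)

    @property
    def prefixes(self) -> frozenset[str]:
        out: set[str] = set()
        for ax in self._axioms.values():
            out |= ax.mentioned_prefixes()
        return frozenset(out)

    def add(self, ax: Axiom) -> None:
        prev = self._axioms.get(ax)
        if prev is None or (prev.origin == INFERRED and ax.origin == ASSERTED):
            self._axioms[ax] = ax

    def add_metadata(self, m: MetadataAssertion) -> None:
        self._metadata.add(m)

    def __len__(self) -> int:
        return len(self._axioms)

    def __iter__(self) -> Iterator[Axiom]:
        return iter(sorted(self._axioms.values(), key=Axiom.tokens))

    def __contains__(self, ax: Axiom) -> bool:
        return ax in self._axioms

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, OntologySet):
            return NotImplemented
        return self.axioms == other.axioms and self.metadata == other.metadata

    def __repr__(self) -> str:
        return f"OntologySet({len(self)} axioms, {len(self._metadata)} metadata)"

    def copy(self) -> "OntologySet":
        return OntologySet(self._axioms.values(), self._metadata)


# ---------------------------------------------------------------------------
# Axiom-line dialect


def _parse_expr(tokens: list[str], pos: int) -> tuple[ClassExpr, int]:
    operands = []
    op, pos = _parse_atom(tokens, pos)
    operands.append(op)
    while pos < len(tokens) and tokens[pos] == "and":
        op, pos = _parse_atom(tokens, pos + 1)
        operands.append(op)
    if len(operands) == 1:
        return operands[0], pos
    return make_and(operands), pos


def _parse_atom(tokens: list[str], pos: int) -> tuple[ClassExpr, int]:
    if pos >= len(tokens):
        raise ValueError("unexpected end of expression")
    tok = tokens[pos]
    if tok == "(":
        expr, pos = _parse_expr(tokens, pos + 1)
        if pos >= len(tokens) or tokens[pos] != ")":
            raise ValueError("unbalanced parenthesis")
        return expr, pos + 1
    if pos + 1 < len(tokens) and tokens[pos + 1] == "some":
        filler, pos = _parse_atom(tokens, pos + 2)
        return Some(tok, filler), pos
    if not CURIE_RE.match(tok):
        raise ValueError(f"expected a CURIE, got {tok!r}")
    return Named(tok), pos + 1


def parse_axiom_line(line: str, source: str = "") -> Axiom:
    """Parse one ``SUBJ kind EXPR`` axiom line."""
    tokens = line.split()
    if len(tokens) < 3:
        raise ValueError("axiom line needs at least 3 tokens")
    subject, kind = tokens[0], tokens[1]
    if kind not in KINDS:
        raise ValueError(f"unknown axiom kind: {kind!r}")
    obj, pos = _parse_expr(tokens, 2)
    if pos != len(tokens):
        raise ValueError(f"trailing tokens: {' '.join(tokens[pos:])!r}")
    return Axiom(kind, subject, obj, origin=ASSERTED, source=source)


def _parse_axiom_lines(path: Path, source: str) -> OntologySet:
    out = OntologySet()
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            try:
                out.add(parse_axiom_line(line, source=source))
            except ValueError as exc:
                raise OntologyParseError(f"{path}:{lineno}: {exc}") from exc
    return out


def _write_axiom_lines(o: OntologySet, path: Path) -> None:
    with open(path, "w") as fh:
        for ax in o:
            fh.write(ax.serialize() + "\n")


# ---------------------------------------------------------------------------
# OBO 1.4 subset dialect

_QUOTED_RE = re.compile(r'^"((?:[^"\\]|\\.)*)"')

# stanza tags that carry no logical or supported meta-data content; ignored
_OBO_IGNORED = {
    "namespace", "alt_id", "xref", "subset", "created_by", "creation_date",
    "is_obsolete", "replaced_by", "consider", "property_value",
}


def _strip_obo_comment(value: str) -> str:
    # OBO trailing comments start with " ! "
    idx = value.find(" ! ")
    if idx >= 0:
        value = value[:idx]
    if value.startswith("!"):
        value = ""
    return value.strip()


def _obo_intersection_element(value: str) -> ClassExpr:
    parts = value.split()
    if len(parts) == 1:
        return Named(parts[0])
    if len(parts) == 2:
        return Some(parts[0], Named(parts[1]))
    raise ValueError(f"malformed intersection_of value: {value!r}")


def _parse_obo(path: Path, source: str) -> OntologySet:
    out = OntologySet()
    skipped = 0
    in_term = False
    term_id: Optional[str] = None
    intersection: list[ClassExpr] = []
    pending: list[tuple[int, str, str]] = []  # (lineno, tag, value) for current term

    def flush(lineno: int) -> None:
        nonlocal term_id, intersection, pending
        if not in_term and term_id is None:
            return
        if term_id is None:
            if pending or intersection:
                raise OntologyParseError(f"{path}:{lineno}: [Term] stanza without id")
            return
        for ln, tag, value in pending:
            try:
                _apply_obo_tag(out, term_id, tag, value, source)
            except ValueError as exc:
                raise OntologyParseError(f"{path}:{ln}: {exc}") from exc
        if len(intersection) == 1:
            raise OntologyParseError(
                f"{path}:{lineno}: intersection_of needs at least two elements"
            )
        if intersection:
            out.add(
                Axiom(EQUIV, term_id, make_and(intersection), origin=ASSERTED, source=source)
            )
        term_id = None
        intersection = []
        pending = []

    with open(path) as fh:
        lineno = 0
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n").strip()
            if not line or line.startswith("!"):
                continue
            if line.startswith("["):
                flush(lineno)
                in_term = line == "[Term]"
                if not in_term and line not in ("[Typedef]", "[Instance]"):
                    raise OntologyParseError(f"{path}:{lineno}: unknown stanza {line!r}")
                continue
            if not in_term:
                continue  # header and typedef lines
            if ":" not in line:
                raise OntologyParseError(f"{path}:{lineno}: malformed tag line {line!r}")
            tag, value = line.split(":", 1)
            tag = tag.strip()
            value = value.strip()
            if tag == "id":
                term_id = _strip_obo_comment(value)
                if not CURIE_RE.match(term_id):
                    raise OntologyParseError(f"{path}:{lineno}: bad term id {term_id!r}")
            elif tag == "intersection_of":
                intersection.append(_obo_intersection_element(_strip_obo_comment(value)))
            elif tag in _OBO_IGNORED:
                continue
            elif tag in ("is_a", "relationship", "disjoint_from", "name",
                         "synonym", "def", "comment"):
                pending.append((lineno, tag, value))
            else:
                warnings.warn(f"{path}:{lineno}: unsupported OBO tag {tag!r} skipped")
                skipped += 1
        flush(lineno)
    out.report = {"skipped_unsupported": skipped}
    return out


def _apply_obo_tag(out: OntologySet, term_id: str, tag: str, value: str, source: str) -> None:
    if tag in ("is_a", "relationship", "disjoint_from"):
        value = _strip_obo_comment(value)
    if tag == "is_a":
        out.add(Axiom(SUBCLASS, term_id, Named(value), origin=ASSERTED, source=source))
    elif tag == "relationship":
        parts = value.split()
        if len(parts) != 2:
            raise ValueError(f"malformed relationship value: {value!r}")
        out.add(
            Axiom(SUBCLASS, term_id, Some(parts[0], Named(parts[1])),
                  origin=ASSERTED, source=source)
        )
    elif tag == "disjoint_from":
        out.add(Axiom(DISJOINT, term_id, Named(value), origin=ASSERTED, source=source))
    elif tag == "name":
        out.add_metadata(MetadataAssertion(term_id, "label", value))
    elif tag == "comment":
        out.add_metadata(MetadataAssertion(term_id, "comment", value))
    elif tag in ("synonym", "def"):
        m = _QUOTED_RE.match(value)
        if not m:
            raise ValueError(f"expected quoted text in {tag} value: {value!r}")
        text = m.group(1).replace('\\"', '"')
        prop = "synonym" if tag == "synonym" else "definition"
        out.add_metadata(MetadataAssertion(term_id, prop, text))


def _obo_expressible(ax: Axiom) -> bool:
    if ax.kind == SUBCLASS:
        return isinstance(ax.object, Named) or (
            isinstance(ax.object, Some) and isinstance(ax.object.filler, Named)
        )
    if ax.kind == DISJOINT:
        return True
    if ax.kind == EQUIV:
        if not isinstance(ax.object, And):
            return False
        return all(
            isinstance(op, Named)
            or (isinstance(op, Some) and isinstance(op.filler, Named))
            for op in ax.object.operands
        )
    return False


def _write_obo(o: OntologySet, path: Path) -> None:
    terms: set[str] = set()
    for ax in o:
        if not _obo_expressible(ax):
            raise ValueError(
                f"axiom not expressible in the OBO subset: {ax.serialize()!r}; "
                "use the axiom-lines format instead"
            )
        terms |= ax.mentioned_classes()
    for m in o.metadata:
        terms.add(m.subject)

    by_subject: dict[str, list[Axiom]] = {}
    for ax in o:
        by_subject.setdefault(ax.subject, []).append(ax)
    meta: dict[str, list[MetadataAssertion]] = {}
    for m in o.metadata:
        meta.setdefault(m.subject, []).append(m)

    with open(path, "w") as fh:
        fh.write("format-version: 1.4\n")
        for term in sorted(terms):
            fh.write(f"\n[Term]\nid: {term}\n")
            for m in sorted(meta.get(term, []), key=lambda m: (m.property, m.text)):
                if m.property == "label":
                    fh.write(f"name: {m.text}\n")
                elif m.property == "definition":
                    fh.write(f'def: "{m.text}" []\n')
                elif m.property == "synonym":
                    fh.write(f'synonym: "{m.text}" EXACT []\n')
                elif m.property == "comment":
                    fh.write(f"comment: {m.text}\n")
            for ax in sorted(by_subject.get(term, []), key=Axiom.tokens):
                if ax.kind == SUBCLASS and isinstance(ax.object, Named):
                    fh.write(f"is_a: {ax.object.curie}\n")
                elif ax.kind == SUBCLASS:
                    assert isinstance(ax.object, Some)
                    fh.write(
                        f"relationship: {ax.object.relation} {ax.object.filler.curie}\n"
                    )
                elif ax.kind == DISJOINT:
                    fh.write(f"disjoint_from: {ax.object.curie}\n")
                elif ax.kind == EQUIV:
                    assert isinstance(ax.object, And)
                    for op in ax.object.operands:
                        if isinstance(op, Named):
                            fh.write(f"intersection_of: {op.curie}\n")
                        else:
                            fh.write(
                                f"intersection_of: {op.relation} {op.filler.curie}\n"
                            )


# ---------------------------------------------------------------------------
# Public IO


def parse_ontology(path: str | Path, format: str = "auto",
                   source: Optional[str] = None) -> OntologySet:
    """Read an ontology file in OBO or axiom-lines format.

    ``format='auto'`` picks OBO for ``.obo`` files and axiom-lines otherwise.
    All parsed axioms carry ``origin='asserted'``; ``source`` defaults to the
    filename stem.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if source is None:
        source = path.stem
    if format == "auto":
        format = "obo" if path.suffix == ".obo" else "axiom-lines"
    if format == "obo":
        return _parse_obo(path, source)
    if format == "axiom-lines":
        return _parse_axiom_lines(path, source)
    raise ValueError(f"unknown ontology format: {format!r}")


def write_ontology(o: OntologySet, path: str | Path, format: str = "auto") -> None:
    """Serialize an OntologySet to OBO or axiom-lines format."""
    path = Path(path)
    if format == "auto":
        format = "obo" if path.suffix == ".obo" else "axiom-lines"
    if format == "obo":
        _write_obo(o, path)
    elif format == "axiom-lines":
        _write_axiom_lines(o, path)
    else:
        raise ValueError(f"unknown ontology format: {format!r}")


# ---------------------------------------------------------------------------
# Set-level operations


def restrict_to_namespace_links(o: OntologySet, external_prefix: str,
                                base_prefix: str) -> OntologySet:
    """Keep base-internal axioms plus cross-references into one external ontology.

    An axiom survives iff every named class it mentions has prefix
    ``base_prefix`` or ``external_prefix``.  Meta-data survives for classes of
    either prefix.  Output is a subset of the input; idempotent.
    """
    keep = {base_prefix, external_prefix}
    axioms = [ax for ax in o.axioms if ax.mentioned_prefixes() <= keep]
    metadata = [m for m in o.metadata if m.subject.split(":", 1)[0] in keep]
    return OntologySet(axioms, metadata)


def merge_or_substitute(host: OntologySet, incoming: OntologySet,
                        replace_prefix: Optional[str] = None) -> OntologySet:
    """Union two axiom sets, optionally replacing one sub-ontology.

    With ``replace_prefix`` given, every host axiom whose mentioned classes
    are all of that prefix (and host meta-data on classes of that prefix) is
    deleted before the union — the "swap the GO inside a host ontology for
    GO-Plus" operation.  Without it this is a plain deduplicating union,
    commutative and idempotent.
    """
    if replace_prefix is None:
        kept_axioms: Iterable[Axiom] = host.axioms
        kept_meta: Iterable[MetadataAssertion] = host.metadata
    else:
        kept_axioms = [
            ax for ax in host.axioms
            if ax.mentioned_prefixes() != {replace_prefix}
        ]
        kept_meta = [
            m for m in host.metadata
            if m.subject.split(":", 1)[0] != replace_prefix
        ]
    out = OntologySet(kept_axioms, kept_meta)
    for ax in incoming.axioms:
        out.add(ax)
    for m in incoming.metadata:
        out.add_metadata(m)
    return out
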