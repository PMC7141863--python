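"""Sentence corpora from axioms, annotations and class meta-data.

The embedding stage consumes plain token sentences.  Three corpus sources
exist: (1) logical-axiom sentences — one sentence per axiom, in its
canonical token serialization — plus one sentence per entity→class
annotation; (2) meta-data sentences — class labels, synonyms, definitions
and comments, tokenized; (3) an optional user-supplied background text file.
Corpora are pure functions of their inputs: bit-identical across runs.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Optional

from .model import CURIE_RE, OntologySet

__all__ = [
    "AnnotationAssertion",
    "Corpus",
    "read_annotations",
    "build_logical_corpus",
    "build_metadata_corpus",
    "read_background_corpus",
    "tokenize_text",
    "DEFAULT_ANNOTATION_RELATION",
]

DEFAULT_ANNOTATION_RELATION = "hasAssociation"


class AnnotationParseError(ValueError):
    """Malformed annotation row, carrying the offending line number."""


@dataclass(frozen=True)
class AnnotationAssertion:
    """An entity→class link, optionally tagged with an evidence code."""

    entity: str
    cls: str
    evidence: Optional[str] = None

    def __post_init__(self) -> None:
        if not CURIE_RE.match(self.cls):
            raise ValueError(f"annotation class must be a CURIE: {self.cls!r}")
        # entity IDs live in a token space disjoint from class CURIEs
        if ":" in self.entity and not self.entity.startswith("ENT:"):
            raise ValueError(
                f"entity id {self.entity!r} contains ':' without the ENT prefix"
            )


@dataclass(frozen=True)
class Corpus:
    """An ordered list of token sentences."""

    sentences: tuple[tuple[str, ...], ...]

    def __post_init__(self) -> None:
        if any(len(s) == 0 for s in self.sentences):
            raise ValueError("corpus must not contain empty sentences")

    def __len__(self) -> int:
        return len(self.sentences)

    def __iter__(self):
        return iter(self.sentences)

    def __add__(self, other: "Corpus") -> "Corpus":
        return Corpus(self.sentences + other.sentences)

    def vocabulary(self) -> set[str]:
        return {t for s in self.sentences for t in s}

    def save(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for s in self.sentences:
                fh.write(" ".join(s) + "\n")

    @classmethod
    def load(cls, path: str | Path) -> "Corpus":
        sentences = []
        with open(path) as fh:
            for line in fh:
                toks = tuple(line.split())
                if toks:
                    sentences.append(toks)
        return cls(tuple(sentences))


# ---------------------------------------------------------------------------
# Annotation files


def read_annotations(
    path: str | Path,
    dialect: str = "tsv",
    excluded_evidence: Iterable[str] = (),
) -> set[AnnotationAssertion]:
    """Read entity→class annotations, dropping excluded evidence codes.

    ``tsv``: columns entity, class[, evidence].  ``gaf``: GAF 2.x — comment
    lines start with ``!``, column 2 is the entity, column 5 the class,
    column 7 the evidence code.
    """
    excluded = set(excluded_evidence)
    out: set[AnnotationAssertion] = set()
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip():
                continue
            if dialect == "gaf":
                if line.startswith("!"):
                    continue
                cols = line.split("\t")
                if len(cols) < 7 or not cols[1].strip() or not cols[4].strip():
                    raise AnnotationParseError(
                        f"{path}:{lineno}: GAF row missing entity or class"
                    )
                entity, cls, evidence = cols[1].strip(), cols[4].strip(), cols[6].strip()
            elif dialect == "tsv":
                if line.startswith("#"):
                    continue
                cols = line.split("\t")
                if len(cols) < 2 or not cols[0].strip() or not cols[1].strip():
                    raise AnnotationParseError(
                        f"{path}:{lineno}: row missing entity or class"
                    )
                entity, cls = cols[0].strip(), cols[1].strip()
                evidence = cols[2].strip() if len(cols) > 2 and cols[2].strip() else None
            else:
                raise ValueError(f"unknown annotation dialect: {dialect!r}")
            if evidence in excluded:
                continue
            try:
                out.add(AnnotationAssertion(entity, cls, evidence or None))
            except ValueError as exc:
                raise AnnotationParseError(f"{path}:{lineno}: {exc}") from exc
    return out


def write_annotations(annotations: Iterable[AnnotationAssertion],
                      path: str | Path) -> None:
    with open(path, "w") as fh:
        for a in sorted(annotations, key=lambda a: (a.entity, a.cls, a.evidence or "")):
            cols = [a.entity, a.cls] + ([a.evidence] if a.evidence else [])
            fh.write("\t".join(cols) + "\n")


# ---------------------------------------------------------------------------
# Corpus builders


def build_logical_corpus(
    o: OntologySet,
    annotations: Iterable[AnnotationAssertion] = (),
    annotation_relation: str = DEFAULT_ANNOTATION_RELATION,
) -> Corpus:
    """One sentence per axiom plus one per annotation, canonically ordered.

    Axiom sentences are the canonical token serialization (subject, kind
    keyword, object tokens with ``some``/``and``); annotation sentences are
    the triple (entity, annotation relation, class).  Axiom sentences come
    first, each group sorted lexicographically — the corpus is a pure
    function of the inputs.
    """
    axiom_sentences = sorted(ax.tokens() for ax in o.axioms)
    ann_sentences = sorted(
        (a.entity, annotation_relation, a.cls) for a in set(annotations)
    )
    return Corpus(tuple(axiom_sentences) + tuple(ann_sentences))


# splitting keeps symbol-heavy chemistry tokens intact: whitespace plus a
# small punctuation set only, and CURIE-shaped tokens pass through verbatim
_SPLIT_RE = re.compile(r'[\s.,;()\[\]{}"]+')


def tokenize_text(text: str) -> tuple[str, ...]:
    """Lowercasing tokenizer for meta-data text; CURIEs keep their case."""
    out = []
    for tok in _SPLIT_RE.split(text):
        if not tok:
            continue
        out.append(tok if CURIE_RE.match(tok) else tok.lower())
    return tuple(out)


def build_metadata_corpus(
    o: OntologySet,
    properties: Iterable[str] = ("label", "synonym", "definition"),
) -> Corpus:
    """One sentence per selected meta-data assertion: subject, property, text tokens."""
    props = set(properties)
    sentences = []
    for m in o.metadata:
        if m.property not in props:
            continue
        toks = tokenize_text(m.text)
        if toks:
            sentences.append((m.subject, m.property) + toks)
    return Corpus(tuple(sorted(sentences)))


def read_background_corpus(path: str | Path) -> Corpus:
    """A user-supplied plain-text background corpus: one sentence per line."""
    sentences = []
    with open(path) as fh:
        for line in fh:
            toks = tokenize_text(line)
            if toks:
                sentences.append(toks)
    return Corpus(tuple(sentences))
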