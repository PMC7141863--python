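"""Relational-pattern graph and biased (Node2Vec-style) random walks.

Axioms involving exactly two named classes compile to labeled edges:
``X SubClassOf Y`` → X→Y labeled ``subClassOf``; ``X SubClassOf R some Y``
→ X→Y labeled R; equivalence versions of either produce the edge in both
directions; ``X DisjointWith Y`` → X→Y labeled ``disjointWith``; each
entity annotation adds an entity→class edge.  Axioms mentioning any other
number of named classes contribute no edge (saturation has already
decomposed genus–differentia equivalences into two-class axioms).

Walks are second-order biased random walks with return parameter p and
in-out parameter q.  Edge direction is stored but traversal is undirected —
pure forward traversal would dead-end at ontology roots and starve leaf
classes of context.  Edge labels do not enter walk sentences; the corpus is
node sequences only.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

import numpy as np

from .corpus import AnnotationAssertion, Corpus, DEFAULT_ANNOTATION_RELATION
from .model import Axiom, DISJOINT, EQUIV, Named, OntologySet, SUBCLASS, Some

__all__ = ["Graph", "WalkParams", "build_graph", "generate_walks"]

SUBCLASS_LABEL = "subClassOf"
DISJOINT_LABEL = "disjointWith"


@dataclass(frozen=True)
class Graph:
    """Labeled directed graph over class CURIEs and entity IDs."""

    nodes: frozenset[str]
    edges: frozenset[tuple[str, str, str, bool]]  # (src, dst, label, directed)

    def save_edgelist(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for src, dst, label, directed in sorted(self.edges):
                fh.write(f"{src}\t{label}\t{dst}\t{'directed' if directed else 'bidirectional'}\n")

    def undirected_adjacency(self) -> dict[str, list[str]]:
        """Neighbor lists ignoring direction; multi-edges collapsed; sorted."""
        adj: dict[str, set[str]] = {n: set() for n in self.nodes}
        for src, dst, _label, _directed in self.edges:
            adj[src].add(dst)
            adj[dst].add(src)
        return {n: sorted(nbrs) for n, nbrs in adj.items()}


@dataclass(frozen=True)
class WalkParams:
    """Node2Vec walk parameters: return bias p, in-out bias q."""

    p: float = 1.0
    q: float = 1.0
    walk_length: int = 20
    walks_per_node: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        if self.p <= 0 or self.q <= 0:
            raise ValueError("p and q must be positive")
        if self.walk_length < 1 or self.walks_per_node < 1:
            raise ValueError("walk_length and walks_per_node must be >= 1")


def _axiom_edge(ax: Axiom) -> tuple[str, str, str, bool] | None:
    """Map a two-named-class axiom to (src, dst, label, directed) or None."""
    if ax.kind == DISJOINT:
        assert isinstance(ax.object, Named)
        return (ax.subject, ax.object.curie, DISJOINT_LABEL, True)
    if isinstance(ax.object, Named):
        label, dst = SUBCLASS_LABEL, ax.object.curie
    elif isinstance(ax.object, Some) and isinstance(ax.object.filler, Named):
        label, dst = ax.object.relation, ax.object.filler.curie
    else:
        return None  # ≠2 named classes → no edge
    if ax.kind == SUBCLASS:
        return (ax.subject, dst, label, True)
    if ax.kind == EQUIV:
        return (ax.subject, dst, label, False)  # bidirectional
    return None


def build_graph(o: OntologySet,
                annotations: Iterable[AnnotationAssertion] = (),
                annotation_relation: str = DEFAULT_ANNOTATION_RELATION) -> Graph:
    """Compile the relational-pattern graph from axioms and annotations."""
    nodes: set[str] = set()
    edges: set[tuple[str, str, str, bool]] = set()
    for ax in o.axioms:
        edge = _axiom_edge(ax)
        if edge is None:
            continue
        edges.add(edge)
        nodes.add(edge[0])
        nodes.add(edge[1])
    for a in annotations:
        edges.add((a.entity, a.cls, annotation_relation, True))
        nodes.add(a.entity)
        nodes.add(a.cls)
    return Graph(frozenset(nodes), frozenset(edges))


def generate_walks(g: Graph, params: WalkParams) -> Corpus:
    """Emit ``walks_per_node`` biased walks from every node, as a corpus.

    Second-order transition weights from previous node t at current node v:
    1/p back to t, 1 to a common neighbor of t and v, 1/q otherwise.  The
    first step is uniform.  Deterministic given the seed; isolated nodes
    yield single-node sentences.
    """
    if not g.nodes:
        return Corpus(())
    rng = np.random.default_rng(params.seed)
    adj = g.undirected_adjacency()
    nbr_sets = {n: set(v) for n, v in adj.items()}
    sentences: list[tuple[str, ...]] = []
    for start in sorted(g.nodes):
        for _ in range(params.walks_per_node):
            walk = [start]
            prev = None
            cur = start
            while len(walk) < params.walk_length:
                nbrs = adj[cur]
                if not nbrs:
                    break  # isolated start node
                if prev is None:
                    nxt = nbrs[int(rng.integers(len(nbrs)))]
                else:
                    prev_nbrs = nbr_sets[prev]
                    w = np.empty(len(nbrs))
                    for i, x in enumerate(nbrs):
                        if x == prev:
                            w[i] = 1.0 / params.p
                        elif x in prev_nbrs:
                            w[i] = 1.0
                        else:
                            w[i] = 1.0 / params.q
                    nxt = nbrs[int(rng.choice(len(nbrs), p=w / w.sum()))]
                walk.append(nxt)
                prev, cur = cur, nxt
            sentences.append(tuple(walk))
    return Corpus(tuple(sentences))
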