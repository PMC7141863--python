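"""Self-contained synthetic studies with an inter-ontology signal path.

The generator emulates the situation where two classes are distant in a
primary hierarchy but both related to the same class of an external
ontology — the "two GO processes sharing a ChEBI chemical" motif.  A random
rooted tree forms the primary hierarchy; its leaves are dealt round-robin
(over a branch-ordered list) into modules, so same-module leaves land in
different root branches and are far apart in the tree.  Each module points
at one class of a small external hierarchy through bridge axioms
``leaf SubClassOf related_to some EXT:k``, emitted with probability ρ.
Entities annotate random leaves; an unordered entity pair is positive with
probability π1 when the two annotation sets touch leaves bridged to a
common external class, and with background probability π0 otherwise.

The interaction labels depend only on module structure, which is invisible
in the primary hierarchy — removing the bridge axioms from a pipeline's
input changes nothing about the pairs, only about the background knowledge
available to the encoder.  π0 > 0 keeps the task noisy, leaving headroom to
detect the axiom effect.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path
from typing import Optional

import numpy as np

from .corpus import AnnotationAssertion, write_annotations
from .model import (
    Axiom,
    MetadataAssertion,
    Named,
    OntologySet,
    SUBCLASS,
    Some,
    write_ontology,
)

__all__ = ["SynthConfig", "SyntheticStudy", "generate_study", "plant_metadata"]

BRIDGE_RELATION = "related_to"
PRIMARY_PREFIX = "PRI"
EXTERNAL_PREFIX = "EXT"


@dataclass(frozen=True)
class SynthConfig:
    """Study-generation parameters (defaults are the standard study conditions)."""

    n_entities: int = 300
    n_primary_classes: int = 120
    n_external_classes: int = 8
    n_modules: int = 8
    annotations_per_entity: int = 3
    link_probability: float = 0.9     # ρ: leaf → its module's external class
    pi1: float = 0.35                 # positive rate for bridged pairs
    pi0: float = 0.03                 # background positive rate
    metadata_signal: str = "none"     # none | labels-share-module-words
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.pi0 <= self.pi1 <= 1.0):
            raise ValueError("need 0 <= pi0 <= pi1 <= 1")
        if not 0.0 <= self.link_probability <= 1.0:
            raise ValueError("link_probability must be in [0, 1]")
        if self.n_modules > self.n_external_classes:
            raise ValueError("n_modules must not exceed n_external_classes")
        if self.metadata_signal not in ("none", "labels-share-module-words"):
            raise ValueError(f"unknown metadata_signal: {self.metadata_signal!r}")


@dataclass
class SyntheticStudy:
    """An in-memory synthetic study; `write` emits the pipeline's file formats."""

    config: SynthConfig
    primary: OntologySet
    external: OntologySet
    bridge: OntologySet
    annotations: set[AnnotationAssertion]
    positives: set[tuple[str, str]]
    truth: dict

    def write(self, outdir: str | Path) -> dict[str, Path]:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {
            "primary": outdir / "primary.obo",
            "external": outdir / "external.obo",
            "bridge": outdir / "bridge.axioms",
            "annotations": outdir / "annotations.tsv",
            "positives": outdir / "positives.tsv",
            "truth": outdir / "truth.json",
        }
        write_ontology(self.primary, paths["primary"], format="obo")
        write_ontology(self.external, paths["external"], format="obo")
        write_ontology(self.bridge, paths["bridge"], format="axiom-lines")
        write_annotations(self.annotations, paths["annotations"])
        with open(paths["positives"], "w") as fh:
            for a, b in sorted(self.positives):
                fh.write(f"{a}\t{b}\n")
        paths["truth"].write_text(json.dumps(self.truth, indent=2, sort_keys=True))
        return paths


def _random_tree_axioms(rng: np.random.Generator, prefix: str, n: int,
                        source: str) -> tuple[OntologySet, list[int]]:
    """Random rooted tree: node i's parent is uniform over 0..i-1.  Returns
    the ontology and the parent list (parents[0] == -1)."""
    parents = [-1] + [int(rng.integers(i)) for i in range(1, n)]
    axioms = [
        Axiom(SUBCLASS, _curie(prefix, i), Named(_curie(prefix, parents[i])),
              source=source)
        for i in range(1, n)
    ]
    return OntologySet(axioms), parents


def _curie(prefix: str, i: int) -> str:
    return f"{prefix}:{i + 1:04d}"


def _branch_of(parents: list[int], node: int) -> int:
    """The child-of-root ancestor of a node (the node itself if depth 1)."""
    while parents[node] > 0:
        node = parents[node]
    return node


def generate_study(cfg: SynthConfig = SynthConfig(),
                   outdir: Optional[str | Path] = None) -> SyntheticStudy:
    """Generate a synthetic study; optionally write its files.

    Fully deterministic given ``cfg.seed``.  The truth record keeps module
    assignments, per-entity bridged-module sets and the linked/positive
    counts the statistical checks need.
    """
    rng = np.random.default_rng(cfg.seed)
    primary, parents = _random_tree_axioms(
        rng, PRIMARY_PREFIX, cfg.n_primary_classes, "primary")
    external, _ = _random_tree_axioms(
        rng, EXTERNAL_PREFIX, cfg.n_external_classes, "external")

    has_child = {p for p in parents if p >= 0}
    leaves = [i for i in range(cfg.n_primary_classes) if i not in has_child]
    if len(leaves) < cfg.n_modules:
        raise ValueError(
            f"tree has {len(leaves)} leaves, fewer than {cfg.n_modules} module slots"
        )
    if cfg.annotations_per_entity > len(leaves):
        raise ValueError("annotations_per_entity exceeds the number of leaves")

    # deal modules round-robin over the branch-ordered leaf list, so each
    # module's members scatter across root branches (distant in the tree)
    leaves_by_branch = sorted(leaves, key=lambda v: (_branch_of(parents, v), v))
    module_of = {leaf: k % cfg.n_modules for k, leaf in enumerate(leaves_by_branch)}

    bridge_axioms = []
    bridged = {}  # leaf index -> module, for leaves that actually got a bridge
    for leaf in sorted(module_of):
        if rng.random() < cfg.link_probability:
            m = module_of[leaf]
            bridged[leaf] = m
            bridge_axioms.append(
                Axiom(SUBCLASS, _curie(PRIMARY_PREFIX, leaf),
                      Some(BRIDGE_RELATION, Named(_curie(EXTERNAL_PREFIX, m))),
                      source="bridge")
            )
    bridge = OntologySet(bridge_axioms)

    entities = [f"E{i + 1:04d}" for i in range(cfg.n_entities)]
    leaf_arr = np.array(sorted(leaves))
    annotations: set[AnnotationAssertion] = set()
    masks = np.zeros(cfg.n_entities, dtype=np.uint64)
    entity_modules: dict[str, list[int]] = {}
    for i, ent in enumerate(entities):
        chosen = rng.choice(leaf_arr, size=cfg.annotations_per_entity, replace=False)
        mods = set()
        for leaf in chosen.tolist():
            annotations.add(AnnotationAssertion(ent, _curie(PRIMARY_PREFIX, leaf)))
            if leaf in bridged:
                mods.add(bridged[leaf])
        entity_modules[ent] = sorted(mods)
        for m in mods:
            masks[i] |= np.uint64(1) << np.uint64(m)

    # vectorized pair labels over the upper triangle
    ii, jj = np.triu_indices(cfg.n_entities, k=1)
    linked = (masks[ii] & masks[jj]) > 0
    prob = np.where(linked, cfg.pi1, cfg.pi0)
    positive = rng.random(len(ii)) < prob
    positives = {
        (entities[a], entities[b])
        for a, b in zip(ii[positive].tolist(), jj[positive].tolist())
    }

    truth = {
        "config": asdict(cfg),
        "leaf_modules": {_curie(PRIMARY_PREFIX, l): m for l, m in module_of.items()},
        "bridged_leaves": sorted(_curie(PRIMARY_PREFIX, l) for l in bridged),
        "module_targets": {
            str(m): _curie(EXTERNAL_PREFIX, m) for m in range(cfg.n_modules)
        },
        "entity_modules": entity_modules,
        "n_pairs": int(len(ii)),
        "n_linked_pairs": int(linked.sum()),
        "n_positive": int(positive.sum()),
        "n_positive_linked": int((positive & linked).sum()),
        "n_positive_unlinked": int((positive & ~linked).sum()),
    }
    study = SyntheticStudy(cfg, primary, external, bridge,
                           annotations, positives, truth)
    # labels are always planted; with signal='none' they are pure noise, so
    # the meta-data null comparison is labels-present-but-uninformative
    study = plant_metadata(cfg, study)
    if outdir is not None:
        study.write(outdir)
    return study


_NOISE_VOCAB = [f"noise{i:02d}" for i in range(40)]


def plant_metadata(cfg: SynthConfig, study: SyntheticStudy) -> SyntheticStudy:
    """Attach labels to every primary class; module members share a marker word.

    With ``metadata_signal='labels-share-module-words'`` each module has a
    marker word present in all of its members' labels, mixed with words from
    a common noise vocabulary; with ``'none'`` every label word is noise.
    Deterministic given the config seed (offset so labels are independent of
    the structural draws).
    """
    rng = np.random.default_rng(cfg.seed + 10_000)
    signal = cfg.metadata_signal == "labels-share-module-words"
    leaf_modules = study.truth["leaf_modules"]
    primary = study.primary.copy()
    classes = sorted(
        {c for ax in primary.axioms for c in ax.mentioned_classes()
         if c.startswith(PRIMARY_PREFIX + ":")}
    )
    marker_counts: dict[str, int] = {}
    for cls in classes:
        words = [
            _NOISE_VOCAB[int(k)] for k in rng.integers(len(_NOISE_VOCAB), size=3)
        ]
        if signal and cls in leaf_modules:
            m = leaf_modules[cls]
            pos = int(rng.integers(len(words) + 1))
            words.insert(pos, f"module{m}marker")
            marker_counts[str(m)] = marker_counts.get(str(m), 0) + 1
        primary.add_metadata(MetadataAssertion(cls, "label", " ".join(words)))
    truth = dict(study.truth)
    truth["metadata"] = {
        "signal": cfg.metadata_signal,
        "marker_label_counts": marker_counts,
        "module_sizes": {
            str(m): sum(1 for v in leaf_modules.values() if v == m)
            for m in range(cfg.n_modules)
        },
    }
    return SyntheticStudy(cfg, primary, study.external, study.bridge,
                          study.annotations, study.positives, truth)
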