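"""Ablation harness: one fixed pair dataset, varying background ontologies.

The experimental design holds the biological data fixed — the annotations,
the positive pairs, the sampled negatives and the train/test split are
byte-identical across variants — and varies only the axiom set handed to
the encoder.  Any AUC difference between variants is then attributable to
the background knowledge, not to the data.

Variants: ``base``, ``plus``, ``plus-ns:<PREFIX>`` (keep only cross-
references into one external ontology), ``plus-external`` (merge the full
external axiom sets), ``plus-metadata`` (include the meta-data corpus),
``substitute:<PREFIX>`` (swap a sub-ontology of the host for the enriched
set).
"""

from __future__ import annotations

import hashlib
from dataclasses import replace
from dataclasses import replace as dc_replace
from pathlib import Path
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .corpus import (
    AnnotationAssertion,
    Corpus,
    build_logical_corpus,
    build_metadata_corpus,
    read_annotations,
)
from .embedding import (
    EmbeddingTable,
    SkipgramParams,
    remove_top_components,
    train_embeddings,
)
from .evaluation import EvalResult, compare_models, roc_auc
from .graph import WalkParams, build_graph, generate_walks
from .inference import saturate
from .model import OntologySet, merge_or_substitute, parse_ontology, \
    restrict_to_namespace_links
from .pairs import (
    NNConfig,
    PairDataset,
    ScoreSet,
    build_pair_dataset,
    cosine_scores,
    nn_fit_and_score,
    pair_key,
    read_positive_pairs,
)

__all__ = [
    "assemble_variant",
    "encode",
    "train_ensemble",
    "score_variant",
    "evaluate_encoding",
    "run_experiment",
    "apply_id_map",
    "paired_seed_test",
    "synthetic_axiom_ablation",
    "synthetic_metadata_ablation",
]

DEFAULT_RESTARTS = 3
DEFAULT_COMMON_COMPONENTS = 6

ENCODERS = ("axiom-corpus", "axiom+metadata-corpus", "graph-walks")
SCORERS = ("cosine", "nn")


def _load_set(paths: str | Path | Sequence[str | Path]) -> OntologySet:
    if isinstance(paths, (str, Path)):
        paths = [paths]
    out = OntologySet()
    for p in paths:
        out = merge_or_substitute(out, parse_ontology(p))
    return out


def assemble_variant(
    variant: str,
    base: OntologySet,
    plus: Optional[OntologySet],
    externals: dict[str, OntologySet],
    base_prefix: str,
) -> tuple[OntologySet, bool]:
    """Resolve a variant name to its axiom set and whether meta-data is used."""
    if variant == "base":
        return base, False
    if plus is None:
        raise ValueError(f"variant {variant!r} needs an enriched ('plus') ontology")
    if variant == "plus":
        return plus, False
    if variant == "plus-metadata":
        return plus, True
    if variant == "plus-external":
        out = plus
        for ext in externals.values():
            out = merge_or_substitute(out, ext)
        return out, False
    if variant.startswith("plus-ns:"):
        prefix = variant.split(":", 1)[1]
        return restrict_to_namespace_links(plus, prefix, base_prefix), False
    if variant.startswith("substitute:"):
        prefix = variant.split(":", 1)[1]
        return merge_or_substitute(base, plus, replace_prefix=prefix), False
    raise ValueError(f"unknown variant: {variant!r}")


def encode(
    o: OntologySet,
    annotations: Iterable[AnnotationAssertion],
    encoder: str = "axiom-corpus",
    include_metadata: bool = False,
    no_inference: bool = False,
    walk_params: Optional[WalkParams] = None,
    metadata_properties: Sequence[str] = ("label", "synonym", "definition"),
) -> Corpus:
    """Saturate and encode an axiom set (plus annotations) as a corpus."""
    sat = o if no_inference else saturate(o)
    if encoder == "graph-walks":
        g = build_graph(sat, annotations)
        return generate_walks(g, walk_params or WalkParams())
    if encoder not in ("axiom-corpus", "axiom+metadata-corpus"):
        raise ValueError(f"unknown encoder: {encoder!r}")
    c = build_logical_corpus(sat, annotations)
    if encoder == "axiom+metadata-corpus" or include_metadata:
        c = c + build_metadata_corpus(sat, metadata_properties)
    return c


def _check_coverage(table: EmbeddingTable, dataset: PairDataset) -> None:
    missing = sorted(e for e in dataset.entities() if e not in table)
    if missing:
        raise ValueError(
            f"{len(missing)} dataset entities lack embeddings: "
            + ", ".join(missing[:20])
            + ("..." if len(missing) > 20 else "")
        )


def train_ensemble(
    corpus: Corpus,
    sg: Optional[SkipgramParams] = None,
    seed: int = 0,
    restarts: int = DEFAULT_RESTARTS,
    common_components: int = DEFAULT_COMMON_COMPONENTS,
) -> list[EmbeddingTable]:
    """Train ``restarts`` independently seeded skip-gram tables on one corpus.

    Skip-gram on corpora of this size has visible run-to-run variance;
    downstream scores are averaged over the restarts to stabilize the
    similarity estimates.  Each table gets the all-but-the-top treatment.
    """
    sg = sg or SkipgramParams()
    tables = []
    for r in range(restarts):
        derived = (seed * 1009 + r) % 2**31
        t = train_embeddings(corpus, replace(sg, seed=derived))
        tables.append(remove_top_components(t, common_components))
    return tables


def score_variant(
    tables: EmbeddingTable | Sequence[EmbeddingTable],
    dataset: PairDataset,
    scorer: str = "cosine",
    nn_config: Optional[NNConfig] = None,
) -> tuple[ScoreSet, EvalResult]:
    """Score the test split with one scorer and evaluate it.

    ``tables`` may be a single embedding table or an ensemble of restarts;
    with an ensemble the per-pair scores are averaged across tables.
    """
    if isinstance(tables, EmbeddingTable):
        tables = [tables]
    test = dataset.subset("test")
    pairs = [(r.entity_a, r.entity_b) for r in test]
    acc: Optional[np.ndarray] = None
    tag = scorer
    for i, table in enumerate(tables):
        _check_coverage(table, dataset)
        if scorer == "cosine":
            ss = cosine_scores(table, pairs)
        elif scorer == "nn":
            cfg = nn_config or NNConfig()
            ss = nn_fit_and_score(table, dataset, replace(cfg, seed=cfg.seed + i))
        else:
            raise ValueError(f"unknown scorer: {scorer!r}")
        s, y = ss.arrays(test)
        acc = s if acc is None else acc + s
    mean = acc / len(tables)
    merged = ScoreSet(
        {pair_key(a, b): float(v) for (a, b), v in zip(pairs, mean)}, tag)
    return merged, roc_auc(mean, y)


def evaluate_encoding(
    o: OntologySet,
    annotations: Iterable[AnnotationAssertion],
    dataset: PairDataset,
    encoder: str = "axiom-corpus",
    scorer: str = "cosine",
    seed: int = 0,
    restarts: int = DEFAULT_RESTARTS,
    common_components: int = DEFAULT_COMMON_COMPONENTS,
    sg: Optional[SkipgramParams] = None,
    include_metadata: bool = False,
    no_inference: bool = False,
    walk_params: Optional[WalkParams] = None,
    nn_config: Optional[NNConfig] = None,
) -> EvalResult:
    """One in-memory pipeline pass: saturate → encode → embed → score → AUC."""
    annotations = set(annotations)
    corpus = encode(o, annotations, encoder=encoder,
                    include_metadata=include_metadata,
                    no_inference=no_inference,
                    walk_params=walk_params)
    tables = train_ensemble(corpus, sg, seed=seed, restarts=restarts,
                            common_components=common_components)
    _, ev = score_variant(tables, dataset, scorer, nn_config)
    return ev


def paired_seed_test(deltas: Sequence[float],
                     alternative: str = "greater") -> float:
    """One-sided paired t-test p-value that the per-seed deltas exceed zero."""
    d = np.asarray(deltas, dtype=float)
    if d.size < 2:
        raise ValueError("need at least two seeds for a paired test")
    if np.allclose(d, d[0]):
        # degenerate: all deltas identical (e.g. a variant compared to itself)
        return 1.0 if d[0] <= 0 else 0.0
    return float(stats.ttest_rel(d, np.zeros_like(d), alternative=alternative).pvalue)


def apply_id_map(pairs: Iterable[tuple[str, str]],
                 map_path: str | Path) -> tuple[set[tuple[str, str]], int]:
    """Translate pair endpoints through a many-to-many 2-column ID map.

    Each endpoint expands to all of its mapped IDs (cartesian product);
    pairs with an unmapped endpoint are dropped and counted.
    """
    mapping: dict[str, list[str]] = {}
    with open(map_path) as fh:
        for lineno, line in enumerate(fh, start=1):
            cols = line.split()
            if not cols or cols[0].startswith("#"):
                continue
            if len(cols) < 2:
                raise ValueError(f"{map_path}:{lineno}: expected two columns")
            mapping.setdefault(cols[0], []).append(cols[1])
    out: set[tuple[str, str]] = set()
    dropped = 0
    for a, b in pairs:
        if a not in mapping or b not in mapping:
            dropped += 1
            continue
        for ma in mapping[a]:
            for mb in mapping[b]:
                if ma != mb:
                    out.add(pair_key(ma, mb))
    return out, dropped


def run_experiment(config: dict) -> pd.DataFrame:
    """Run the full ablation grid described by a flat config mapping.

    Required keys: ``base`` (path or list), ``annotations``, ``positives``,
    ``variants`` (list).  Optional: ``plus``, ``external`` (prefix → path
    mapping), ``base_prefix``, ``annotation_dialect``, ``excluded_evidence``,
    ``encoder``, ``scorers``, ``seeds``, ``negative_ratio``,
    ``split_fraction``, ``no_inference``, ``embedding`` /, ``walks`` /
    ``nn`` parameter overrides, ``id_map``, ``outdir``.

    Returns one row per (variant, scorer) with the seed-averaged AUC and the
    comparison against ``base``.  The pair dataset for a given seed is built
    once and shared by every variant.
    """
    base = _load_set(config["base"])
    plus = _load_set(config["plus"]) if config.get("plus") else None
    externals = {
        prefix: _load_set(path)
        for prefix, path in (config.get("external") or {}).items()
    }
    base_prefix = config.get("base_prefix", "")

    annotations = read_annotations(
        config["annotations"],
        dialect=config.get("annotation_dialect", "tsv"),
        excluded_evidence=config.get("excluded_evidence", ()),
    )
    universe = sorted({a.entity for a in annotations})
    positives = read_positive_pairs(config["positives"])
    if config.get("id_map"):
        positives, n_dropped = apply_id_map(positives, config["id_map"])
    else:
        n_dropped = 0
    in_universe = {p for p in positives if p[0] in set(universe) and p[1] in set(universe)}
    n_unannotated = len(positives) - len(in_universe)

    encoder = config.get("encoder", "axiom-corpus")
    scorers = config.get("scorers", ["cosine"])
    if isinstance(scorers, str):
        scorers = [scorers]
    seeds = config.get("seeds", [0])
    variants = config["variants"]
    no_inference = bool(config.get("no_inference", False))
    sg = SkipgramParams(**config.get("embedding", {}))
    wp = WalkParams(**config.get("walks", {}))
    nn_cfg = NNConfig(**config.get("nn", {}))

    # per-seed shared datasets; identity across variants asserted by hash
    datasets: dict[int, PairDataset] = {}
    dataset_hashes: dict[int, str] = {}
    for seed in seeds:
        d = build_pair_dataset(
            in_universe, universe,
            negative_ratio=config.get("negative_ratio", 1.0),
            split_fraction=config.get("split_fraction", 0.7),
            seed=seed,
        )
        datasets[seed] = d
        blob = "\n".join(
            f"{r.entity_a}\t{r.entity_b}\t{r.label}\t{r.split}" for r in d.records
        )
        dataset_hashes[seed] = hashlib.sha256(blob.encode()).hexdigest()

    aucs: dict[tuple[int, str], list[float]] = {}
    last_scores: dict[tuple[int, str], ScoreSet] = {}
    counts: dict[tuple[int, str], tuple[int, int]] = {}
    restarts = int(config.get("embedding_restarts", DEFAULT_RESTARTS))
    common = int(config.get("common_components", DEFAULT_COMMON_COMPONENTS))
    for vi, variant in enumerate(variants):
        o, use_meta = assemble_variant(variant, base, plus, externals, base_prefix)
        for seed in seeds:
            corpus = encode(
                o, annotations, encoder=encoder, include_metadata=use_meta,
                no_inference=no_inference,
                walk_params=replace(wp, seed=seed),
            )
            tables = train_ensemble(corpus, sg, seed=seed, restarts=restarts,
                                    common_components=common)
            for scorer in scorers:
                ss, ev = score_variant(
                    tables, datasets[seed], scorer,
                    replace(nn_cfg, seed=seed),
                )
                aucs.setdefault((vi, scorer), []).append(ev.auc)
                last_scores[(vi, scorer)] = ss
                counts[(vi, scorer)] = (ev.n_pos, ev.n_neg)

    base_idx = variants.index("base") if "base" in variants else None
    rows = []
    for (vi, scorer), vals in aucs.items():
        variant = variants[vi]
        base_vals = aucs.get((base_idx, scorer)) if base_idx is not None else None
        delta = p = None
        if base_vals is not None:
            delta = float(np.mean(vals) - np.mean(base_vals))
            if vi == base_idx:
                p = 1.0
            elif len(seeds) > 1:
                p = paired_seed_test(np.asarray(vals) - np.asarray(base_vals))
            else:
                test = datasets[seeds[0]].subset("test")
                sa, y = last_scores[(vi, scorer)].arrays(test)
                sb, _ = last_scores[(base_idx, scorer)].arrays(test)
                if np.array_equal(sa, sb):
                    p = 1.0
                else:
                    p = compare_models(sa, sb, y, method="paired-bootstrap",
                                       seed=seeds[0]).p_value
        n_pos, n_neg = counts[(vi, scorer)]
        rows.append({
            "variant": variant, "scorer": scorer,
            "auc": float(np.mean(vals)), "auc_sd": float(np.std(vals)),
            "n_seeds": len(vals), "n_pos": n_pos, "n_neg": n_neg,
            "delta_vs_base": delta, "p_vs_base": p,
        })
    report = pd.DataFrame(rows)
    report.attrs["dataset_sha256"] = dataset_hashes
    report.attrs["n_positives_dropped_by_id_map"] = n_dropped
    report.attrs["n_positives_unannotated"] = n_unannotated

    if config.get("outdir"):
        outdir = Path(config["outdir"])
        outdir.mkdir(parents=True, exist_ok=True)
        report.to_csv(outdir / "report.tsv", sep="\t", index=False)
    return report


# ---------------------------------------------------------------------------
# Headline synthetic experiments


def _study_dataset(study, seed: int) -> PairDataset:
    universe = sorted({a.entity for a in study.annotations})
    return build_pair_dataset(study.positives, universe, seed=seed)


def synthetic_axiom_ablation(
    seeds: Sequence[int],
    base_config=None,
    scorer: str = "cosine",
    encoder: str = "axiom-corpus",
    restarts: int = DEFAULT_RESTARTS,
    sg: Optional[SkipgramParams] = None,
) -> pd.DataFrame:
    """Per-seed AUC with and without the inter-ontology bridge axioms.

    For each seed a fresh synthetic study is generated; the pair dataset is
    shared between the two arms, so the only difference is whether the
    bridge axioms are part of the encoder's background knowledge.  Returns
    one row per seed with ``auc_base``, ``auc_plus`` and ``delta``.
    """
    from .synth import SynthConfig, generate_study

    base_config = base_config or SynthConfig()
    rows = []
    for seed in seeds:
        study = generate_study(dc_replace(base_config, seed=seed))
        dataset = _study_dataset(study, seed)
        plus = merge_or_substitute(study.primary, study.bridge)
        ev_base = evaluate_encoding(study.primary, study.annotations, dataset,
                                    encoder=encoder, scorer=scorer, seed=seed,
                                    restarts=restarts, sg=sg)
        ev_plus = evaluate_encoding(plus, study.annotations, dataset,
                                    encoder=encoder, scorer=scorer, seed=seed,
                                    restarts=restarts, sg=sg)
        rows.append({"seed": seed, "auc_base": ev_base.auc,
                     "auc_plus": ev_plus.auc,
                     "delta": ev_plus.auc - ev_base.auc})
    return pd.DataFrame(rows)


def synthetic_metadata_ablation(
    seeds: Sequence[int],
    signal: str | Sequence[str] = "labels-share-module-words",
    base_config=None,
    scorer: str = "cosine",
    restarts: int = DEFAULT_RESTARTS,
    sg: Optional[SkipgramParams] = None,
) -> pd.DataFrame:
    """Per-seed AUC of the meta-data-augmented corpus vs the logical corpus.

    Bridge axioms are withheld in both arms, so any difference is carried by
    the class labels alone; ``signal='none'`` is the null (noise labels).
    ``signal`` may be a list; the structural study for a given seed is
    identical across signal settings (labels never enter the logical
    corpus), so the axiom-only arm is computed once per seed and shared.
    """
    from .synth import SynthConfig, generate_study

    signals = [signal] if isinstance(signal, str) else list(signal)
    base_config = base_config or SynthConfig()
    rows = []
    for seed in seeds:
        ev_ax = None
        for sig in signals:
            cfg = dc_replace(base_config, seed=seed, metadata_signal=sig)
            study = generate_study(cfg)
            dataset = _study_dataset(study, seed)
            if ev_ax is None:
                ev_ax = evaluate_encoding(study.primary, study.annotations,
                                          dataset, encoder="axiom-corpus",
                                          scorer=scorer, seed=seed,
                                          restarts=restarts, sg=sg)
            ev_meta = evaluate_encoding(study.primary, study.annotations,
                                        dataset,
                                        encoder="axiom+metadata-corpus",
                                        scorer=scorer, seed=seed,
                                        restarts=restarts, sg=sg)
            rows.append({"seed": seed, "signal": sig,
                         "auc_axioms": ev_ax.auc,
                         "auc_metadata": ev_meta.auc,
                         "delta": ev_meta.auc - ev_ax.auc})
    return pd.DataFrame(rows)
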