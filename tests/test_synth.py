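"""Synthetic study generator: structure, statistics and file round-trips."""

import itertools
import json

import networkx as nx
import numpy as np
import pytest
from scipy import stats

from ontoembed.corpus import read_annotations
from ontoembed.model import Named, SUBCLASS, parse_ontology
from ontoembed.pairs import read_positive_pairs
from ontoembed.synth import SynthConfig, generate_study, plant_metadata


SMALL = SynthConfig(n_entities=60, n_primary_classes=60, n_external_classes=6,
                    n_modules=6, seed=0)


def undirected_hierarchy(study):
    g = nx.Graph()
    for ax in study.primary.axioms:
        if ax.kind == SUBCLASS and isinstance(ax.object, Named):
            g.add_edge(ax.subject, ax.object.curie)
    return g


class TestGenerateStudy:
    def test_deterministic_given_seed(self):
        s1 = generate_study(SMALL)
        s2 = generate_study(SMALL)
        assert s1.primary == s2.primary
        assert s1.positives == s2.positives
        assert s1.truth == s2.truth

    def test_positive_count_matches_closed_form(self):
        """Positives ≈ π1·L + π0·(T−L) within 3 binomial σ, per seed."""
        for seed in range(5):
            study = generate_study(SynthConfig(seed=seed))
            t = study.truth
            L, T = t["n_linked_pairs"], t["n_pairs"]
            cfg = study.config
            mean = cfg.pi1 * L + cfg.pi0 * (T - L)
            var = (cfg.pi1 * (1 - cfg.pi1) * L + cfg.pi0 * (1 - cfg.pi0) * (T - L))
            assert abs(len(study.positives) - mean) < 3 * np.sqrt(var)

    def test_null_construction_rates_indistinguishable(self):
        """With π1 = π0 the linked/unlinked positive rates match (χ²)."""
        pvals = []
        for seed in range(5):
            cfg = SynthConfig(pi1=0.1, pi0=0.1, seed=seed)
            t = generate_study(cfg).truth
            table = np.array([
                [t["n_positive_linked"],
                 t["n_linked_pairs"] - t["n_positive_linked"]],
                [t["n_positive_unlinked"],
                 (t["n_pairs"] - t["n_linked_pairs"]) - t["n_positive_unlinked"]],
            ])
            pvals.append(stats.chi2_contingency(table).pvalue)
        assert max(pvals) > 0.01

    def test_same_module_leaves_scattered_in_hierarchy(self):
        """Same-module leaves sit farther apart than sibling leaves on average."""
        study = generate_study(SynthConfig(seed=3))
        g = undirected_hierarchy(study)
        lm = study.truth["leaf_modules"]
        by_module = {}
        for leaf, m in lm.items():
            by_module.setdefault(m, []).append(leaf)
        dists = dict(nx.all_pairs_shortest_path_length(g))
        same_module = [
            dists[a][b]
            for mems in by_module.values()
            for a, b in itertools.combinations(sorted(mems), 2)
        ]
        # sibling leaves (sharing a parent) are at distance 2 by definition
        assert np.mean(same_module) > 2.0

    def test_signal_lives_only_in_bridge(self):
        """Positives are a function of truth alone, not of bridge file use."""
        cfg = SynthConfig(seed=5)
        with_bridge = generate_study(cfg)
        # regenerating is deterministic; the bridge axioms never feed the labels:
        # every positive pair is justified by entity module overlap in truth
        em = with_bridge.truth["entity_modules"]
        n_linked_pos = sum(
            1 for a, b in with_bridge.positives if set(em[a]) & set(em[b]))
        assert n_linked_pos == with_bridge.truth["n_positive_linked"]

    def test_infeasible_sizes_error(self):
        with pytest.raises(ValueError, match="module"):
            generate_study(SynthConfig(n_primary_classes=6, n_modules=6,
                                       n_external_classes=6, seed=1))
        with pytest.raises(ValueError):
            SynthConfig(pi1=0.1, pi0=0.5)
        with pytest.raises(ValueError):
            SynthConfig(n_modules=9, n_external_classes=8)

    def test_written_files_reload_consistently(self, tmp_path):
        study = generate_study(SMALL, outdir=tmp_path)
        primary = parse_ontology(tmp_path / "primary.obo")
        assert primary.axioms == study.primary.axioms
        bridge = parse_ontology(tmp_path / "bridge.axioms")
        assert bridge.axioms == study.bridge.axioms
        anns = read_annotations(tmp_path / "annotations.tsv")
        assert {(a.entity, a.cls) for a in anns} == \
            {(a.entity, a.cls) for a in study.annotations}
        assert read_positive_pairs(tmp_path / "positives.tsv") == study.positives
        truth = json.loads((tmp_path / "truth.json").read_text())
        assert truth["n_pairs"] == study.truth["n_pairs"]


class TestPlantMetadata:
    def test_null_labels_have_no_module_words(self):
        cfg = SynthConfig(metadata_signal="none", seed=2,
                          n_entities=60, n_primary_classes=60,
                          n_external_classes=6, n_modules=6)
        study = plant_metadata(cfg, generate_study(cfg))
        words = {w for m in study.primary.metadata for w in m.text.split()}
        assert all(not w.startswith("module") for w in words)

    def test_marker_word_covers_module_members(self):
        cfg = SynthConfig(metadata_signal="labels-share-module-words", seed=2,
                          n_entities=60, n_primary_classes=60,
                          n_external_classes=6, n_modules=6)
        study = generate_study(cfg)
        meta = study.truth["metadata"]
        for m, size in meta["module_sizes"].items():
            covered = meta["marker_label_counts"].get(m, 0)
            assert covered >= 0.8 * size
        # and the marker genuinely appears in the labels
        labels = {x.subject: x.text for x in study.primary.metadata}
        lm = study.truth["leaf_modules"]
        hits = sum(1 for leaf, m in lm.items()
                   if f"module{m}marker" in labels[leaf])
        assert hits >= 0.8 * len(lm)

    def test_labels_roundtrip_through_obo(self, tmp_path):
        cfg = SynthConfig(metadata_signal="labels-share-module-words", seed=4,
                          n_entities=60, n_primary_classes=60,
                          n_external_classes=6, n_modules=6)
        study = generate_study(cfg, outdir=tmp_path)
        reread = parse_ontology(tmp_path / "primary.obo")
        assert reread.metadata == study.primary.metadata
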