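"""Pair dataset construction, cosine scoring and the feed-forward scorer."""

import numpy as np
import pytest

from ontoembed.embedding import EmbeddingTable
from ontoembed.evaluation import roc_auc
from ontoembed.pairs import (
    NNConfig,
    PairRecord,
    build_pair_dataset,
    cosine_scores,
    nn_fit_and_score,
    pair_key,
    read_positive_pairs,
)


def cluster_table(rng, n_clusters=8, n_per_cluster=12, dim=10, spread=0.5,
                  separation=6.0):
    """Well-separated Gaussian clusters of entity vectors.

    Several clusters (not two) so that pair inputs do not collapse into a
    handful of degenerate groups — the permuted-label canary needs scores
    that vary within the same-cluster/cross-cluster strata.
    """
    centers = rng.normal(0, 1, (n_clusters, dim))
    centers /= np.linalg.norm(centers, axis=1, keepdims=True)
    centers *= separation
    vecs, membership = {}, {}
    for c in range(n_clusters):
        for i in range(n_per_cluster):
            name = f"c{c}e{i}"
            vecs[name] = centers[c] + rng.normal(0, spread, dim)
            membership[name] = c
    return EmbeddingTable(dim, vecs), membership


def separable_dataset(rng, table, membership, n_pairs=400, split=0.7, seed=0):
    """Positives = same-cluster pairs, negatives = cross-cluster pairs."""
    ents = sorted(membership)
    positives, negatives = set(), set()
    while len(positives) < n_pairs // 2 or len(negatives) < n_pairs // 2:
        a, b = rng.choice(ents, 2, replace=False)
        if membership[a] == membership[b] and len(positives) < n_pairs // 2:
            positives.add(pair_key(a, b))
        elif membership[a] != membership[b] and len(negatives) < n_pairs // 2:
            negatives.add(pair_key(a, b))

    split_rng = np.random.default_rng(seed)
    records = []
    for label, group in ((1, sorted(positives)), (0, sorted(negatives))):
        order = split_rng.permutation(len(group))
        n_train = int(round(split * len(group)))
        for rank, k in enumerate(order):
            a, b = group[k]
            records.append(PairRecord(a, b, label,
                                      "train" if rank < n_train else "test"))
    from ontoembed.pairs import PairDataset
    return PairDataset(tuple(records), split, seed)


class TestBuildPairDataset:
    def test_seventy_thirty_arithmetic(self):
        ents = [f"e{i}" for i in range(30)]
        positives = {pair_key(ents[i], ents[i + 1]) for i in range(0, 20, 2)}
        d = build_pair_dataset(positives, ents, negative_ratio=1.0,
                               split_fraction=0.7, seed=0)
        assert len(d.records) == 20
        train = d.subset("train")
        test = d.subset("test")
        assert len(train) == 14 and len(test) == 6
        assert sum(r.label for r in train) == 7

    def test_zero_ratio_gives_positives_only(self):
        ents = ["a", "b", "c", "d"]
        d = build_pair_dataset({("a", "b")}, ents, negative_ratio=0.0, seed=1)
        assert all(r.label == 1 for r in d.records)

    def test_negatives_never_overlap_positives(self):
        rng = np.random.default_rng(12)
        for trial in range(20):
            n = int(rng.integers(6, 25))
            ents = [f"e{i}" for i in range(n)]
            n_pos = int(rng.integers(1, n))
            positives = set()
            while len(positives) < n_pos:
                a, b = rng.choice(ents, 2, replace=False)
                positives.add(pair_key(a, b))
            d = build_pair_dataset(positives, ents, negative_ratio=2.0, seed=trial)
            negs = {pair_key(r.entity_a, r.entity_b)
                    for r in d.records if r.label == 0}
            assert negs.isdisjoint(positives)
            assert all(a != b for a, b in negs)
            # no duplicate unordered pairs
            all_pairs = [pair_key(r.entity_a, r.entity_b) for r in d.records]
            assert len(all_pairs) == len(set(all_pairs))

    def test_cap_with_warning_when_universe_small(self):
        ents = ["a", "b", "c"]
        positives = {("a", "b"), ("a", "c")}
        with pytest.warns(UserWarning, match="capping"):
            d = build_pair_dataset(positives, ents, negative_ratio=3.0, seed=0)
        assert sum(r.label == 0 for r in d.records) == 1  # only (b,c) left

    def test_deterministic_given_seed(self):
        ents = [f"e{i}" for i in range(15)]
        positives = {pair_key("e0", "e1"), pair_key("e2", "e3")}
        d1 = build_pair_dataset(positives, ents, seed=9)
        d2 = build_pair_dataset(positives, ents, seed=9)
        assert d1.records == d2.records

    def test_entity_disjoint_split_mode(self):
        rng = np.random.default_rng(4)
        ents = [f"e{i}" for i in range(30)]
        positives = set()
        while len(positives) < 40:
            a, b = rng.choice(ents, 2, replace=False)
            positives.add(pair_key(a, b))
        d = build_pair_dataset(positives, ents, negative_ratio=1.0, seed=2,
                               split_mode="entity-disjoint")
        train_ents = {e for r in d.subset("train")
                      for e in (r.entity_a, r.entity_b)}
        test_ents = {e for r in d.subset("test")
                     for e in (r.entity_a, r.entity_b)}
        assert train_ents.isdisjoint(test_ents)

    def test_roundtrip_tsv(self, tmp_path):
        d = build_pair_dataset({("a", "b")}, ["a", "b", "c"], seed=0)
        p = tmp_path / "pairs.tsv"
        d.save(p)
        from ontoembed.pairs import PairDataset
        assert PairDataset.load(p).records == d.records


class TestCosineScores:
    def test_identical_and_orthogonal(self):
        t = EmbeddingTable(2, {"a": np.array([1.0, 0.0]),
                               "b": np.array([1.0, 0.0]),
                               "c": np.array([0.0, 2.0])})
        s = cosine_scores(t, [("a", "b"), ("a", "c")])
        assert s[("a", "b")] == pytest.approx(1.0)
        assert s[("a", "c")] == pytest.approx(0.0)

    def test_symmetry_and_arithmetic_oracle(self):
        rng = np.random.default_rng(3)
        t = EmbeddingTable(8, {f"e{i}": rng.normal(size=8) for i in range(20)})
        pairs = [tuple(rng.choice([f"e{i}" for i in range(20)], 2, replace=False))
                 for _ in range(100)]
        s = cosine_scores(t, pairs)
        for a, b in pairs:
            va, vb = t[a], t[b]
            direct = va @ vb / (np.linalg.norm(va) * np.linalg.norm(vb))
            assert s[(a, b)] == pytest.approx(direct, abs=1e-12)
            assert s[(a, b)] == s[(b, a)]

    def test_missing_token_and_zero_vector(self):
        t = EmbeddingTable(2, {"a": np.array([1.0, 0.0]),
                               "z": np.zeros(2)})
        with pytest.raises(KeyError, match="ghost"):
            cosine_scores(t, [("a", "ghost")])
        with pytest.raises(ValueError, match="zero vector"):
            cosine_scores(t, [("a", "z")])


class TestNNScorer:
    def test_scores_in_unit_interval_and_architecture(self):
        rng = np.random.default_rng(0)
        table, membership = cluster_table(rng)
        d = separable_dataset(rng, table, membership, seed=0)
        ss = nn_fit_and_score(table, d, NNConfig(epochs=5, seed=0))
        vals = np.array(list(ss.scores.values()))
        assert np.all(vals >= 0) and np.all(vals <= 1)
        assert ss.model_info["hidden_layer_sizes"] == [800, 200]

    def test_separable_benchmark_high_auc(self):
        aucs = []
        for seed in range(3):
            rng = np.random.default_rng(200 + seed)
            table, membership = cluster_table(rng)
            d = separable_dataset(rng, table, membership, seed=seed)
            ss = nn_fit_and_score(table, d, NNConfig(seed=seed))
            s, y = ss.arrays(d.subset("test"))
            aucs.append(roc_auc(s, y).auc)
        assert np.mean(aucs) >= 0.95, aucs

    def test_order_symmetry_of_scores(self):
        rng = np.random.default_rng(1)
        table, membership = cluster_table(rng, n_per_cluster=10)
        d = separable_dataset(rng, table, membership, n_pairs=60, seed=1)
        ss = nn_fit_and_score(table, d, NNConfig(epochs=5, seed=1))
        for r in d.subset("test"):
            assert ss[(r.entity_a, r.entity_b)] == ss[(r.entity_b, r.entity_a)]

    def test_single_class_train_split_errors(self):
        rng = np.random.default_rng(2)
        table, _ = cluster_table(rng, n_clusters=2, n_per_cluster=3)
        recs = tuple(
            [PairRecord("c0e0", "c0e1", 1, "train"),
             PairRecord("c0e0", "c0e2", 1, "train"),
             PairRecord("c1e0", "c1e1", 1, "test"),
             PairRecord("c1e0", "c1e2", 0, "test")]
        )
        from ontoembed.pairs import PairDataset
        d = PairDataset(recs, 0.5, 0)
        with pytest.raises(ValueError, match="single class"):
            nn_fit_and_score(table, d, NNConfig(epochs=2, seed=0))

    def test_label_permutation_canary(self):
        """Shuffling train labels destroys test performance (no leakage)."""
        rng = np.random.default_rng(7)
        table, membership = cluster_table(rng)
        d = separable_dataset(rng, table, membership, seed=7)
        perm = np.random.default_rng(0).permutation(
            [r.label for r in d.records if r.split == "train"])
        from ontoembed.pairs import PairDataset
        shuffled = []
        k = 0
        for r in d.records:
            if r.split == "train":
                shuffled.append(PairRecord(r.entity_a, r.entity_b,
                                           int(perm[k]), "train"))
                k += 1
            else:
                shuffled.append(r)
        d2 = PairDataset(tuple(shuffled), d.split_fraction, d.seed)
        ss = nn_fit_and_score(table, d2, NNConfig(epochs=10, seed=3))
        s, y = ss.arrays(d2.subset("test"))
        assert abs(roc_auc(s, y).auc - 0.5) < 0.15


def test_read_positive_pairs(tmp_path):
    p = tmp_path / "pos.tsv"
    p.write_text("# comment\nP1\tP2\nP2\tP1\nP3\tP3\nP4\tP5\n")
    pairs = read_positive_pairs(p)
    assert pairs == {("P1", "P2"), ("P4", "P5")}  # dedup, self-pair dropped
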