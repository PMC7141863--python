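"""Labeled entity-pair datasets and pair scoring.

Positive pairs come from an interaction list; negatives are sampled
uniformly from non-positive, non-self unordered pairs.  The dataset is
split 70/30 (by default) at the pair level, stratified by label.  Two
scorers exist: cosine similarity of the entity vectors, and a feed-forward
network on the concatenated vectors (two hidden layers, 800 and 200 units,
sigmoid output trained with binary cross-entropy).  Pairs are unordered, so
the network trains on both orderings and averages the two order scores at
inference.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence

import numpy as np
from sklearn.exceptions import ConvergenceWarning
from sklearn.neural_network import MLPClassifier

from .embedding import EmbeddingTable

__all__ = [
    "PairRecord",
    "PairDataset",
    "NNConfig",
    "ScoreSet",
    "build_pair_dataset",
    "cosine_scores",
    "nn_fit_and_score",
    "read_positive_pairs",
]


def pair_key(a: str, b: str) -> tuple[str, str]:
    """Canonical (sorted) form of an unordered pair."""
    return (a, b) if a <= b else (b, a)


@dataclass(frozen=True)
class PairRecord:
    entity_a: str
    entity_b: str
    label: int
    split: str  # train | test


@dataclass(frozen=True)
class PairDataset:
    records: tuple[PairRecord, ...]
    split_fraction: float
    seed: int

    def subset(self, split: str) -> tuple[PairRecord, ...]:
        return tuple(r for r in self.records if r.split == split)

    def entities(self) -> set[str]:
        return {r.entity_a for r in self.records} | {r.entity_b for r in self.records}

    def save(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for r in self.records:
                fh.write(f"{r.entity_a}\t{r.entity_b}\t{r.label}\t{r.split}\n")

    @classmethod
    def load(cls, path: str | Path, split_fraction: float = 0.7,
             seed: int = 0) -> "PairDataset":
        records = []
        with open(path) as fh:
            for line in fh:
                a, b, label, split = line.split()
                records.append(PairRecord(a, b, int(label), split))
        return cls(tuple(records), split_fraction, seed)


@dataclass(frozen=True)
class NNConfig:
    """Feed-forward pair-scorer configuration: two hidden layers, 800 and 200 units."""

    hidden_sizes: tuple[int, ...] = (800, 200)
    activation: str = "relu"
    learning_rate: float = 1e-3
    batch_size: int = 64
    epochs: int = 20
    seed: int = 0

    def __post_init__(self) -> None:
        if any(h < 1 for h in self.hidden_sizes):
            raise ValueError("hidden sizes must be positive")


@dataclass(frozen=True)
class ScoreSet:
    """Pair → score map with the scorer tag (``cosine`` in [-1,1], ``nn`` in [0,1])."""

    scores: dict[tuple[str, str], float]
    scorer: str
    model_info: dict = field(default_factory=dict)

    def __getitem__(self, pair: Sequence[str]) -> float:
        return self.scores[pair_key(pair[0], pair[1])]

    def __len__(self) -> int:
        return len(self.scores)

    def arrays(self, records: Iterable[PairRecord]) -> tuple[np.ndarray, np.ndarray]:
        """Aligned (scores, labels) arrays for a record sequence."""
        recs = list(records)
        s = np.array([self[(r.entity_a, r.entity_b)] for r in recs])
        y = np.array([r.label for r in recs])
        return s, y


def read_positive_pairs(path: str | Path) -> set[tuple[str, str]]:
    """Two-column TSV of interacting entity pairs (STRING-style export)."""
    out: set[tuple[str, str]] = set()
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            cols = line.split()
            if not cols or cols[0].startswith("#"):
                continue
            if len(cols) < 2:
                raise ValueError(f"{path}:{lineno}: expected two columns")
            if cols[0] != cols[1]:
                out.add(pair_key(cols[0], cols[1]))
    return out


def build_pair_dataset(
    positives: Iterable[tuple[str, str]],
    universe: Iterable[str],
    negative_ratio: float = 1.0,
    split_fraction: float = 0.7,
    seed: int = 0,
    split_mode: str = "pair",
) -> PairDataset:
    """Sample negatives and split train/test, stratified by label.

    Negatives are drawn uniformly without replacement from the non-positive,
    non-self unordered pairs over the universe; their count is
    ``round(negative_ratio * n_positives)``, capped (with a warning) at the
    number of available pairs.  Deterministic given the seed.

    ``split_mode='pair'`` splits at the pair level, so an entity may appear
    on both sides; ``'entity-disjoint'`` assigns entities to train/test and
    keeps only pairs internal to one side (stricter, discards cross pairs).
    """
    if not 0 < split_fraction < 1:
        raise ValueError("split_fraction must be in (0, 1)")
    if split_mode not in ("pair", "entity-disjoint"):
        raise ValueError(f"unknown split_mode: {split_mode!r}")
    ents = sorted(set(universe))
    pos = {pair_key(a, b) for a, b in positives}
    for a, b in pos:
        if a not in ents or b not in ents:
            raise ValueError(f"positive pair ({a}, {b}) outside the universe")

    rng = np.random.default_rng(seed)
    n = len(ents)
    total_pairs = n * (n - 1) // 2
    n_wanted = int(round(negative_ratio * len(pos)))
    n_avail = total_pairs - len(pos)
    if n_wanted > n_avail:
        warnings.warn(
            f"universe supplies only {n_avail} negative pairs "
            f"(requested {n_wanted}); capping"
        )
        n_wanted = n_avail

    negatives: list[tuple[str, str]] = []
    if n_wanted > 0:
        # enumerate the upper triangle; order is deterministic
        ii, jj = np.triu_indices(n, k=1)
        mask = np.ones(len(ii), dtype=bool)
        idx_of = {e: i for i, e in enumerate(ents)}
        for a, b in pos:
            i, j = idx_of[a], idx_of[b]
            if i > j:
                i, j = j, i
            # position of (i, j) in triu order
            k = i * (2 * n - i - 1) // 2 + (j - i - 1)
            mask[k] = False
        candidates = np.flatnonzero(mask)
        chosen = rng.choice(candidates, size=n_wanted, replace=False)
        negatives = [(ents[ii[k]], ents[jj[k]]) for k in sorted(chosen)]

    if split_mode == "entity-disjoint":
        order = rng.permutation(n)
        n_train_ents = int(round(split_fraction * n))
        side = {ents[k]: ("train" if rank < n_train_ents else "test")
                for rank, k in enumerate(order)}

        def split_group(pairs, label):
            recs = []
            for a, b in pairs:
                if side[a] == side[b]:  # cross-side pairs are discarded
                    recs.append(PairRecord(a, b, label, side[a]))
            return recs
    else:
        def split_group(pairs, label):
            order = rng.permutation(len(pairs))
            n_train = int(round(split_fraction * len(pairs)))
            recs = []
            for rank, k in enumerate(order):
                a, b = pairs[k]
                recs.append(
                    PairRecord(a, b, label, "train" if rank < n_train else "test"))
            return recs

    records = split_group(sorted(pos), 1) + split_group(negatives, 0)
    return PairDataset(tuple(records), split_fraction, seed)


# ---------------------------------------------------------------------------
# Scoring


def cosine_scores(t: EmbeddingTable, pairs: Iterable[Sequence[str]]) -> ScoreSet:
    """Cosine similarity per pair; symmetric in pair order.

    Missing tokens raise KeyError naming the token; zero vectors are an error.
    """
    scores: dict[tuple[str, str], float] = {}
    for a, b in pairs:
        va, vb = t[a], t[b]
        na, nb = np.linalg.norm(va), np.linalg.norm(vb)
        if na == 0.0:
            raise ValueError(f"zero vector for token {a!r}")
        if nb == 0.0:
            raise ValueError(f"zero vector for token {b!r}")
        scores[pair_key(a, b)] = float(np.dot(va, vb) / (na * nb))
    return ScoreSet(scores, "cosine")


def _pair_matrix(t: EmbeddingTable, recs: Sequence[PairRecord],
                 order: str) -> np.ndarray:
    if order == "ab":
        return np.array([np.concatenate([t[r.entity_a], t[r.entity_b]]) for r in recs])
    return np.array([np.concatenate([t[r.entity_b], t[r.entity_a]]) for r in recs])


def nn_fit_and_score(t: EmbeddingTable, d: PairDataset,
                     cfg: NNConfig = NNConfig()) -> ScoreSet:
    """Fit the feed-forward scorer on the train split; score the test split.

    Input is the concatenation of the two entity vectors; each training pair
    is presented in both orders; test scores average the two orders, making
    the score exactly symmetric.  Only train records are used for fitting.
    """
    train = d.subset("train")
    test = d.subset("test")
    if not train or not test:
        raise ValueError("dataset needs non-empty train and test splits")
    y = np.array([r.label for r in train])
    if len(np.unique(y)) < 2:
        raise ValueError("train split contains a single class")

    x = np.vstack([_pair_matrix(t, train, "ab"), _pair_matrix(t, train, "ba")])
    yy = np.concatenate([y, y])

    clf = MLPClassifier(
        hidden_layer_sizes=cfg.hidden_sizes,
        activation=cfg.activation,
        solver="adam",
        learning_rate_init=cfg.learning_rate,
        batch_size=cfg.batch_size,
        max_iter=cfg.epochs,
        random_state=cfg.seed,
        shuffle=True,
    )
    with warnings.catch_warnings():
        # the epoch budget is fixed by design; sklearn warns when it is hit
        warnings.simplefilter("ignore", ConvergenceWarning)
        clf.fit(x, yy)

    pos_col = int(np.flatnonzero(clf.classes_ == 1)[0])
    p_ab = clf.predict_proba(_pair_matrix(t, test, "ab"))[:, pos_col]
    p_ba = clf.predict_proba(_pair_matrix(t, test, "ba"))[:, pos_col]
    p = (p_ab + p_ba) / 2.0
    scores = {
        pair_key(r.entity_a, r.entity_b): float(s) for r, s in zip(test, p)
    }
    info = {
        "hidden_layer_sizes": [w.shape[1] for w in clf.coefs_[:-1]],
        "activation": cfg.activation,
        "n_train": len(train),
    }
    return ScoreSet(scores, "nn", info)
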