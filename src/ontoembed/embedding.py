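"""Skip-gram embeddings with negative sampling, trained on token corpora.

A compact single-threaded trainer: symmetric fixed context window,
unigram^0.75 negative-sampling distribution, frequent-token subsampling,
linearly decaying learning rate, minibatched SGD with deterministic numpy
sampling.  With a fixed seed the resulting table is bit-identical across
runs.  Vectors persist in the word2vec text format (header ``<vocab> <dim>``
then one token per line).

Subsampling matters here more than in free text: axiom sentences repeat a
handful of keyword tokens (the axiom kinds, ``some``, the annotation
relation) in nearly every sentence, and without downweighting them every
vector aligns with theirs, washing out the class/entity structure.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterator, Mapping, Optional

import numpy as np
from scipy import sparse

from .corpus import Corpus

__all__ = ["SkipgramParams", "EmbeddingTable", "train_embeddings",
           "remove_top_components"]


@dataclass(frozen=True)
class SkipgramParams:
    """Skip-gram hyperparameters.

    ``min_count=1`` by default so every entity and class token receives a
    vector — pair scoring fails loudly on missing tokens.  Training is
    single-threaded; ``threads`` must stay 1 (the determinism contract).
    """

    dimension: int = 50
    window: int = 5
    min_count: int = 1
    negative_samples: int = 5
    epochs: int = 100
    seed: int = 0
    threads: int = 1
    learning_rate: float = 0.025
    subsample: float = 5e-3
    vectors: str = "input"
    batch_size: int = 512

    def __post_init__(self) -> None:
        if self.dimension < 1 or self.min_count < 1:
            raise ValueError("dimension and min_count must be >= 1")
        if self.threads != 1:
            raise ValueError("only single-threaded training is supported (threads=1)")
        if self.vectors not in ("input", "input+output"):
            raise ValueError("vectors must be 'input' or 'input+output'")


class EmbeddingTable(Mapping):
    """Immutable token → n-dimensional vector map of fixed dimension."""

    def __init__(self, dimension: int, vectors: dict[str, np.ndarray]) -> None:
        if dimension < 1:
            raise ValueError("dimension must be >= 1")
        for tok, v in vectors.items():
            if v.shape != (dimension,):
                raise ValueError(
                    f"vector for {tok!r} has shape {v.shape}, expected ({dimension},)"
                )
        self.dimension = dimension
        self._vectors = dict(vectors)

    def __getitem__(self, token: str) -> np.ndarray:
        try:
            return self._vectors[token]
        except KeyError:
            raise KeyError(f"no embedding for token {token!r}") from None

    def __iter__(self) -> Iterator[str]:
        return iter(self._vectors)

    def __len__(self) -> int:
        return len(self._vectors)

    def save(self, path: str | Path) -> None:
        """Write word2vec text format, 17 significant digits."""
        with open(path, "w") as fh:
            fh.write(f"{len(self._vectors)} {self.dimension}\n")
            for tok in sorted(self._vectors):
                vals = " ".join(format(x, ".17g") for x in self._vectors[tok])
                fh.write(f"{tok} {vals}\n")

    @classmethod
    def load(cls, path: str | Path) -> "EmbeddingTable":
        with open(path) as fh:
            header = fh.readline().split()
            if len(header) != 2:
                raise ValueError(f"{path}: malformed word2vec header")
            vocab_size, dim = int(header[0]), int(header[1])
            vectors: dict[str, np.ndarray] = {}
            for row, line in enumerate(fh, start=1):
                parts = line.split()
                if not parts:
                    continue
                if len(parts) != dim + 1:
                    raise ValueError(
                        f"{path}: row {row} has {len(parts) - 1} values, expected {dim}"
                    )
                vectors[parts[0]] = np.array([float(x) for x in parts[1:]])
        if len(vectors) != vocab_size:
            raise ValueError(
                f"{path}: header promises {vocab_size} rows, found {len(vectors)}"
            )
        return cls(dim, vectors)


def _window_pattern(n: int, window: int,
                    cache: dict[int, tuple[np.ndarray, np.ndarray]]):
    """Positions (i, j), i≠j, |i−j| ≤ window, for a sentence of length n."""
    if n not in cache:
        i, j = np.meshgrid(np.arange(n), np.arange(n), indexing="ij")
        m = (i != j) & (np.abs(i - j) <= window)
        cache[n] = (i[m], j[m])
    return cache[n]


def _epoch_pairs(sent_ids: list[np.ndarray], window: int,
                 keep_prob: Optional[np.ndarray],
                 rng: np.random.Generator,
                 cache: dict) -> np.ndarray:
    """(center, context) index pairs within the window, after subsampling.

    Frequent tokens are dropped from the token stream with word2vec's keep
    probability ``sqrt(t/f)`` before windows are formed, so contexts stretch
    across removed tokens.  Redrawn every epoch.
    """
    chunks = []
    for ids in sent_ids:
        if keep_prob is not None:
            kp = keep_prob[ids]
            ids = ids[rng.random(len(ids)) < kp]
        n = len(ids)
        if n < 2:
            continue
        i, j = _window_pattern(n, window, cache)
        chunks.append(np.column_stack((ids[i], ids[j])))
    if not chunks:
        return np.empty((0, 2), dtype=np.int64)
    return np.concatenate(chunks)


def _scatter_add(target: np.ndarray, idx: np.ndarray,
                 updates: np.ndarray) -> None:
    """target[idx] += updates with duplicate indices accumulated (C speed)."""
    n = idx.shape[0]
    sel = sparse.csr_matrix((np.ones(n), (idx, np.arange(n))),
                            shape=(target.shape[0], n))
    target += sel @ updates


def _sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


def train_embeddings(c: Corpus, params: SkipgramParams = SkipgramParams(),
                     pretrain: Optional[Corpus] = None) -> EmbeddingTable:
    """Train skip-gram vectors on a corpus.

    With ``pretrain`` given, the model first trains on the background corpus
    (same number of epochs), then continues on the main corpus — the
    two-phase pre-training mode.  The vocabulary covers both corpora.
    Every token with total frequency >= ``min_count`` gets a vector.
    """
    if len(c) == 0:
        raise ValueError("cannot train embeddings on an empty corpus")

    phases = ([pretrain] if pretrain is not None else []) + [c]
    counts: dict[str, int] = {}
    for phase in phases:
        for sent in phase:
            for tok in sent:
                counts[tok] = counts.get(tok, 0) + 1
    vocab = sorted(t for t, n in counts.items() if n >= params.min_count)
    if not vocab:
        raise ValueError("no token reaches min_count")
    index = {t: i for i, t in enumerate(vocab)}

    # unigram^0.75 noise distribution over the vocabulary
    raw = np.array([counts[t] for t in vocab], dtype=np.float64)
    freq = raw ** 0.75
    noise_cdf = np.cumsum(freq / freq.sum())
    if params.subsample > 0:
        keep_prob = np.minimum(
            np.sqrt(params.subsample / (raw / raw.sum())), 1.0)
    else:
        keep_prob = None

    rng = np.random.default_rng(params.seed)
    dim = params.dimension
    w_in = (rng.random((len(vocab), dim)) - 0.5) / dim
    w_out = np.zeros((len(vocab), dim))
    pattern_cache: dict = {}

    for phase in phases:
        sent_ids = [
            np.array([index[t] for t in sent if t in index], dtype=np.int64)
            for sent in phase
        ]
        # lr decays against the un-subsampled pair count
        total = params.epochs * max(
            len(_epoch_pairs(sent_ids, params.window, None, rng,
                             pattern_cache)), 1)
        step = 0
        for _epoch in range(params.epochs):
            pairs = _epoch_pairs(sent_ids, params.window, keep_prob, rng,
                                 pattern_cache)
            order = rng.permutation(len(pairs))
            for lo in range(0, len(order), params.batch_size):
                batch = pairs[order[lo:lo + params.batch_size]]
                lr = params.learning_rate * max(1.0 - step / total, 1e-4)
                step += len(batch)
                cen, ctx = batch[:, 0], batch[:, 1]
                neg = np.searchsorted(
                    noise_cdf, rng.random((len(batch), params.negative_samples))
                )
                vc = w_in[cen]                                    # (B, d)
                # positive context update
                s_pos = _sigmoid(np.einsum("bd,bd->b", vc, w_out[ctx]))
                g_pos = (s_pos - 1.0)[:, None]                    # (B, 1)
                # negative samples update
                vn = w_out[neg]                                   # (B, k, d)
                s_neg = _sigmoid(np.einsum("bd,bkd->bk", vc, vn))
                grad_c = g_pos * w_out[ctx] + np.einsum("bk,bkd->bd", s_neg, vn)
                out_idx = np.concatenate([ctx, neg.ravel()])
                out_upd = np.concatenate([
                    -lr * g_pos * vc,
                    (-lr * s_neg[:, :, None] * vc[:, None, :]).reshape(-1, dim),
                ])
                _scatter_add(w_out, out_idx, out_upd)
                _scatter_add(w_in, cen, -lr * grad_c)

    final = w_in if params.vectors == "input" else w_in + w_out
    return EmbeddingTable(dim, {t: final[i].copy() for t, i in index.items()})


def remove_top_components(table: EmbeddingTable, n: int = 6) -> EmbeddingTable:
    """All-but-the-top post-processing: drop the common mean and top-n PCs.

    Skip-gram tables carry a large shared component (frequent co-occurring
    keywords pull every vector in the same direction), which compresses
    cosine similarities toward 1 and drowns fine structure.  Centering the
    table and projecting out the top principal components is the standard
    remedy for cosine-similarity tasks.  ``n=0`` centers only.
    """
    tokens = sorted(table)
    if len(tokens) < 2:
        return table
    m = np.array([table[t] for t in tokens])
    x = m - m.mean(axis=0)
    n = min(n, table.dimension - 1, len(tokens) - 1)
    if n > 0:
        _, _, vt = np.linalg.svd(x, full_matrices=False)
        x = x - (x @ vt[:n].T) @ vt[:n]
    return EmbeddingTable(table.dimension,
                          {t: x[i].copy() for i, t in enumerate(tokens)})
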