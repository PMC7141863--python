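"""ROC/AUC, Mann–Whitney U and model-vs-model comparison.

AUC is computed by the rank statistic with ties given half credit,

    AUC = (#{s+ > s-} + 0.5 * #{s+ = s-}) / (n+ * n-),

which coincides with U/(n+ * n-) for the Mann–Whitney U of the positive
scores against the negative scores — the identity the tests assert exactly.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
from scipy import stats
from sklearn.metrics import roc_curve

__all__ = [
    "EvalResult",
    "ComparisonResult",
    "MWUResult",
    "roc_auc",
    "mann_whitney",
    "compare_models",
]


@dataclass(frozen=True)
class EvalResult:
    auc: float
    fpr: np.ndarray
    tpr: np.ndarray
    thresholds: np.ndarray
    n_pos: int
    n_neg: int

    def save(self, path: str | Path) -> None:
        """Write ROC points as TSV plus a JSON summary block alongside."""
        path = Path(path)
        with open(path, "w") as fh:
            fh.write("threshold\tfpr\ttpr\n")
            for t, f, tp in zip(self.thresholds, self.fpr, self.tpr):
                fh.write(f"{t:.17g}\t{f:.17g}\t{tp:.17g}\n")
        summary = {"auc": self.auc, "n_pos": self.n_pos, "n_neg": self.n_neg}
        path.with_suffix(path.suffix + ".json").write_text(json.dumps(summary, indent=2))


@dataclass(frozen=True)
class MWUResult:
    u: float
    p_value: float
    method: str  # exact | asymptotic


@dataclass(frozen=True)
class ComparisonResult:
    auc_a: float
    auc_b: float
    delta: float
    p_value: float
    test_name: str
    n_resamples: Optional[int] = None


def roc_auc(scores: Sequence[float], labels: Sequence[int]) -> EvalResult:
    """Rank-based AUC (ties half-weighted) plus the full ROC curve."""
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels, dtype=int)
    if s.shape != y.shape or s.ndim != 1:
        raise ValueError("scores and labels must be 1-D and aligned")
    n_pos = int((y == 1).sum())
    n_neg = int((y == 0).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both labels must be present")
    ranks = stats.rankdata(s)  # midranks implement the half-credit tie rule
    auc = (ranks[y == 1].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg)
    fpr, tpr, thr = roc_curve(y, s, drop_intermediate=False)
    return EvalResult(float(auc), fpr, tpr, thr, n_pos, n_neg)


def mann_whitney(sample_a: Sequence[float], sample_b: Sequence[float]) -> MWUResult:
    """Two-sided Mann–Whitney U test for sample_a vs sample_b.

    The null distribution is exact (full enumeration) when
    ``n_a * n_b <= 400`` and there are no ties across the pooled sample;
    otherwise the normal approximation with tie and continuity corrections
    is used.
    """
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be non-empty")
    pooled = np.concatenate([a, b])
    has_ties = len(np.unique(pooled)) < pooled.size
    if a.size * b.size <= 400 and not has_ties:
        method = "exact"
    else:
        method = "asymptotic"
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method,
                             use_continuity=True)
    return MWUResult(float(res.statistic), float(res.pvalue), method)


def compare_models(
    scores_a: Sequence[float],
    scores_b: Sequence[float],
    labels: Sequence[int],
    method: str = "paired-bootstrap",
    seed: int = 0,
    n_resamples: int = 1000,
) -> ComparisonResult:
    """Compare two scorers evaluated on the same pair set.

    ``mwu-on-positive-scores``: Mann–Whitney U between the two models'
    scores restricted to positive pairs.  ``paired-bootstrap``: resample the
    pairs (stratified by label so both classes survive) and report the
    two-sided bootstrap p for a non-zero AUC difference.
    """
    sa = np.asarray(scores_a, dtype=float)
    sb = np.asarray(scores_b, dtype=float)
    y = np.asarray(labels, dtype=int)
    if not (sa.shape == sb.shape == y.shape):
        raise ValueError("score sets and labels must be aligned (same pair universe)")
    auc_a = roc_auc(sa, y).auc
    auc_b = roc_auc(sb, y).auc
    delta = auc_a - auc_b

    if method == "mwu-on-positive-scores":
        mwu = mann_whitney(sa[y == 1], sb[y == 1])
        return ComparisonResult(auc_a, auc_b, delta, mwu.p_value,
                                "mwu-on-positive-scores")
    if method != "paired-bootstrap":
        raise ValueError(f"unknown comparison method: {method!r}")

    rng = np.random.default_rng(seed)
    pos_idx = np.flatnonzero(y == 1)
    neg_idx = np.flatnonzero(y == 0)
    deltas = np.empty(n_resamples)
    for i in range(n_resamples):
        idx = np.concatenate([
            rng.choice(pos_idx, size=pos_idx.size, replace=True),
            rng.choice(neg_idx, size=neg_idx.size, replace=True),
        ])
        deltas[i] = roc_auc(sa[idx], y[idx]).auc - roc_auc(sb[idx], y[idx]).auc
    p = 2.0 * min(float(np.mean(deltas <= 0)), float(np.mean(deltas >= 0)))
    return ComparisonResult(auc_a, auc_b, delta, min(p, 1.0),
                            "paired-bootstrap", n_resamples)
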