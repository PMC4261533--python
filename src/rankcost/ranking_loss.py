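"""Bipartite pair construction, the 0/1 ranking loss, and its convex relaxation.

The classification problem is recast as partial ranking over all
minority-majority pairs: a scorer F is correct on a pair (x, x̄) when the
minority member scores at least as high, F(x) >= F(x̄).  The number of
reversed pairs is the 0/1 ranking loss; since minimizing it directly is
combinatorial, training uses the convex squared-hinge relaxation

    L̃(F) = ½ Σ_k max{0, F(x̄_k) − F(x_k) + τ}²

whose margin τ > 0 rules out the trivial constant scorer.  Gradients are
supplied both per pair and aggregated per sample (the form the booster
fits trees to).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "PairSet",
    "LossParams",
    "build_pairs",
    "indicator_loss",
    "relaxed_loss",
    "pair_gradients",
    "sample_gradients",
]


@dataclass(frozen=True)
class PairSet:
    """Index pairs (minority, majority) defining the ranking problem."""

    pos_index: np.ndarray
    neg_index: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "pos_index", np.asarray(self.pos_index, dtype=np.intp))
        object.__setattr__(self, "neg_index", np.asarray(self.neg_index, dtype=np.intp))
        if self.pos_index.shape != self.neg_index.shape or self.pos_index.ndim != 1:
            raise ValueError("pos_index and neg_index must be 1-D and equal length")

    @property
    def K(self) -> int:
        return self.pos_index.shape[0]


@dataclass(frozen=True)
class LossParams:
    """Margin of the squared-hinge relaxation; must be positive."""

    tau: float = 1.0

    def __post_init__(self) -> None:
        if not self.tau > 0:
            raise ValueError("tau must be positive (tau = 0 admits the constant scorer)")


def build_pairs(labels: np.ndarray) -> PairSet:
    """Exhaustive cross product of minority and majority indices.

    With S positives and T negatives, K = S x T pairs in deterministic
    positive-major order.  Raises on single-class input, where ranking is
    undefined.
    """
    labels = np.asarray(labels)
    pos = np.flatnonzero(labels == 1)
    neg = np.flatnonzero(labels == -1)
    if pos.size == 0 or neg.size == 0:
        raise ValueError("ranking is undefined without both classes present")
    return PairSet(np.repeat(pos, neg.size), np.tile(neg, pos.size))


def _margins(scores: np.ndarray, pairs: PairSet, tau: float) -> np.ndarray:
    scores = np.asarray(scores, dtype=np.float64)
    return scores[pairs.neg_index] - scores[pairs.pos_index] + tau


def indicator_loss(scores: np.ndarray, pairs: PairSet) -> int:
    """Number of reversed pairs; ties count as correctly ranked."""
    scores = np.asarray(scores, dtype=np.float64)
    return int(np.sum(scores[pairs.pos_index] < scores[pairs.neg_index]))


def relaxed_loss(scores: np.ndarray, pairs: PairSet, params: LossParams = LossParams()) -> float:
    """Squared-hinge relaxation ½ Σ_k max{0, F(x̄_k) − F(x_k) + τ}²."""
    m = _margins(scores, pairs, params.tau)
    return 0.5 * float(np.sum(np.square(np.maximum(m, 0.0))))


def pair_gradients(
    scores: np.ndarray, pairs: PairSet, params: LossParams = LossParams()
) -> tuple[np.ndarray, np.ndarray]:
    """Per-pair negative gradients (r_pos, r_neg) of the relaxed loss.

    A pair is active only while F(x_k) < F(x̄_k) + τ (strictly); at the
    margin boundary both gradients are zero.  Always r_neg = -r_pos and
    r_pos >= 0.
    """
    m = _margins(scores, pairs, params.tau)
    r_pos = np.where(m > 0, m, 0.0)
    return r_pos, -r_pos


def sample_gradients(
    scores: np.ndarray, pairs: PairSet, params: LossParams = LossParams()
) -> np.ndarray:
    """Per-sample negative gradient of the relaxed loss wrt each score.

    Entry i sums the pairwise negative gradients of every pair containing
    sample i, i.e. equals −∂L̃/∂F(x_i).  This aggregated vector is the true
    functional gradient the booster's regression trees are fitted to.
    """
    scores = np.asarray(scores, dtype=np.float64)
    r_pos, r_neg = pair_gradients(scores, pairs, params)
    n = scores.shape[0]
    out = np.bincount(pairs.pos_index, weights=r_pos, minlength=n)
    out += np.bincount(pairs.neg_index, weights=r_neg, minlength=n)
    return out
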