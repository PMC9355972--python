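"""Multinomial likelihood and the two penalized-likelihood (BIC) objectives.

Each mutation is modelled as a draw from ``Mult(1; q)`` over the 96
trinucleotide channels, with a common probability vector ``q`` inside a
segment (or cluster).  A segmentation into ``T`` parts of a chromosome
carrying ``N`` mutations is scored by

    BIC(S) = -2 log L(S) + lambda1 * T * ln(N)

and a clustering into ``K`` clusters of a genome with ``N`` mutations by
the same form with ``lambda2 * K * ln(N)``.  Natural logarithms are used
throughout, with the convention ``0 * log 0 = 0`` so empty channels are
harmless.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

N_CHANNELS = 96


@dataclass(frozen=True)
class ModelConfig:
    """Tuning parameters of the segmentation/clustering model.

    Attributes
    ----------
    lambda1 :
        Penalty weight per segment in the segmentation BIC (default 5).
    lambda2 :
        Penalty weight per cluster in the clustering BIC (default 5).
    min_bin_count :
        Mutations per initial bin (default 30).
    """

    lambda1: float = 5.0
    lambda2: float = 5.0
    min_bin_count: int = 30

    def __post_init__(self) -> None:
        if self.lambda1 <= 0 or self.lambda2 <= 0:
            raise ValueError("lambda1 and lambda2 must be positive")
        if self.min_bin_count < 1:
            raise ValueError("min_bin_count must be >= 1")


def _as_counts(c: np.ndarray) -> np.ndarray:
    c = np.asarray(c, dtype=float)
    if c.ndim != 1 or c.shape[0] != N_CHANNELS:
        raise ValueError(f"count vector must have length {N_CHANNELS}")
    if (c < 0).any():
        raise ValueError("negative counts")
    return c


def mle_profile(counts: np.ndarray) -> np.ndarray:
    """Maximum-likelihood channel profile ``q_hat = counts / n``.

    Raises
    ------
    ValueError
        If the counts sum to zero (empty segment).
    """
    c = _as_counts(counts)
    n = c.sum()
    if n == 0:
        raise ValueError("cannot compute MLE profile of an empty segment")
    return c / n


def neg2_loglik(counts: np.ndarray, q: np.ndarray) -> float:
    """``-2 * sum_i counts_i * ln(q_i)`` with ``0 * ln 0 = 0``.

    Returns ``+inf`` when some channel has positive count but zero
    probability (flagged, not raised: callers treat it as an
    impossible-fit score).
    """
    c = _as_counts(counts)
    q = np.asarray(q, dtype=float)
    pos = c > 0
    if not pos.any():
        return 0.0
    qp = q[pos]
    if (qp <= 0).any():
        return float("inf")
    return float(-2.0 * np.dot(c[pos], np.log(qp)))


def neg2_loglik_mle(counts: np.ndarray) -> float:
    """``-2 log L`` of a count vector under its own MLE profile.

    Closed form ``-2 * (sum_i c_i ln c_i - n ln n)``; the quantity every
    BIC evaluation in the greedy merges is built from.
    """
    c = _as_counts(counts)
    n = c.sum()
    if n == 0:
        raise ValueError("empty count vector")
    pos = c[c > 0]
    return float(-2.0 * (np.dot(pos, np.log(pos)) - n * np.log(n)))


def segmentation_bic(
    segment_counts: Sequence[np.ndarray], cfg: ModelConfig | None = None
) -> float:
    """BIC of a segmentation given each segment's 96-channel counts.

    ``N`` is the total over all segments (the chromosome's mutation
    count when scoring one chromosome's segmentation).
    """
    cfg = cfg or ModelConfig()
    if len(segment_counts) == 0:
        raise ValueError("empty segmentation")
    ll = 0.0
    total = 0.0
    for c in segment_counts:
        ll += neg2_loglik_mle(c)
        total += float(np.asarray(c).sum())
    return ll + cfg.lambda1 * len(segment_counts) * np.log(total)


def clustering_bic(
    cluster_counts: Sequence[np.ndarray], cfg: ModelConfig | None = None
) -> float:
    """BIC of a clustering given each cluster's pooled 96-channel counts."""
    cfg = cfg or ModelConfig()
    if len(cluster_counts) == 0:
        raise ValueError("empty clustering")
    ll = 0.0
    total = 0.0
    for c in cluster_counts:
        ll += neg2_loglik_mle(c)
        total += float(np.asarray(c).sum())
    return ll + cfg.lambda2 * len(cluster_counts) * np.log(total)
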