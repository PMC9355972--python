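"""Greedy BIC clustering of non-adjacent mutation segments.

After local merging, distant segments of the same genome may still share
a channel profile because a mutational process acts non-uniformly across
chromosomes.  Starting from singleton clusters, the pair of clusters
whose pooled merge most reduces the clustering BIC is merged repeatedly
until every merge would increase it.  Merging is genome-wide within a
sample (pairs need not be adjacent, and may span chromosomes); the
penalty uses the sample's total mutation count.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.base import BaseEstimator
from sklearn.utils.validation import check_is_fitted

from .model import ModelConfig, clustering_bic, neg2_loglik_mle
from .segmentation import Segmentation


@dataclass
class Cluster:
    """A set of segments (possibly non-adjacent) with a pooled profile."""

    cluster_id: int
    sample_id: str
    member_segments: list[int]  # indices into the Segmentation's segment list
    pooled_counts: np.ndarray = field(repr=False)

    @property
    def s_k(self) -> int:
        return len(self.member_segments)

    @property
    def N_k(self) -> int:
        return int(self.pooled_counts.sum())

    def mle_profile(self) -> np.ndarray:
        return self.pooled_counts / self.pooled_counts.sum()


@dataclass
class Clustering:
    clusters: list[Cluster]
    bic: float  # sum of per-sample clustering BICs

    @property
    def K(self) -> int:
        return len(self.clusters)

    def segment_labels(self, n_segments: int) -> np.ndarray:
        lab = np.full(n_segments, -1, dtype=np.int64)
        for c in self.clusters:
            for s in c.member_segments:
                lab[s] = c.cluster_id
        if (lab < 0).any():
            raise ValueError("clusters do not cover all segments")
        return lab

    def mutation_labels(self, segmentation: Segmentation, n_rows: int) -> np.ndarray:
        """Per-mutation cluster id, via each mutation's segment."""
        seg_lab = self.segment_labels(segmentation.T)
        lab = np.full(n_rows, -1, dtype=np.int64)
        for si, seg in enumerate(segmentation.segments):
            lab[seg.start_idx:seg.end_idx] = seg_lab[si]
        return lab


def cluster_profiles(clustering: Clustering) -> np.ndarray:
    """K x 96 matrix of pooled MLE profiles, ordered by cluster_id."""
    ordered = sorted(clustering.clusters, key=lambda c: c.cluster_id)
    return np.vstack([c.mle_profile() for c in ordered])


def _greedy_cluster(
    counts: list[np.ndarray], n_total: float, cfg: ModelConfig
) -> list[list[int]]:
    """Greedy pairwise merging of pooled count vectors within one sample.

    Returns the grouping of input indices.  The merge delta for a pair is
    [-2 log L pooled] - [-2 log L separate] - lambda2 * ln N; the most
    negative delta is merged first, ties broken toward the smallest
    (i, j) index pair; only deltas involving the merged cluster are
    recomputed.
    """
    penalty = cfg.lambda2 * float(np.log(n_total))
    active = list(range(len(counts)))
    pooled = {i: counts[i].copy() for i in active}
    ll = {i: neg2_loglik_mle(pooled[i]) for i in active}
    members = {i: [i] for i in active}

    def delta(i: int, j: int) -> float:
        return neg2_loglik_mle(pooled[i] + pooled[j]) - ll[i] - ll[j] - penalty

    deltas = {
        (i, j): delta(i, j)
        for a, i in enumerate(active)
        for j in active[a + 1:]
    }
    while len(active) > 1:
        best_pair = None
        best = np.inf
        for i_a, i in enumerate(active):
            for j in active[i_a + 1:]:
                d = deltas[(i, j)]
                if d < best:  # strict: first (lexicographically smallest) wins ties
                    best = d
                    best_pair = (i, j)
        if best > 0:
            break
        i, j = best_pair
        pooled[i] = pooled[i] + pooled[j]
        ll[i] = neg2_loglik_mle(pooled[i])
        members[i] = members[i] + members[j]
        active.remove(j)
        for k in list(deltas):
            if j in k:
                del deltas[k]
        for k in active:
            if k != i:
                pair = (min(i, k), max(i, k))
                deltas[pair] = delta(*pair)
    return [members[i] for i in active]


def distant_merge(
    segmentation: Segmentation,
    cfg: ModelConfig | None = None,
    per_chromosome: bool = False,
) -> Clustering:
    """Cluster a segmentation's segments by greedy BIC merging.

    Cluster ids are renumbered within each sample by the genomic
    position of each cluster's first segment.
    """
    cfg = cfg or ModelConfig()
    segs = segmentation.segments
    if not segs:
        raise ValueError("empty segmentation")

    def block_key(i: int):
        if per_chromosome:
            return (segs[i].sample_id, segs[i].chrom)
        return (segs[i].sample_id,)

    clusters: list[Cluster] = []
    next_id = 0
    i = 0
    while i < len(segs):
        j = i
        while j < len(segs) and block_key(j) == block_key(i):
            j += 1
        block = list(range(i, j))
        n_total = float(sum(segs[s].n_t for s in block))
        groups = _greedy_cluster([segs[s].counts for s in block], n_total, cfg)
        # order clusters by the catalog position of their first segment
        groups = [sorted(block[m] for m in g) for g in groups]
        groups.sort(key=lambda g: segs[g[0]].start_idx)
        for g in groups:
            clusters.append(
                Cluster(
                    next_id,
                    segs[g[0]].sample_id,
                    g,
                    np.sum([segs[s].counts for s in g], axis=0),
                )
            )
            next_id += 1
        i = j
    bic = _total_bic(clusters, cfg)
    return Clustering(clusters, bic)


def _total_bic(clusters: list[Cluster], cfg: ModelConfig) -> float:
    total = 0.0
    samples = list(dict.fromkeys(c.sample_id for c in clusters))
    for s in samples:
        total += clustering_bic(
            [c.pooled_counts for c in clusters if c.sample_id == s], cfg
        )
    return total


class BICClusterer(BaseEstimator):
    """Group segments into clusters of shared channel profile.

    Parameters
    ----------
    lambda2 :
        Penalty weight per cluster in the BIC (default 5).
    per_chromosome :
        If True, restrict merging to within a chromosome; default is
        genome-wide within each sample.

    Attributes
    ----------
    clustering_ : Clustering
    labels_ : ndarray of shape (n_segments,)
        Cluster id per segment.
    n_clusters_ : int
    bic_ : float
    """

    def __init__(self, lambda2: float = 5.0, per_chromosome: bool = False):
        self.lambda2 = lambda2
        self.per_chromosome = per_chromosome

    def fit(self, segmentation: Segmentation, y=None) -> "BICClusterer":
        if not isinstance(segmentation, Segmentation):
            raise TypeError("BICClusterer.fit expects a Segmentation")
        cfg = ModelConfig(lambda2=self.lambda2)
        self.clustering_ = distant_merge(segmentation, cfg, self.per_chromosome)
        self.labels_ = self.clustering_.segment_labels(segmentation.T)
        self.n_clusters_ = self.clustering_.K
        self.bic_ = self.clustering_.bic
        return self

    def fit_predict(self, segmentation: Segmentation, y=None) -> np.ndarray:
        return self.fit(segmentation).labels_

    @property
    def profiles_(self) -> np.ndarray:
        check_is_fitted(self, "clustering_")
        return cluster_profiles(self.clustering_)
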