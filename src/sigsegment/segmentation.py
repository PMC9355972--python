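"""Greedy BIC segmentation of per-chromosome mutation sequences.

Each (sample, chromosome) block of a sorted catalog is first cut into
initial bins of ``min_bin_count`` consecutive mutations.  Neighboring
segments are then merged greedily: the similarity score of an adjacent
pair is the BIC change caused by merging them,

    Sim(S_t, S_{t+1}) = [-2 log L merged] - [-2 log L separate] - lambda1 * ln N,

with N the block's mutation total.  At each step the pair with the
smallest score is merged if the score is <= 0; the process stops when
every adjacent pair has a positive score.  Each accepted merge lowers
the block BIC by exactly the magnitude of its score.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.base import BaseEstimator
from sklearn.utils.validation import check_is_fitted

from .catalog import MutationCatalog
from .model import ModelConfig, neg2_loglik_mle, segmentation_bic


@dataclass
class Segment:
    """A contiguous run of mutations with a homogeneous channel profile."""

    sample_id: str
    chrom: str
    start_idx: int  # catalog row indices, half-open
    end_idx: int
    counts: np.ndarray = field(repr=False)

    @property
    def n_t(self) -> int:
        return self.end_idx - self.start_idx

    def mle_profile(self) -> np.ndarray:
        return self.counts / self.counts.sum()


@dataclass
class Segmentation:
    """An ordered tiling of the catalog's rows by segments."""

    segments: list[Segment]
    bic: float  # sum of per-block segmentation BICs
    small_blocks: list[tuple[str, str]] = field(default_factory=list)

    @property
    def T(self) -> int:
        return len(self.segments)

    def labels(self, n_rows: int) -> np.ndarray:
        """Per-mutation segment index, following catalog row order."""
        lab = np.full(n_rows, -1, dtype=np.int64)
        for i, seg in enumerate(self.segments):
            lab[seg.start_idx:seg.end_idx] = i
        if (lab < 0).any():
            raise ValueError("segments do not tile the catalog")
        return lab

    def validate(self, catalog: MutationCatalog) -> None:
        """Check the tiling invariant and that counts match the catalog."""
        prev_end = 0
        for seg in self.segments:
            if seg.start_idx != prev_end:
                raise ValueError("segments are not contiguous")
            if seg.end_idx <= seg.start_idx:
                raise ValueError("empty segment")
            c = catalog.count_vector(slice(seg.start_idx, seg.end_idx))
            if not np.array_equal(c, seg.counts):
                raise ValueError("segment counts disagree with catalog")
            prev_end = seg.end_idx
        if prev_end != catalog.n:
            raise ValueError("segments do not cover the catalog")


def _block_bins(channels: np.ndarray, start: int, min_count: int) -> list[tuple[int, int]]:
    """Initial bin boundaries for one (sample, chrom) block of rows."""
    n = len(channels)
    if n <= min_count:
        return [(start, start + n)]
    n_bins = n // min_count
    bounds = [start + i * min_count for i in range(n_bins)]
    bounds.append(start + n)  # remainder (< min_count) merges into the last bin
    return list(zip(bounds[:-1], bounds[1:]))


def initial_bins(catalog: MutationCatalog, cfg: ModelConfig | None = None) -> Segmentation:
    """Cut every (sample, chromosome) block into bins of ``min_bin_count``.

    The trailing remainder of a block joins the previous bin; blocks
    smaller than ``min_bin_count`` become a single flagged bin.
    """
    cfg = cfg or ModelConfig()
    if catalog.n == 0:
        raise ValueError("empty catalog")
    channels = catalog.channels()
    segments: list[Segment] = []
    small: list[tuple[str, str]] = []
    for sample, chrom, lo, hi in catalog.groupby_sample_chrom():
        if hi - lo < cfg.min_bin_count:
            small.append((sample, chrom))
        for a, b in _block_bins(channels[lo:hi], lo, cfg.min_bin_count):
            counts = np.bincount(channels[a:b], minlength=96).astype(np.int64)
            segments.append(Segment(sample, chrom, a, b, counts))
    bic = _total_bic(segments, cfg)
    return Segmentation(segments, bic, small)


def _total_bic(segments: list[Segment], cfg: ModelConfig) -> float:
    """Sum of per-(sample, chrom) segmentation BICs."""
    total = 0.0
    i = 0
    while i < len(segments):
        j = i
        block = []
        while (
            j < len(segments)
            and segments[j].sample_id == segments[i].sample_id
            and segments[j].chrom == segments[i].chrom
        ):
            block.append(segments[j].counts)
            j += 1
        total += segmentation_bic(block, cfg)
        i = j
    return total


def sim_score(
    counts_a: np.ndarray, counts_b: np.ndarray, n_total: float, cfg: ModelConfig | None = None
) -> float:
    """BIC change from merging two adjacent segments in a block of N mutations.

    Negative or zero means merging does not increase the block BIC.
    """
    cfg = cfg or ModelConfig()
    merged = neg2_loglik_mle(counts_a + counts_b)
    separate = neg2_loglik_mle(counts_a) + neg2_loglik_mle(counts_b)
    return merged - separate - cfg.lambda1 * float(np.log(n_total))


def _merge_block(
    counts: list[np.ndarray], n_total: float, cfg: ModelConfig
) -> list[list[int]]:
    """Greedy adjacent merging inside one block.

    Returns the grouping of original bin indices into final segments.
    Ties on the minimal score are broken toward the leftmost pair, and
    only the scores adjacent to a merged pair are recomputed.
    """
    groups = [[i] for i in range(len(counts))]
    counts = [c.copy() for c in counts]
    ll = [neg2_loglik_mle(c) for c in counts]
    penalty = cfg.lambda1 * float(np.log(n_total))

    def score(i: int) -> float:
        return neg2_loglik_mle(counts[i] + counts[i + 1]) - ll[i] - ll[i + 1] + (-penalty)

    sims = [score(i) for i in range(len(counts) - 1)]
    while sims:
        k = int(np.argmin(sims))
        if sims[k] > 0:
            break
        counts[k] = counts[k] + counts[k + 1]
        ll[k] = neg2_loglik_mle(counts[k])
        groups[k] = groups[k] + groups[k + 1]
        del counts[k + 1], ll[k + 1], groups[k + 1], sims[k]
        if k < len(sims):
            sims[k] = score(k)
        if k > 0:
            sims[k - 1] = score(k - 1)
    return groups


def local_merge(seg0: Segmentation, cfg: ModelConfig | None = None) -> Segmentation:
    """Merge neighboring segments greedily until no merge lowers the BIC."""
    cfg = cfg or ModelConfig()
    out: list[Segment] = []
    i = 0
    segs = seg0.segments
    while i < len(segs):
        j = i
        while (
            j < len(segs)
            and segs[j].sample_id == segs[i].sample_id
            and segs[j].chrom == segs[i].chrom
        ):
            j += 1
        block = segs[i:j]
        n_total = float(sum(s.n_t for s in block))
        groups = _merge_block([s.counts for s in block], n_total, cfg)
        for g in groups:
            members = [block[m] for m in g]
            out.append(
                Segment(
                    members[0].sample_id,
                    members[0].chrom,
                    members[0].start_idx,
                    members[-1].end_idx,
                    np.sum([m.counts for m in members], axis=0),
                )
            )
        i = j
    return Segmentation(out, _total_bic(out, cfg), list(seg0.small_blocks))


class BICSegmenter(BaseEstimator):
    """Partition sorted mutation catalogs into homogeneous segments.

    Parameters
    ----------
    lambda1 :
        Penalty weight per segment in the BIC (default 5).
    min_bin_count :
        Mutations per initial bin (default 30).
    bin_mode :
        ``"count"`` (default): bins of exactly ``min_bin_count``
        mutations.  ``"width"``: fixed genomic windows of ``bin_width``
        bp grown rightward until they hold at least ``min_bin_count``
        mutations.
    bin_width :
        Window size in bp for ``bin_mode="width"`` (default 1e6).

    Attributes
    ----------
    segmentation_ : Segmentation
    labels_ : ndarray of shape (n_mutations,)
        Segment index per catalog row.
    n_segments_ : int
    bic_ : float
    """

    def __init__(
        self,
        lambda1: float = 5.0,
        min_bin_count: int = 30,
        bin_mode: str = "count",
        bin_width: float = 1_000_000.0,
    ):
        self.lambda1 = lambda1
        self.min_bin_count = min_bin_count
        self.bin_mode = bin_mode
        self.bin_width = bin_width

    def _config(self) -> ModelConfig:
        return ModelConfig(lambda1=self.lambda1, min_bin_count=self.min_bin_count)

    def fit(self, catalog: MutationCatalog, y=None) -> "BICSegmenter":
        if not isinstance(catalog, MutationCatalog):
            raise TypeError("BICSegmenter.fit expects a MutationCatalog")
        cfg = self._config()
        if self.bin_mode == "count":
            seg0 = initial_bins(catalog, cfg)
        elif self.bin_mode == "width":
            seg0 = self._width_bins(catalog, cfg)
        else:
            raise ValueError(f"unknown bin_mode {self.bin_mode!r}")
        self.initial_segmentation_ = seg0
        self.segmentation_ = local_merge(seg0, cfg)
        self.segmentation_.validate(catalog)
        self.labels_ = self.segmentation_.labels(catalog.n)
        self.n_segments_ = self.segmentation_.T
        self.bic_ = self.segmentation_.bic
        return self

    def fit_predict(self, catalog: MutationCatalog, y=None) -> np.ndarray:
        return self.fit(catalog).labels_

    def _width_bins(self, catalog: MutationCatalog, cfg: ModelConfig) -> Segmentation:
        channels = catalog.channels()
        pos = catalog.df["pos"].to_numpy()
        segments: list[Segment] = []
        small: list[tuple[str, str]] = []
        for sample, chrom, lo, hi in catalog.groupby_sample_chrom():
            if hi - lo < cfg.min_bin_count:
                small.append((sample, chrom))
            bounds = [lo]
            cursor = lo
            window_end = pos[lo] + self.bin_width
            for r in range(lo, hi):
                if pos[r] >= window_end and r - cursor >= cfg.min_bin_count:
                    bounds.append(r)
                    cursor = r
                    window_end = pos[r] + self.bin_width
            if hi - bounds[-1] < cfg.min_bin_count and len(bounds) > 1:
                bounds.pop()
            bounds.append(hi)
            for a, b in zip(bounds[:-1], bounds[1:]):
                counts = np.bincount(channels[a:b], minlength=96).astype(np.int64)
                segments.append(Segment(sample, chrom, a, b, counts))
        return Segmentation(segments, _total_bic(segments, cfg), small)

    def segment_table(self, catalog: MutationCatalog):
        """Per-segment summary DataFrame (coordinates, size)."""
        check_is_fitted(self, "segmentation_")
        import pandas as pd

        pos = catalog.df["pos"].to_numpy()
        rows = [
            {
                "segment_id": i,
                "sample_id": s.sample_id,
                "chrom": s.chrom,
                "start_pos": int(pos[s.start_idx]),
                "end_pos": int(pos[s.end_idx - 1]),
                "n_mutations": s.n_t,
            }
            for i, s in enumerate(self.segmentation_.segments)
        ]
        return pd.DataFrame(rows)
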