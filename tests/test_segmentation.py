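"""Initial binning, Sim scores and greedy local merging."""

from itertools import combinations

import numpy as np
import pytest
from scipy.special import xlogy

from sigsegment import BICSegmenter, ModelConfig, initial_bins, local_merge, sim_score
from sigsegment.model import segmentation_bic

from conftest import make_catalog


def bf_bic(segment_counts, n_total, lam=5.0):
    """Brute-force segmentation BIC, written independently of the package."""
    ll = 0.0
    for c in segment_counts:
        c = np.asarray(c, float)
        ll += -2.0 * xlogy(c, c / c.sum()).sum()
    return ll + lam * len(segment_counts) * np.log(n_total)


class TestInitialBins:
    def test_remainder_merges_into_last_bin(self):
        cat = make_catalog(np.zeros(95, dtype=int))
        seg = initial_bins(cat)
        assert [s.n_t for s in seg.segments] == [30, 30, 35]

    def test_exact_single_bin(self):
        cat = make_catalog(np.zeros(30, dtype=int))
        assert [s.n_t for s in initial_bins(cat).segments] == [30]

    def test_small_chromosome_flagged(self):
        cat = make_catalog(np.zeros(10, dtype=int))
        seg = initial_bins(cat)
        assert [s.n_t for s in seg.segments] == [10]
        assert seg.small_blocks == [("S", "1")]

    def test_empty_catalog_errors(self, catalog_factory):
        import pandas as pd

        from sigsegment import MutationCatalog

        empty = MutationCatalog(
            pd.DataFrame(
                columns=["sample_id", "chrom", "pos", "ref", "alt", "channel"]
            ).astype({"pos": int, "channel": int})
        )
        with pytest.raises(ValueError):
            initial_bins(empty)


class TestSimScore:
    def test_identical_pure_segments(self):
        a = np.zeros(96); a[0] = 30
        assert sim_score(a, a, 60) == pytest.approx(-5 * np.log(60), abs=1e-9)

    def test_disjoint_pure_segments(self):
        a = np.zeros(96); a[0] = 30
        b = np.zeros(96); b[1] = 30
        expected = -2 * 60 * np.log(0.5) - 5 * np.log(60)
        assert sim_score(a, b, 60) == pytest.approx(expected, abs=1e-9)
        assert expected == pytest.approx(62.71, abs=5e-3)

    def test_matches_direct_bic_difference_on_mixed_profiles(self):
        """Sim equals BIC(merged segmentation) - BIC(current) recomputed."""
        rng = np.random.default_rng(7)
        q = np.zeros(96); q[[0, 1]] = 0.5
        a = rng.multinomial(30, q)
        b = rng.multinomial(30, q)
        merged_bic = bf_bic([a + b], 60)
        split_bic = bf_bic([a, b], 60)
        assert sim_score(a, b, 60) == pytest.approx(merged_bic - split_bic, abs=1e-9)


class TestLocalMerge:
    def test_homogeneous_bins_collapse_to_one_segment(self):
        cat = make_catalog(np.zeros(120, dtype=int))
        seg = local_merge(initial_bins(cat))
        assert seg.T == 1
        assert seg.segments[0].n_t == 120

    def test_two_regime_boundary_recovered_exactly(self):
        channels = np.array([0] * 60 + [50] * 60)
        cat = make_catalog(channels)
        seg = local_merge(initial_bins(cat))
        assert [s.n_t for s in seg.segments] == [60, 60]
        assert seg.segments[1].start_idx == 60

    def test_fixed_point(self):
        channels = np.array([0] * 60 + [50] * 60)
        cat = make_catalog(channels)
        once = local_merge(initial_bins(cat))
        twice = local_merge(once)
        assert [s.n_t for s in twice.segments] == [s.n_t for s in once.segments]
        assert twice.bic == pytest.approx(once.bic, abs=1e-12)

    def test_bic_non_increasing_and_partition(self):
        rng = np.random.default_rng(3)
        channels = rng.integers(0, 4, size=300)
        cat = make_catalog(channels)
        seg0 = initial_bins(cat)
        seg = local_merge(seg0)
        assert seg.bic <= seg0.bic + 1e-9
        assert sum(s.n_t for s in seg.segments) == 300
        seg.validate(cat)

    def test_accepted_merges_change_bic_by_their_sim(self):
        """Each greedy merge changes the block BIC by exactly its Sim score."""
        rng = np.random.default_rng(11)
        channels = rng.integers(0, 3, size=150)
        cat = make_catalog(channels)
        seg0 = initial_bins(cat)
        counts = [s.counts.astype(float) for s in seg0.segments]
        n_total = 150
        # replay the greedy loop with full recomputation as oracle
        current = [c.copy() for c in counts]
        bic = bf_bic(current, n_total)
        while len(current) > 1:
            sims = [
                sim_score(current[i], current[i + 1], n_total)
                for i in range(len(current) - 1)
            ]
            k = int(np.argmin(sims))
            if sims[k] > 0:
                break
            current[k] = current[k] + current[k + 1]
            del current[k + 1]
            new_bic = bf_bic(current, n_total)
            assert new_bic - bic == pytest.approx(sims[k], abs=1e-9)
            bic = new_bic
        final = local_merge(seg0)
        assert final.bic == pytest.approx(bic, abs=1e-9)
        assert [c.sum() for c in current] == [s.n_t for s in final.segments]


def all_contiguous_partitions(n_bins):
    for r in range(n_bins):
        for cuts in combinations(range(1, n_bins), r):
            bounds = (0, *cuts, n_bins)
            yield [(bounds[i], bounds[i + 1]) for i in range(len(bounds) - 1)]


class TestBruteForceOracle:
    def test_greedy_bic_is_in_reachable_set_and_sims_match(self):
        """On <= 6 bins, greedy Sims equal brute-force BIC differences and the
        final BIC equals the BIC of the greedy-reachable partition."""
        rng = np.random.default_rng(5)
        channels = np.concatenate(
            [rng.integers(0, 2, 90), 3 + rng.integers(0, 2, 90)]
        )
        cat = make_catalog(channels)
        seg0 = initial_bins(cat)
        assert seg0.T == 6
        bins = [s.counts for s in seg0.segments]
        n_total = len(channels)
        # every adjacent-pair Sim equals the brute-force BIC difference
        for i in range(5):
            merged_partition = bins[:i] + [bins[i] + bins[i + 1]] + bins[i + 2:]
            diff = bf_bic(merged_partition, n_total) - bf_bic(bins, n_total)
            assert sim_score(bins[i], bins[i + 1], n_total) == pytest.approx(
                diff, abs=1e-9
            )
        final = local_merge(seg0)
        # the greedy result is one of the contiguous partitions, with its BIC
        all_bics = {}
        for part in all_contiguous_partitions(6):
            key = tuple(b - a for a, b in part)
            counts = [sum(bins[a:b], start=np.zeros(96)) for a, b in part]
            all_bics[key] = bf_bic(counts, n_total)
        key = tuple(s.n_t // 30 for s in final.segments)
        assert key in all_bics
        assert final.bic == pytest.approx(all_bics[key], abs=1e-9)
        # and no contiguous partition reachable by a further single merge is better
        assert final.bic <= min(
            all_bics[k] for k in all_bics if len(k) == len(key) - 1
        ) + 1e-9 if len(key) > 1 else True


class TestEstimatorInterface:
    def test_sklearn_conventions(self):
        est = BICSegmenter(lambda1=4.0)
        assert est.get_params()["lambda1"] == 4.0
        est.set_params(min_bin_count=10)
        cat = make_catalog(np.zeros(40, dtype=int))
        labels = est.fit_predict(cat)
        assert est.n_segments_ == 1
        assert (labels == 0).all()

    def test_width_mode_covers_catalog(self):
        rng = np.random.default_rng(2)
        cat = make_catalog(rng.integers(0, 4, 200), spacing=5000)
        est = BICSegmenter(bin_mode="width", bin_width=200_000).fit(cat)
        est.segmentation_.validate(cat)

    def test_rejects_non_catalog(self):
        with pytest.raises(TypeError):
            BICSegmenter().fit(np.zeros((10, 96)))
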