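"""Greedy BIC clustering of segments: oracles, invariances, profiles."""

import numpy as np
import pytest
from scipy.special import xlogy

from sigsegment import BICClusterer, cluster_profiles, distant_merge
from sigsegment.segmentation import Segment, Segmentation


def seg(channel_counts, chrom="1", sample="S", start=0):
    c = np.zeros(96)
    for ch, n in channel_counts.items():
        c[ch] = n
    n_t = int(c.sum())
    return Segment(sample, chrom, start, start + n_t, c)


def make_segmentation(segments):
    # assign contiguous index ranges in the given order
    out = []
    cursor = 0
    for s in segments:
        n = int(s.counts.sum())
        out.append(Segment(s.sample_id, s.chrom, cursor, cursor + n, s.counts))
        cursor += n
    return Segmentation(out, bic=0.0)


def bf_clustering_bic(cluster_counts, n_total, lam=5.0):
    ll = 0.0
    for c in cluster_counts:
        c = np.asarray(c, float)
        ll += -2.0 * xlogy(c, c / c.sum()).sum()
    return ll + lam * len(cluster_counts) * np.log(n_total)


def all_set_partitions(items):
    if len(items) == 1:
        yield [items]
        return
    first, rest = items[0], items[1:]
    for part in all_set_partitions(rest):
        for i in range(len(part)):
            yield part[:i] + [[first] + part[i]] + part[i + 1:]
        yield [[first]] + part


class TestDistantMerge:
    def test_identical_pure_profiles_across_chromosomes_merge(self):
        sg = make_segmentation([seg({0: 30}, chrom="1"), seg({0: 30}, chrom="2")])
        clustering = distant_merge(sg)
        assert clustering.K == 1
        assert clustering.clusters[0].s_k == 2
        assert clustering.clusters[0].N_k == 60

    def test_disjoint_pure_profiles_stay_apart(self):
        sg = make_segmentation([seg({0: 30}), seg({1: 30})])
        clustering = distant_merge(sg)
        assert clustering.K == 2
        # the rejected merge would have cost ~ +62.71
        merged = bf_clustering_bic([sg.segments[0].counts + sg.segments[1].counts], 60)
        split = bf_clustering_bic([sg.segments[0].counts, sg.segments[1].counts], 60)
        assert merged - split == pytest.approx(62.71, abs=5e-3)

    def test_five_segments_two_latent_mixtures_bruteforce(self, toy3):
        """Greedy K=2 with correct membership; greedy BIC equals the best
        among all 52 set partitions of the five segments."""
        rng = np.random.default_rng(42)
        qa = 0.8 * toy3.probs[0] + 0.2 * toy3.probs[1]
        qb = 0.8 * toy3.probs[2] + 0.2 * toy3.probs[1]
        counts = [
            rng.multinomial(200, qa),
            rng.multinomial(200, qa),
            rng.multinomial(200, qa),
            rng.multinomial(200, qb),
            rng.multinomial(200, qb),
        ]
        sg = make_segmentation(
            [Segment("S", "1", 0, 200, c) for c in counts]
        )
        sg = make_segmentation(sg.segments)
        clustering = distant_merge(sg)
        assert clustering.K == 2
        members = sorted(sorted(c.member_segments) for c in clustering.clusters)
        assert members == [[0, 1, 2], [3, 4]]
        n_total = 1000
        best = min(
            bf_clustering_bic(
                [sum((counts[i] for i in grp), start=np.zeros(96)) for grp in part],
                n_total,
            )
            for part in all_set_partitions(list(range(5)))
        )
        assert clustering.bic == pytest.approx(best, abs=1e-9)

    def test_greedy_deltas_match_bruteforce_differences(self):
        """The first greedy merge delta equals the brute-force BIC change."""
        rng = np.random.default_rng(9)
        counts = [rng.multinomial(100, np.full(96, 1 / 96)) for _ in range(4)]
        n_total = 400
        base = bf_clustering_bic(counts, n_total)
        from sigsegment.clustering import _greedy_cluster
        from sigsegment.model import ModelConfig

        # oracle: delta for each pair from scratch
        deltas = {}
        for i in range(4):
            for j in range(i + 1, 4):
                merged = [c for k, c in enumerate(counts) if k not in (i, j)]
                merged.append(counts[i] + counts[j])
                deltas[(i, j)] = bf_clustering_bic(merged, n_total) - base
        from sigsegment.model import neg2_loglik_mle

        cfg = ModelConfig()
        pen = cfg.lambda2 * np.log(n_total)
        for (i, j), d in deltas.items():
            impl = (
                neg2_loglik_mle(counts[i] + counts[j])
                - neg2_loglik_mle(counts[i])
                - neg2_loglik_mle(counts[j])
                - pen
            )
            assert impl == pytest.approx(d, abs=1e-9)

    def test_input_order_invariance(self, toy3):
        rng = np.random.default_rng(1)
        qa = toy3.probs[0]
        qb = toy3.probs[2]
        counts = [
            rng.multinomial(150, qa),
            rng.multinomial(150, qb),
            rng.multinomial(150, qa),
            rng.multinomial(150, qb),
        ]
        sg1 = make_segmentation([Segment("S", "1", 0, 0, c) for c in counts])
        clustering1 = distant_merge(sg1)
        sg2 = make_segmentation(
            [Segment("S", "1", 0, 0, c) for c in counts[::-1]]
        )
        clustering2 = distant_merge(sg2)
        # compare partitions as sets of pooled count vectors
        def signature(cl, sgm):
            return sorted(
                tuple(np.sort([int(sgm.segments[i].counts.argmax()) for i in c.member_segments]))
                for c in cl.clusters
            )

        m1 = sorted(tuple(sorted(c.member_segments)) for c in clustering1.clusters)
        m2 = sorted(
            tuple(sorted(3 - i for i in c.member_segments))
            for c in clustering2.clusters
        )
        assert m1 == m2

    def test_cluster_ids_ordered_by_genomic_position(self, toy3):
        rng = np.random.default_rng(3)
        counts = [rng.multinomial(200, toy3.probs[v]) for v in (2, 0, 2, 0)]
        sg = make_segmentation([Segment("S", "1", 0, 0, c) for c in counts])
        clustering = distant_merge(sg)
        assert clustering.K == 2
        first = [min(c.member_segments) for c in clustering.clusters]
        assert first == sorted(first)
        assert [c.cluster_id for c in clustering.clusters] == [0, 1]


class TestClusterProfiles:
    def test_pure_cluster_unit_row(self):
        sg = make_segmentation([seg({5: 30}), seg({5: 40})])
        clustering = distant_merge(sg)
        prof = cluster_profiles(clustering)
        assert prof.shape == (1, 96)
        assert prof[0, 5] == 1.0

    def test_equal_mix_row(self):
        counts = np.zeros(96)
        counts[0] = 30
        counts2 = np.zeros(96)
        counts2[1] = 30
        from sigsegment.clustering import Cluster, Clustering

        cl = Clustering(
            [Cluster(0, "S", [0, 1], counts + counts2)], bic=0.0
        )
        prof = cluster_profiles(cl)
        assert prof[0, 0] == prof[0, 1] == 0.5

    def test_singleton_equals_segment_mle(self, toy3):
        rng = np.random.default_rng(0)
        c = rng.multinomial(100, toy3.probs[1])
        sg = make_segmentation([Segment("S", "1", 0, 0, c)])
        clustering = distant_merge(sg)
        assert np.allclose(cluster_profiles(clustering)[0], c / c.sum())


class TestEstimator:
    def test_fit_sets_sklearn_attributes(self, toy3):
        rng = np.random.default_rng(4)
        counts = [rng.multinomial(200, toy3.probs[v]) for v in (0, 2, 0)]
        sg = make_segmentation([Segment("S", "1", 0, 0, c) for c in counts])
        est = BICClusterer().fit(sg)
        assert est.n_clusters_ == 2
        assert est.labels_.shape == (3,)
        assert est.labels_[0] == est.labels_[2] != est.labels_[1]
        assert est.profiles_.shape == (2, 96)
        assert est.get_params()["lambda2"] == 5.0
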