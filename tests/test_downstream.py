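"""Kataegis detection/enrichment and CCF pair discordance."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import hypergeom

from sigsegment import MutationCatalog
from sigsegment.downstream import (
    HypermutationFilter,
    ccf_pair_discordance,
    detect_kataegis,
    enriched_signatures,
    kataegis_enrichment,
)

from conftest import make_catalog


class TestDetectKataegis:
    def test_run_of_seven_at_500bp(self):
        cat = make_catalog(np.zeros(7, dtype=int), spacing=500)
        events, _ = detect_kataegis(cat, hyper_filter=None)
        assert len(events) == 1
        assert events[0].size == 7

    def test_exact_1000bp_spacing_is_not_kataegis(self):
        cat = make_catalog(np.zeros(6, dtype=int), spacing=1000)
        events, _ = detect_kataegis(cat, hyper_filter=None)
        assert events == []

    def test_short_run_is_not_kataegis(self):
        cat = make_catalog(np.zeros(5, dtype=int), spacing=10)
        events, _ = detect_kataegis(cat, hyper_filter=None)
        assert events == []

    def test_runs_are_maximal_and_disjoint(self):
        # two runs separated by a wide gap
        pos = np.concatenate([1000 + 100 * np.arange(8), 10_000_000 + 50 * np.arange(6)])
        df = pd.DataFrame(
            {
                "sample_id": "S",
                "chrom": "1",
                "pos": pos,
                "ref": "C",
                "alt": "T",
                "channel": 0,
            }
        )
        cat = MutationCatalog(df)
        events, _ = detect_kataegis(cat, hyper_filter=None)
        assert [e.size for e in events] == [8, 6]
        rows = np.concatenate([e.member_rows for e in events])
        assert len(rows) == len(set(rows.tolist()))

    def test_offset_concatenation_doubles_event_count(self):
        pos = 1000 + 100 * np.arange(9)
        base = pd.DataFrame(
            {
                "sample_id": "S",
                "chrom": "1",
                "pos": pos,
                "ref": "C",
                "alt": "T",
                "channel": 0,
            }
        )
        shifted = base.assign(pos=base["pos"] + 10_000_000)
        single = MutationCatalog(base)
        double = MutationCatalog(pd.concat([base, shifted], ignore_index=True))
        e1, _ = detect_kataegis(single, hyper_filter=None)
        e2, _ = detect_kataegis(double, hyper_filter=None)
        assert len(e2) == 2 * len(e1)

    def test_chromosome_change_breaks_runs(self):
        df = pd.DataFrame(
            {
                "sample_id": "S",
                "chrom": ["1"] * 4 + ["2"] * 4,
                "pos": [100, 200, 300, 400] * 2,
                "ref": "C",
                "alt": "T",
                "channel": 0,
            }
        )
        events, _ = detect_kataegis(MutationCatalog(df), hyper_filter=None)
        assert events == []

    def test_hypermutation_filter(self):
        cat = make_catalog(np.zeros(50, dtype=int), spacing=100)
        events, skipped = detect_kataegis(
            cat, hyper_filter=HypermutationFilter(max_mutations=50)
        )
        assert events == [] and skipped == ["S"]
        events, skipped = detect_kataegis(
            cat, hyper_filter=HypermutationFilter(max_mutations=51)
        )
        assert len(events) == 1 and skipped == []


class TestEnrichment:
    def test_pure_event_table_6_0_0_6(self):
        """[6,0;0,6] one-sided Fisher p = 1/C(12,6) = 1/924."""
        channels = np.zeros(12, dtype=int)
        pos = np.concatenate([100 + 100 * np.arange(6), [10_000_000 + 100_000 * k for k in range(6)]])
        df = pd.DataFrame(
            {
                "sample_id": "S",
                "chrom": "1",
                "pos": pos,
                "ref": "C",
                "alt": "T",
                "channel": channels,
            }
        )
        cat = MutationCatalog(df)
        events, _ = detect_kataegis(cat, hyper_filter=None)
        assert len(events) == 1
        labels = np.array(["v"] * 6 + ["w"] * 6, dtype=object)
        pvals = kataegis_enrichment(events[0], labels, cat)
        assert pvals["v"] == pytest.approx(1 / 924, rel=1e-9)
        assert enriched_signatures(events[0]) == ["v"]

    def test_matches_hypergeometric_tail(self):
        """Strongly enriched event: p equals the hypergeometric survival."""
        n_bg = 1000
        pos = np.concatenate(
            [100 + 50 * np.arange(10), 10_000_000 + 100_000 * np.arange(n_bg)]
        )
        labels = np.array(
            ["v"] * 10 + ["v"] * 10 + ["w"] * (n_bg - 10), dtype=object
        )
        df = pd.DataFrame(
            {
                "sample_id": "S",
                "chrom": "1",
                "pos": pos,
                "ref": "C",
                "alt": "T",
                "channel": 0,
            }
        )
        cat = MutationCatalog(df)
        events, _ = detect_kataegis(cat, hyper_filter=None)
        pvals = kataegis_enrichment(events[0], labels, cat)
        # oracle: hypergeometric tail P(X >= 10) with M=1010, n=20, N=10
        expected = hypergeom.sf(9, 1010, 20, 10)
        assert pvals["v"] == pytest.approx(expected, rel=1e-6)
        assert pvals["v"] < 0.05

    def test_background_composition_not_enriched(self):
        rng = np.random.default_rng(0)
        n = 500
        pos = np.concatenate([100 + 50 * np.arange(8), 10_000_000 + 100_000 * np.arange(n)])
        labels = np.array(
            ["v", "w"] * 4 + ["v", "w"] * (n // 2), dtype=object
        )
        df = pd.DataFrame(
            {
                "sample_id": "S",
                "chrom": "1",
                "pos": pos,
                "ref": "C",
                "alt": "T",
                "channel": 0,
            }
        )
        cat = MutationCatalog(df)
        events, _ = detect_kataegis(cat, hyper_filter=None)
        pvals = kataegis_enrichment(events[0], labels, cat)
        assert all(p > 0.2 for p in pvals.values())

    def test_unknown_sample_errors(self):
        cat = make_catalog(np.zeros(7, dtype=int), spacing=100)
        events, _ = detect_kataegis(cat, hyper_filter=None)
        events[0].sample_id = "OTHER"
        with pytest.raises(ValueError):
            kataegis_enrichment(events[0], np.array(["v"] * 7, dtype=object), cat)


def _ccf_catalog(groups):
    """groups: list of (sample, sig, ccf_values)."""
    frames = []
    cursor = 0
    for sample, sig, vals in groups:
        n = len(vals)
        frames.append(
            pd.DataFrame(
                {
                    "sample_id": sample,
                    "chrom": "1",
                    "pos": 1000 + 100 * np.arange(cursor, cursor + n),
                    "ref": "C",
                    "alt": "T",
                    "channel": 0,
                    "ccf": vals,
                    "sig": sig,
                }
            )
        )
        cursor += n
    df = pd.concat(frames, ignore_index=True)
    cat = MutationCatalog(df)
    return cat, cat.df["sig"].to_numpy(dtype=object)


class TestCCFPairs:
    def test_identical_distributions_not_discordant(self):
        vals = np.linspace(0.1, 0.9, 50)
        cat, labels = _ccf_catalog([("S", "v", vals), ("S", "w", vals)])
        df = ccf_pair_discordance(cat, labels)
        assert len(df) == 1
        assert df.loc[0, "D"] == 0.0
        assert df.loc[0, "p_value"] == 1.0
        assert not df.loc[0, "discordant"]

    def test_disjoint_supports_fully_discordant(self):
        cat, labels = _ccf_catalog(
            [("S", "v", np.full(50, 1.0)), ("S", "w", np.full(50, 0.1))]
        )
        df = ccf_pair_discordance(cat, labels)
        assert df.loc[0, "D"] == 1.0
        assert df.loc[0, "fdr_q"] < 0.05
        assert df.loc[0, "sig_early"] == "v"  # higher median CCF = earlier

    def test_min_per_signature_filter(self):
        cat, labels = _ccf_catalog(
            [("S", "v", np.full(50, 0.9)), ("S", "w", np.full(5, 0.1))]
        )
        df = ccf_pair_discordance(cat, labels, min_per_signature=10)
        assert len(df) == 0

    def test_bh_matches_bruteforce(self):
        rng = np.random.default_rng(4)
        groups = []
        for s in range(12):
            groups.append((f"S{s:02d}", "v", rng.beta(5, 2, 30)))
            groups.append((f"S{s:02d}", "w", rng.beta(2, 5, 30)))
        cat, labels = _ccf_catalog(groups)
        df = ccf_pair_discordance(cat, labels)
        # brute-force BH
        p = df["p_value"].to_numpy()
        m = len(p)
        order = np.argsort(p)
        q = np.empty(m)
        prev = 1.0
        for rank, idx in enumerate(reversed(order), start=0):
            i = m - rank
            prev = min(prev, p[idx] * m / i)
            q[idx] = prev
        assert np.allclose(df["fdr_q"].to_numpy(), q, atol=1e-12)
        assert (df["fdr_q"].to_numpy() >= p - 1e-15).all()

    def test_no_ccf_errors(self):
        cat = make_catalog(np.zeros(12, dtype=int))
        with pytest.raises(ValueError):
            ccf_pair_discordance(cat, np.array(["v"] * 12, dtype=object))
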