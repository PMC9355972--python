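"""Kataegis detection/enrichment and CCF-based signature-pair discordance.

Kataegis is a localized hypermutation event: a maximal run of at least
``min_run`` consecutive mutations on one chromosome, each pair of
successive members separated by fewer than ``max_dist`` bp (defaults 6
and 1000).  Hypermutated samples (>= 30,000 mutations by default) are
excluded.  Per event, signature enrichment against the sample background
is scored by a one-sided Fisher exact test.

Evolutionary discordance of two signatures within a sample is scored by
a two-sided two-sample Kolmogorov-Smirnov test on the cancer cell
fraction (CCF) values of their assigned mutations, with Benjamini-
Hochberg FDR control pooled across all pairs of all samples.  In a
discordant pair the signature with the higher median CCF is reported as
the earlier (more clonal) process.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from scipy.stats import fisher_exact, ks_2samp
from statsmodels.stats.multitest import multipletests

from .catalog import MutationCatalog


@dataclass(frozen=True)
class HypermutationFilter:
    """Samples with at least ``max_mutations`` SNVs are excluded."""

    max_mutations: int = 30_000

    def passes(self, sample_size: int) -> bool:
        return sample_size < self.max_mutations


@dataclass
class KataegisEvent:
    sample_id: str
    chrom: str
    start: int
    end: int
    member_rows: np.ndarray = field(repr=False)
    signature_counts: dict | None = None
    enrichment_p: dict | None = None

    @property
    def size(self) -> int:
        return len(self.member_rows)


def detect_kataegis(
    catalog: MutationCatalog,
    min_run: int = 6,
    max_dist: int = 1000,
    hyper_filter: HypermutationFilter | None = HypermutationFilter(),
) -> tuple[list[KataegisEvent], list[str]]:
    """Maximal close-spaced mutation runs per sample and chromosome.

    Returns the events plus the list of samples skipped by the
    hypermutation filter.  Runs require every successive intermutation
    distance to be strictly below ``max_dist``; chromosome changes break
    runs; events are maximal and therefore disjoint.
    """
    sizes = catalog.sample_sizes()
    skipped = (
        [s for s, n in sizes.items() if not hyper_filter.passes(n)]
        if hyper_filter is not None
        else []
    )
    skipped_set = set(skipped)
    pos = catalog.df["pos"].to_numpy()
    events: list[KataegisEvent] = []
    for sample, chrom, lo, hi in catalog.groupby_sample_chrom():
        if sample in skipped_set:
            continue
        run_start = lo
        for i in range(lo + 1, hi + 1):
            if i == hi or pos[i] - pos[i - 1] >= max_dist:
                if i - run_start >= min_run:
                    rows = np.arange(run_start, i)
                    events.append(
                        KataegisEvent(
                            sample, chrom, int(pos[run_start]), int(pos[i - 1]), rows
                        )
                    )
                run_start = i
    return events, skipped


def kataegis_enrichment(
    event: KataegisEvent,
    signature_labels: np.ndarray,
    catalog: MutationCatalog,
    alpha: float = 0.05,
) -> dict:
    """One-sided Fisher enrichment of each signature present in an event.

    The 2x2 table for signature v is [[v in event, other in event],
    [v elsewhere in the sample, other elsewhere]]; the alternative is
    enrichment ("greater").  Returns per-signature p-values; an event
    may carry two or more signatures below *alpha*.
    """
    labels = np.asarray(signature_labels, dtype=object)
    if len(labels) != catalog.n:
        raise ValueError("signature labels do not cover the catalog")
    sample_rows = np.where(
        (catalog.df["sample_id"] == event.sample_id).to_numpy()
    )[0]
    if sample_rows.size == 0:
        raise ValueError(f"sample {event.sample_id!r} absent from assignments")
    in_event = np.zeros(catalog.n, dtype=bool)
    in_event[event.member_rows] = True
    event_labels = labels[event.member_rows]
    sample_mask = np.zeros(catalog.n, dtype=bool)
    sample_mask[sample_rows] = True
    outside = sample_mask & ~in_event
    n_event = event.size
    n_outside = int(outside.sum())
    pvals: dict = {}
    counts: dict = {}
    for sig in pd.unique(event_labels):
        if sig is None:
            continue
        a = int((event_labels == sig).sum())
        c = int((labels[outside] == sig).sum())
        table = [[a, n_event - a], [c, n_outside - c]]
        _, p = fisher_exact(table, alternative="greater")
        pvals[sig] = float(p)
        counts[sig] = a
    event.signature_counts = counts
    event.enrichment_p = pvals
    return pvals


def enriched_signatures(event: KataegisEvent, alpha: float = 0.05) -> list:
    if event.enrichment_p is None:
        raise ValueError("run kataegis_enrichment first")
    return [s for s, p in event.enrichment_p.items() if p < alpha]


def ccf_pair_discordance(
    catalog: MutationCatalog,
    signature_labels: np.ndarray,
    min_per_signature: int = 10,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Pairwise KS discordance of per-signature CCF distributions.

    Within each sample, signatures with at least ``min_per_signature``
    assigned mutations carrying CCF values are compared pairwise by a
    two-sided two-sample KS test; q-values are Benjamini-Hochberg over
    the pooled list of all pairs of all samples.  The earlier signature
    of a pair is the one with the higher median CCF.

    Returns a DataFrame with columns sample_id, sig_early, sig_late,
    n_early, n_late, D, p_value, fdr_q, discordant.
    """
    labels = np.asarray(signature_labels, dtype=object)
    if len(labels) != catalog.n:
        raise ValueError("signature labels do not cover the catalog")
    ccf = catalog.df["ccf"].to_numpy(dtype=float)
    if np.isnan(ccf).all():
        raise ValueError("catalog has no CCF values")
    rows = []
    for sample in catalog.samples:
        mask = (catalog.df["sample_id"] == sample).to_numpy() & ~np.isnan(ccf)
        by_sig = {}
        for sig in pd.unique(labels[mask]):
            if sig is None:
                continue
            vals = ccf[mask & (labels == sig)]
            if len(vals) >= min_per_signature:
                by_sig[sig] = vals
        for v, w in combinations(sorted(by_sig, key=str), 2):
            res = ks_2samp(by_sig[v], by_sig[w], alternative="two-sided")
            early, late = (
                (v, w) if np.median(by_sig[v]) >= np.median(by_sig[w]) else (w, v)
            )
            rows.append(
                {
                    "sample_id": sample,
                    "sig_early": early,
                    "sig_late": late,
                    "n_early": len(by_sig[early]),
                    "n_late": len(by_sig[late]),
                    "D": float(res.statistic),
                    "p_value": float(res.pvalue),
                }
            )
    df = pd.DataFrame(
        rows,
        columns=[
            "sample_id", "sig_early", "sig_late", "n_early", "n_late", "D", "p_value",
        ],
    )
    if len(df) == 0:
        df["fdr_q"] = pd.Series(dtype=float)
        df["discordant"] = pd.Series(dtype=bool)
        return df
    _, q, _, _ = multipletests(df["p_value"].to_numpy(), method="fdr_bh")
    df["fdr_q"] = q
    df["discordant"] = df["fdr_q"] < alpha
    return df
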