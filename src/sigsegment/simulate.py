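"""Ground-truth synthetic catalogs for every stage of the pipeline.

The generator mirrors the model's own assumptions: a genome is a list of
regions, each with a mutation count, a signature exposure vector d, a
latent three-level signal band and a clonality mode.  Per mutation, a
signature is drawn from d, a channel from that signature's row of H,
and a genomic position by cumulative geometric spacing.  Regions that
share an exposure vector form a latent cluster, which is what the
segmentation + clustering stages are expected to recover.

Positions are memoryless (geometric gaps) rather than a full genomic
background model; CCF is Beta-distributed per clonality mode; the
signal is a noisy three-band track.  These choices are sufficient for
every consuming test but do not emulate real covariates such as
replication-timing gradients or copy number.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .catalog import MutationCatalog
from .channels import channel_label
from .model import N_CHANNELS
from .signatures import SignatureMatrix

#: latent signal band means for levels 1, 2, 3 (arbitrary signal units)
SIGNAL_BAND_MEANS = {1: 0.2, 2: 0.5, 3: 0.8}
SIGNAL_BAND_SD = 0.05

#: CCF Beta parameters per clonality mode
CCF_PARAMS = {"clonal": (50.0, 2.0), "subclonal": (5.0, 15.0)}


@dataclass
class RegionSpec:
    """One homogeneous genomic region of the synthetic genome."""

    chrom: str
    mutation_count: int
    exposures: np.ndarray
    signal_level: int = 2
    ccf_mode: str = "clonal"
    spacing_mean_bp: float = 1000.0
    sample_id: str = "SIM"

    def __post_init__(self) -> None:
        self.exposures = np.asarray(self.exposures, dtype=float)
        if self.mutation_count < 1:
            raise ValueError("mutation_count must be >= 1")
        if abs(self.exposures.sum() - 1.0) > 1e-9 or (self.exposures < 0).any():
            raise ValueError("exposures must be a probability vector")
        if self.signal_level not in (1, 2, 3):
            raise ValueError("signal_level must be 1, 2 or 3")
        if self.ccf_mode not in CCF_PARAMS:
            raise ValueError(f"unknown ccf_mode {self.ccf_mode!r}")


def toy_signature_matrix(
    n_signatures: int = 4,
    decay: float = 0.45,
    own_block: int = 4,
    shared_block: int = 4,
    shared_mass: tuple[float, float] = (0.45, 0.20),
) -> SignatureMatrix:
    """Synthetic signatures emulating the structure of real ones.

    Two features of real signature catalogs are reproduced.  First,
    concentration: each signature's own channels decay geometrically,
    so most of its mass sits on a handful of channels (as the CpG C>T
    channels dominate the clock-like signature).  The BIC penalty
    (lambda * ln N) is far below the 95 nominal degrees of freedom of a
    full channel profile, so the merge machinery presumes exactly this
    concentration.  Second, non-exclusivity: all signatures share a
    common channel block — the first signature places ``shared_mass[0]``
    (default 45%) of its mass there and every other signature
    ``shared_mass[1]`` (default 20%), mirroring how the CpG transition
    channels are representative of one process yet produced by several.
    Shared channels make per-mutation assignment genuinely probabilistic
    and region-dependent; without them the channel alone would identify
    the signature.
    """
    if not 1 <= n_signatures <= 7:
        raise ValueError("toy matrix supports 1..7 signatures")
    if n_signatures * own_block + shared_block > N_CHANNELS:
        raise ValueError("blocks exceed 96 channels")
    probs = np.zeros((n_signatures, N_CHANNELS))
    own_w = decay ** np.arange(own_block)
    own_w /= own_w.sum()
    shr_w = decay ** np.arange(shared_block)
    shr_w /= shr_w.sum()
    shared = slice(N_CHANNELS - shared_block, N_CHANNELS)
    for v in range(n_signatures):
        s = shared_mass[0] if v == 0 else shared_mass[1]
        probs[v, v * own_block:(v + 1) * own_block] = (1.0 - s) * own_w
        probs[v, shared] = s * shr_w
    ids = [f"TOY{v + 1}" for v in range(n_signatures)]
    return SignatureMatrix(ids, probs)


def _channel_ref_alt(channel: int) -> tuple[str, str]:
    label = channel_label(channel)  # e.g. A[C>A]A
    return label[2], label[4]


def simulate_catalog(
    regions: list[RegionSpec],
    H: SignatureMatrix,
    seed: int | None = None,
    chrom_gap_bp: int = 100_000,
) -> tuple[MutationCatalog, pd.DataFrame]:
    """Draw a sorted catalog and its truth table from region specs.

    Returns the catalog and a row-aligned truth DataFrame with columns
    ``true_signature`` (signature index into H), ``region_id`` and
    ``true_cluster`` (regions sharing an exposure vector share a
    cluster id).
    """
    if not regions:
        raise ValueError("need at least one region")
    V = H.n_signatures
    for r in regions:
        if len(r.exposures) != V:
            raise ValueError(
                f"region exposure length {len(r.exposures)} != {V} signatures"
            )
    rng = np.random.default_rng(seed)
    cluster_ids: dict[tuple, int] = {}
    cursors: dict[tuple[str, str], int] = {}
    frames = []
    for rid, region in enumerate(regions):
        key = tuple(np.round(region.exposures, 12))
        cluster = cluster_ids.setdefault(key, len(cluster_ids))
        n = region.mutation_count
        sigs = rng.choice(V, size=n, p=region.exposures)
        channels = np.empty(n, dtype=np.int64)
        for v in range(V):
            m = sigs == v
            if m.any():
                channels[m] = rng.choice(N_CHANNELS, size=int(m.sum()), p=H.probs[v])
        gaps = rng.geometric(1.0 / region.spacing_mean_bp, size=n)
        start = cursors.get((region.sample_id, region.chrom), 0) + chrom_gap_bp
        pos = start + np.cumsum(gaps)
        cursors[(region.sample_id, region.chrom)] = int(pos[-1])
        refalt = [_channel_ref_alt(c) for c in channels]
        frames.append(
            pd.DataFrame(
                {
                    "sample_id": region.sample_id,
                    "chrom": region.chrom,
                    "pos": pos,
                    "ref": [ra[0] for ra in refalt],
                    "alt": [ra[1] for ra in refalt],
                    "channel": channels,
                    "true_signature": sigs,
                    "region_id": rid,
                    "true_cluster": cluster,
                }
            )
        )
    df = pd.concat(frames, ignore_index=True)
    catalog = MutationCatalog(df)
    truth = catalog.df[["true_signature", "region_id", "true_cluster"]].copy()
    return catalog, truth


def attach_ccf_and_signal(
    catalog: MutationCatalog,
    regions: list[RegionSpec],
    seed: int | None = None,
) -> MutationCatalog:
    """Fill per-mutation CCF and signal columns from the region specs.

    Clonal regions draw CCF from Beta(50, 2) (mode near 1), subclonal
    from Beta(5, 15); the signal is Gaussian around the region's level
    band mean.  Deterministic per seed.
    """
    if "region_id" not in catalog.df.columns:
        raise ValueError("catalog lacks region_id; use simulate_catalog output")
    rng = np.random.default_rng(seed)
    df = catalog.df.copy()
    rid = df["region_id"].to_numpy()
    ccf = np.empty(len(df))
    signal = np.empty(len(df))
    for i, region in enumerate(regions):
        mask = rid == i
        k = int(mask.sum())
        a, b = CCF_PARAMS[region.ccf_mode]
        ccf[mask] = rng.beta(a, b, size=k)
        signal[mask] = rng.normal(
            SIGNAL_BAND_MEANS[region.signal_level], SIGNAL_BAND_SD, size=k
        )
    df["ccf"] = np.clip(ccf, 0.0, 1.0)
    df["signal"] = signal
    return MutationCatalog(df)


def simulate_kataegis(
    catalog: MutationCatalog,
    events: int,
    size: int,
    spacing_bp: int,
    signature: int,
    H: SignatureMatrix,
    seed: int | None = None,
    min_clearance_bp: int = 10_000,
) -> MutationCatalog:
    """Inject close-spaced mutation runs into an existing catalog.

    Each run has ``size`` mutations at ``spacing_bp`` intervals, with
    channels drawn from signature ``signature`` of H, placed at random
    loci at least ``min_clearance_bp`` away from every existing or
    previously injected mutation.
    """
    if spacing_bp >= 1000:
        raise ValueError("spacing_bp must be < 1000 so injected runs are kataegic")
    rng = np.random.default_rng(seed)
    df = catalog.df
    chrom = df["chrom"].iloc[0]
    sample = df["sample_id"].iloc[0]
    chrom_mask = (df["chrom"] == chrom) & (df["sample_id"] == sample)
    occupied = np.sort(df.loc[chrom_mask, "pos"].to_numpy())
    span = size * spacing_bp
    lo, hi = int(occupied.min()), int(occupied.max()) + 10 * min_clearance_bp
    new_frames = []
    placed = 0
    for _ in range(events * 200):
        if placed == events:
            break
        start = int(rng.integers(lo, hi))
        window = (start - min_clearance_bp, start + span + min_clearance_bp)
        i = np.searchsorted(occupied, window[0])
        if i < len(occupied) and occupied[i] < window[1]:
            continue
        pos = start + spacing_bp * np.arange(size)
        channels = rng.choice(N_CHANNELS, size=size, p=H.probs[signature])
        refalt = [_channel_ref_alt(c) for c in channels]
        new_frames.append(
            pd.DataFrame(
                {
                    "sample_id": sample,
                    "chrom": chrom,
                    "pos": pos,
                    "ref": [ra[0] for ra in refalt],
                    "alt": [ra[1] for ra in refalt],
                    "channel": channels,
                    "true_signature": signature,
                    "region_id": -1,
                    "true_cluster": -1,
                }
            )
        )
        occupied = np.sort(np.concatenate([occupied, pos]))
        placed += 1
    if placed < events:
        raise RuntimeError("no room left on the simulated chromosome")
    base = df.copy()
    for col in ("true_signature", "region_id", "true_cluster"):
        if col not in base.columns:
            base[col] = -1
    out = pd.concat([base] + new_frames, ignore_index=True)
    return MutationCatalog(out)


def two_regime_chromosome(
    n_per_regime: int = 1000,
    seed: int | None = None,
    n_signatures: int = 3,
) -> tuple[MutationCatalog, pd.DataFrame, int]:
    """A single chromosome with one exposure switch at a known index."""
    H = toy_signature_matrix(n_signatures)
    d_a = np.zeros(n_signatures); d_a[0] = 0.7; d_a[1] = 0.2; d_a[-1] += 0.1
    d_b = d_a[::-1].copy()
    regions = [
        RegionSpec("1", n_per_regime, d_a),
        RegionSpec("1", n_per_regime, d_b),
    ]
    catalog, truth = simulate_catalog(regions, H, seed=seed)
    return catalog, truth, n_per_regime


def default_study_genome(
    seed: int | None = None,
    n_per_region: int = 5000,
    n_signatures: int = 3,
) -> tuple[MutationCatalog, pd.DataFrame, list[RegionSpec], SignatureMatrix]:
    """The reference two-cluster, three-signature study genome.

    Four regions on two chromosomes; regions 0 and 2 share exposure
    vector d_A = (0.7, 0.2, 0.1) and latent signal level 1 (clonal),
    regions 1 and 3 share d_B = (0.1, 0.2, 0.7) and level 3
    (subclonal).  With the default 5000 mutations per region the genome
    carries N = 20,000 mutations and its true cluster count is 2.
    """
    H = toy_signature_matrix(n_signatures)
    d_a = np.array([0.7, 0.2, 0.1] + [0.0] * (n_signatures - 3))
    d_b = d_a[::-1].copy()
    regions = [
        RegionSpec("1", n_per_region, d_a, signal_level=1, ccf_mode="clonal"),
        RegionSpec("1", n_per_region, d_b, signal_level=3, ccf_mode="subclonal"),
        RegionSpec("2", n_per_region, d_a, signal_level=1, ccf_mode="clonal"),
        RegionSpec("2", n_per_region, d_b, signal_level=3, ccf_mode="subclonal"),
    ]
    catalog, truth = simulate_catalog(regions, H, seed=seed)
    catalog = attach_ccf_and_signal(catalog, regions, seed=None if seed is None else seed + 1)
    return catalog, truth, regions, H


def alternating_genome(
    seed: int | None = None,
    n_regions: int = 12,
    n_per_region: int = 300,
    n_signatures: int = 3,
) -> tuple[MutationCatalog, pd.DataFrame, list[RegionSpec], SignatureMatrix]:
    """Many short regions alternating between two exposure vectors.

    This is the regime where assignment granularity matters: regional
    exposures differ strongly from the genome-wide average (so
    sample-level refitting mislabels shared-channel mutations), and
    individual segments are short enough that their own exposure
    estimates are noisy — pooling same-profile segments into clusters
    is what recovers precision.
    """
    H = toy_signature_matrix(n_signatures)
    d_a = np.array([0.7, 0.2, 0.1] + [0.0] * (n_signatures - 3))
    d_b = d_a[::-1].copy()
    regions = [
        RegionSpec(str(1 + i // 4), n_per_region, d_a if i % 2 == 0 else d_b)
        for i in range(n_regions)
    ]
    catalog, truth = simulate_catalog(regions, H, seed=seed)
    return catalog, truth, regions, H


def bayes_optimal_accuracy(
    region_exposures: np.ndarray,
    region_weights: np.ndarray,
    H: SignatureMatrix,
) -> float:
    """Analytic Bayes-optimal assignment accuracy of a synthetic genome.

    Given true region exposures d_r and the mutation fraction w_r of
    each region, the best achievable accuracy of any per-mutation rule
    that sees (region, channel) is

        sum_r w_r * sum_c max_v d_rv * h_vc .
    """
    D = np.atleast_2d(np.asarray(region_exposures, dtype=float))
    w = np.asarray(region_weights, dtype=float)
    w = w / w.sum()
    acc = 0.0
    for d, wr in zip(D, w):
        joint = d[:, None] * H.probs  # V x 96
        acc += wr * joint.max(axis=0).sum()
    return float(acc)
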