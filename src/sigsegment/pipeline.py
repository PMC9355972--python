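"""End-to-end pipeline: read, segment, cluster, refit, assign, analyze.

The stages mirror the method: catalog construction, per-chromosome BIC
segmentation, genome-wide BIC clustering, per-cluster exposure
refitting, maximum-posterior assignment, then the optional downstream
analyses (signal concordance, kataegis, CCF pair discordance).  A run
manifest records the configuration, seeds and output checksums so a
re-run with identical inputs is byte-identical.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .assignment import SignatureAssigner
from .catalog import MutationCatalog
from .concordance import cluster_concordance
from .downstream import (
    HypermutationFilter,
    ccf_pair_discordance,
    detect_kataegis,
    kataegis_enrichment,
)
from .io import SignalTrack, attach_signal, read_mutations, write_outputs
from .signatures import read_signature_matrix

ALL_STAGES = ("segment", "cluster", "assign", "concordance", "kataegis", "ks-pairs")


@dataclass
class PipelineConfig:
    """Configuration of a full run; defaults are the method's settings."""

    input_path: str
    signatures_path: str
    out_dir: str
    input_format: str = "auto"
    fasta: str | None = None
    sample_id: str | None = None
    min_mutations: int = 3000
    lambda1: float = 5.0
    lambda2: float = 5.0
    min_bin_count: int = 30
    method: str = "em"
    granularity: str = "cluster"
    signature_subset: list[str] | None = None
    min_exposure: float = 0.0
    permutations: int = 10_000
    seed: int = 0
    signal: str | None = None  # bedGraph path or catalog column name
    kataegis_min_run: int = 6
    kataegis_max_dist: int = 1000
    hypermutation_cap: int = 30_000
    ks_min_per_signature: int = 10
    fdr_alpha: float = 0.05
    stages: tuple = ALL_STAGES


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_pipeline(
    cfg: PipelineConfig, catalog: MutationCatalog | None = None
) -> dict:
    """Execute the configured stages; returns the manifest dict.

    On failure, files created during this run are removed before the
    exception propagates.
    """
    out_dir = Path(cfg.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    created: list[Path] = []
    try:
        return _run(cfg, catalog, out_dir, created)
    except Exception:
        for p in created:
            p.unlink(missing_ok=True)
        raise


def _run(cfg, catalog, out_dir: Path, created: list[Path]) -> dict:
    signatures = read_signature_matrix(cfg.signatures_path)
    if cfg.signature_subset:
        signatures = signatures.subset(list(cfg.signature_subset))
    if catalog is None:
        catalog = read_mutations(
            cfg.input_path,
            format=cfg.input_format,
            fasta=cfg.fasta,
            min_mutations=cfg.min_mutations,
            sample_id=cfg.sample_id,
        )
    if cfg.signal and not cfg.signal in catalog.df.columns:
        track = SignalTrack.from_bedgraph(cfg.signal)
        catalog = attach_signal(catalog, track)

    assigner = SignatureAssigner(
        signatures=signatures,
        lambda1=cfg.lambda1,
        lambda2=cfg.lambda2,
        min_bin_count=cfg.min_bin_count,
        method=cfg.method,
        granularity=cfg.granularity,
        min_exposure=cfg.min_exposure,
    ).fit(catalog)

    want = set(cfg.stages)
    if hasattr(assigner, "segmenter_"):
        segmentation = assigner.segmenter_.segmentation_
    else:  # sample granularity skips segmentation; outputs still need it
        from .segmentation import BICSegmenter

        segmentation = (
            BICSegmenter(lambda1=cfg.lambda1, min_bin_count=cfg.min_bin_count)
            .fit(catalog)
            .segmentation_
        )
    if hasattr(assigner, "clusterer_"):
        clustering = assigner.clusterer_.clustering_
    else:
        # exposures were fit at another granularity; clusters are still
        # computed for the segment/cluster output tables
        from .clustering import BICClusterer

        clustering = BICClusterer(lambda2=cfg.lambda2).fit(segmentation).clustering_
    posterior = assigner.posterior_ if "assign" in want else None
    paths = write_outputs(
        catalog,
        segmentation,
        clustering,
        out_dir,
        posterior=posterior,
        signature_ids=signatures.signature_ids,
        signature_labels=assigner.signature_labels_ if "assign" in want else None,
    )
    created.extend(paths.values())

    results: dict = {"n_segments": segmentation.T, "n_clusters": clustering.K}
    if "concordance" in want and catalog.has_signal:
        tests = cluster_concordance(
            catalog.df["signal"].to_numpy(),
            assigner.region_labels_,
            B=cfg.permutations,
            seed=cfg.seed,
        )
        df = pd.DataFrame(
            {
                "cluster_id": [t.cluster_id for t in tests],
                "entropy": [t.observed_entropy for t in tests],
                "p_value": [t.p_value for t in tests],
                "B": [t.B for t in tests],
                "seed": [t.seed for t in tests],
            }
        )
        p = out_dir / "concordance.tsv"
        df.to_csv(p, sep="\t", index=False, float_format="%.10g")
        created.append(p)
        paths["concordance"] = p

    if "kataegis" in want and "assign" in want:
        events, skipped = detect_kataegis(
            catalog,
            min_run=cfg.kataegis_min_run,
            max_dist=cfg.kataegis_max_dist,
            hyper_filter=HypermutationFilter(cfg.hypermutation_cap),
        )
        labels = np.asarray(assigner.signature_labels_, dtype=object)
        rows = []
        for e in events:
            pvals = kataegis_enrichment(e, labels, catalog, alpha=cfg.fdr_alpha)
            rows.append(
                {
                    "sample_id": e.sample_id,
                    "chrom": e.chrom,
                    "start": e.start,
                    "end": e.end,
                    "size": e.size,
                    "enriched": ",".join(
                        str(s) for s, p in sorted(pvals.items()) if p < cfg.fdr_alpha
                    ),
                }
            )
        p = out_dir / "kataegis.tsv"
        pd.DataFrame(
            rows, columns=["sample_id", "chrom", "start", "end", "size", "enriched"]
        ).to_csv(p, sep="\t", index=False)
        created.append(p)
        paths["kataegis"] = p
        results["n_kataegis"] = len(events)
        results["kataegis_skipped_samples"] = skipped

    if "ks-pairs" in want and "assign" in want and catalog.has_ccf:
        df = ccf_pair_discordance(
            catalog,
            np.asarray(assigner.signature_labels_, dtype=object),
            min_per_signature=cfg.ks_min_per_signature,
            alpha=cfg.fdr_alpha,
        )
        p = out_dir / "ks_pairs.tsv"
        df.to_csv(p, sep="\t", index=False, float_format="%.10g")
        created.append(p)
        paths["ks_pairs"] = p
        results["n_discordant_pairs"] = int(df["discordant"].sum()) if len(df) else 0

    manifest = {
        "version": __version__,
        "config": {
            k: (list(v) if isinstance(v, tuple) else v)
            for k, v in asdict(cfg).items()
        },
        "results": results,
        "outputs": {k: {"path": str(v), "sha256": _sha256(v)} for k, v in paths.items()},
    }
    mpath = out_dir / "manifest.json"
    mpath.write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    created.append(mpath)
    return manifest
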