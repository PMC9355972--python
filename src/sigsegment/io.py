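"""Readers and writers for mutation calls, signal tracks and results.

Input coordinates are 1-based (VCF/MAF convention); all BED output is
0-based half-open.  Non-SNV rows are skipped and counted, records whose
reference base disagrees with the FASTA are dropped and counted, and
samples below the ``min_mutations`` floor are rejected with an explicit
status rather than silently propagated.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .catalog import CORE_COLUMNS, MutationCatalog
from .channels import ContextError, encode_context
from .signatures import SignatureMatrix

_BASES = {"A", "C", "G", "T"}

#: accepted column aliases for the generic TSV dialect, lower-cased
_TSV_ALIASES = {
    "chrom": {"chrom", "chromosome", "chr", "#chrom"},
    "pos": {"pos", "position", "start", "start_position"},
    "ref": {"ref", "reference_allele", "ref_allele"},
    "alt": {"alt", "alt_allele", "tumor_seq_allele2"},
    "sample_id": {"sample_id", "sample", "tumor_sample_barcode"},
    "context": {"context", "trinucleotide", "tri"},
    "channel": {"channel"},
    "signal": {"signal"},
}


@dataclass
class ReadReport:
    """Bookkeeping from catalog construction."""

    n_records: int = 0
    n_non_snv_skipped: int = 0
    n_ref_mismatch_dropped: int = 0
    n_context_unresolved: int = 0
    rejected_samples: dict = field(default_factory=dict)
    nonprimary_contigs: int = 0


def _fasta_context(fasta, chrom: str, pos: int) -> str:
    seq = fasta[chrom][pos - 2:pos + 1]
    return str(seq).upper()


def _finalize(
    df: pd.DataFrame,
    fasta_path: str | Path | None,
    min_mutations: int,
    ccf_column: str | None,
    report: ReadReport,
) -> MutationCatalog:
    """Compute channels, apply the sample floor, build the catalog."""
    df = df.copy()
    df["ref"] = df["ref"].astype(str).str.upper()
    df["alt"] = df["alt"].astype(str).str.upper()
    snv = df["ref"].isin(_BASES) & df["alt"].isin(_BASES) & (df["ref"] != df["alt"])
    report.n_non_snv_skipped += int((~snv).sum())
    df = df[snv]

    if "channel" not in df.columns or df["channel"].isna().any():
        if "context" in df.columns and df["context"].notna().all():
            contexts = df["context"].astype(str).str.upper()
        else:
            if fasta_path is None:
                raise ValueError(
                    "no context/channel columns in input; a reference FASTA is required"
                )
            from pyfaidx import Fasta

            fasta = Fasta(str(fasta_path), sequence_always_upper=True)
            contexts = pd.Series(
                [
                    _fasta_context(fasta, c, p)
                    for c, p in zip(df["chrom"].astype(str), df["pos"].astype(int))
                ],
                index=df.index,
            )
        channels = np.full(len(df), -1, dtype=np.int64)
        keep = np.ones(len(df), dtype=bool)
        for i, (tri, ref, alt) in enumerate(
            zip(contexts, df["ref"], df["alt"])
        ):
            if len(tri) != 3 or tri[1] != ref:
                report.n_ref_mismatch_dropped += 1
                keep[i] = False
                continue
            try:
                channels[i] = encode_context(tri, ref, alt)
            except ContextError:
                report.n_context_unresolved += 1
                keep[i] = False
        df = df.assign(channel=channels)[keep]

    if ccf_column and ccf_column in df.columns and "ccf" not in df.columns:
        df = df.rename(columns={ccf_column: "ccf"})

    if len(df) == 0:
        raise ValueError("no usable SNV records in input")

    sizes = df.groupby("sample_id").size()
    small = sizes[sizes < min_mutations]
    for s, n in small.items():
        report.rejected_samples[s] = int(n)
    df = df[~df["sample_id"].isin(small.index)]
    if len(df) == 0:
        raise ValueError(
            f"all samples fall below the {min_mutations}-mutation floor: "
            f"{report.rejected_samples}"
        )
    keep_cols = CORE_COLUMNS + [c for c in ("ccf", "signal") if c in df.columns]
    catalog = MutationCatalog(df[keep_cols])
    report.n_records = catalog.n
    report.nonprimary_contigs = int(catalog.flag_nonprimary().sum())
    catalog.report = report
    return catalog


def _read_tsv(path, sample_id: str, ccf_column: str | None) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    rename = {}
    for col in df.columns:
        low = str(col).lower()
        for canon, aliases in _TSV_ALIASES.items():
            if low in aliases:
                rename[col] = canon
    df = df.rename(columns=rename)
    required = {"chrom", "pos", "ref", "alt"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"TSV is missing columns: {sorted(missing)}")
    if "sample_id" not in df.columns:
        df["sample_id"] = sample_id
    df["chrom"] = df["chrom"].astype(str)
    return df


def _read_maf(path, ccf_column: str | None) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", comment="#", low_memory=False)
    cols = {
        "Chromosome": "chrom",
        "Start_Position": "pos",
        "Reference_Allele": "ref",
        "Tumor_Seq_Allele2": "alt",
        "Tumor_Sample_Barcode": "sample_id",
    }
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise ValueError(f"MAF is missing columns: {missing}")
    keep = list(cols) + [c for c in (ccf_column,) if c and c in df.columns]
    df = df[keep].rename(columns=cols)
    df["chrom"] = df["chrom"].astype(str)
    return df


def _read_vcf(path, sample_id: str, ccf_column: str | None) -> pd.DataFrame:
    from cyvcf2 import VCF

    rows = []
    for var in VCF(str(path)):
        for alt in var.ALT:  # multi-allelic sites are split per ALT
            rows.append(
                {
                    "sample_id": sample_id,
                    "chrom": str(var.CHROM),
                    "pos": var.POS,
                    "ref": var.REF,
                    "alt": alt,
                    "ccf": var.INFO.get(ccf_column) if ccf_column else None,
                }
            )
    if not rows:
        raise ValueError("no usable SNV records in input")
    return pd.DataFrame(rows)


def read_mutations(
    path: str | Path,
    format: str = "auto",
    fasta: str | Path | None = None,
    min_mutations: int = 3000,
    sample_id: str | None = None,
    ccf_column: str | None = "ccf",
) -> MutationCatalog:
    """Read somatic SNVs from VCF, MAF or TSV into a sorted catalog.

    ``min_mutations`` applies the cohort inclusion floor per sample
    (default 3000); rejected samples are listed in the returned
    catalog's ``report.rejected_samples``.
    """
    path = Path(path)
    if format == "auto":
        suffixes = "".join(path.suffixes).lower()
        if ".vcf" in suffixes:
            format = "vcf"
        elif ".maf" in suffixes:
            format = "maf"
        else:
            format = "tsv"
    sample = sample_id or path.stem
    report = ReadReport()
    if format == "tsv":
        df = _read_tsv(path, sample, ccf_column)
    elif format == "maf":
        df = _read_maf(path, ccf_column)
    elif format == "vcf":
        df = _read_vcf(path, sample, ccf_column)
    else:
        raise ValueError(f"unknown format {format!r}")
    if ccf_column and ccf_column in df.columns:
        df = df.rename(columns={ccf_column: "ccf"})
    return _finalize(df, fasta, min_mutations, "ccf", report)


# ---------------------------------------------------------------------------
# signal tracks


@dataclass
class SignalTrack:
    """Per-chromosome sorted, non-overlapping (start, end, value) intervals.

    Coordinates are 0-based half-open, as in bedGraph/bigWig.
    """

    intervals: pd.DataFrame  # columns chrom, start, end, value

    def __post_init__(self) -> None:
        need = {"chrom", "start", "end", "value"}
        if not need <= set(self.intervals.columns):
            raise ValueError(f"track needs columns {sorted(need)}")
        df = self.intervals.sort_values(["chrom", "start"]).reset_index(drop=True)
        for _, grp in df.groupby("chrom", sort=False):
            if (grp["start"].to_numpy()[1:] < grp["end"].to_numpy()[:-1]).any():
                raise ValueError("overlapping intervals in signal track")
        self.intervals = df

    @classmethod
    def from_bedgraph(cls, path: str | Path) -> "SignalTrack":
        df = pd.read_csv(
            path,
            sep="\t",
            comment="#",
            header=None,
            names=["chrom", "start", "end", "value"],
            dtype={"chrom": str},
        )
        return cls(df)

    @classmethod
    def from_bigwig(cls, path: str | Path) -> "SignalTrack":
        import pyBigWig

        bw = pyBigWig.open(str(path))
        rows = []
        for chrom in bw.chroms():
            for start, end, value in bw.intervals(chrom) or []:
                rows.append((chrom, start, end, value))
        bw.close()
        return cls(pd.DataFrame(rows, columns=["chrom", "start", "end", "value"]))

    def values_at(self, chroms: np.ndarray, positions: np.ndarray) -> np.ndarray:
        """Signal value covering each 1-based position; NaN in gaps."""
        chroms = np.asarray(chroms, dtype=object)
        pos0 = np.asarray(positions, dtype=np.int64) - 1  # to 0-based
        out = np.full(len(pos0), np.nan)
        for chrom, grp in self.intervals.groupby("chrom", sort=False):
            mask = chroms == chrom
            if not mask.any():
                continue
            starts = grp["start"].to_numpy()
            ends = grp["end"].to_numpy()
            vals = grp["value"].to_numpy(dtype=float)
            idx = np.searchsorted(starts, pos0[mask], side="right") - 1
            ok = (idx >= 0) & (pos0[mask] < ends[np.clip(idx, 0, None)])
            res = np.full(int(mask.sum()), np.nan)
            res[ok] = vals[idx[ok]]
            out[mask] = res
        return out


def attach_signal(catalog: MutationCatalog, track: SignalTrack) -> MutationCatalog:
    """Annotate every mutation with the covering track value (NaN in gaps)."""
    df = catalog.df.copy()
    df["signal"] = track.values_at(df["chrom"].to_numpy(), df["pos"].to_numpy())
    out = MutationCatalog(df)
    out.n_signal_gaps = int(np.isnan(out.df["signal"].to_numpy()).sum())
    return out


# ---------------------------------------------------------------------------
# result writers

_FLOAT_FMT = "%.10g"


def write_outputs(
    catalog: MutationCatalog,
    segmentation,
    clustering,
    out_dir: str | Path,
    posterior: np.ndarray | None = None,
    signature_ids: list[str] | None = None,
    signature_labels: list | None = None,
) -> dict[str, Path]:
    """Write segments.bed, clusters.tsv and (optionally) assignments.tsv.

    Output is deterministic: fixed column order and float formatting, so
    identical inputs give byte-identical files.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    if clustering is None or clustering.K == 0:
        raise ValueError("empty clustering; nothing to write")
    pos = catalog.df["pos"].to_numpy()
    seg_cluster = clustering.segment_labels(segmentation.T)

    paths: dict[str, Path] = {}
    bed = out_dir / "segments.bed"
    with open(bed, "w") as fh:
        for i, seg in enumerate(segmentation.segments):
            fh.write(
                f"{seg.chrom}\t{pos[seg.start_idx] - 1}\t{pos[seg.end_idx - 1]}\t"
                f"segment_{i}|cluster_{seg_cluster[i]}|{seg.sample_id}\t{seg.n_t}\t.\n"
            )
    paths["segments"] = bed

    rows = []
    for c in sorted(clustering.clusters, key=lambda c: c.cluster_id):
        rows.append(
            {
                "cluster_id": c.cluster_id,
                "sample_id": c.sample_id,
                "n_segments": c.s_k,
                "n_mutations": c.N_k,
                "member_segments": ",".join(map(str, c.member_segments)),
            }
        )
    clusters_path = out_dir / "clusters.tsv"
    pd.DataFrame(rows).to_csv(clusters_path, sep="\t", index=False)
    paths["clusters"] = clusters_path

    if posterior is not None:
        if signature_ids is None:
            raise ValueError("signature_ids required with posterior")
        mut_cluster = clustering.mutation_labels(segmentation, catalog.n)
        df = catalog.df[["sample_id", "chrom", "pos", "ref", "alt", "channel"]].copy()
        df["cluster_id"] = mut_cluster
        if signature_labels is not None:
            df["assigned_signature"] = [
                s if s is not None else "." for s in signature_labels
            ]
        for j, sid in enumerate(signature_ids):
            df[f"p_{sid}"] = posterior[:, j]
        assign_path = out_dir / "assignments.tsv"
        df.to_csv(assign_path, sep="\t", index=False, float_format=_FLOAT_FMT)
        paths["assignments"] = assign_path
    return paths


def read_assignments(path: str | Path) -> pd.DataFrame:
    """Round-trip reader for assignments.tsv."""
    return pd.read_csv(path, sep="\t", dtype={"chrom": str})


def write_catalog_tsv(catalog: MutationCatalog, path: str | Path) -> None:
    """Write a catalog in the package's own TSV dialect (re-readable)."""
    cols = ["sample_id", "chrom", "pos", "ref", "alt", "channel"]
    for c in ("ccf", "signal"):
        if catalog.df[c].notna().any():
            cols.append(c)
    catalog.df[cols].to_csv(path, sep="\t", index=False, float_format=_FLOAT_FMT)
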