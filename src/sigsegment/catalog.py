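"""Coordinate-sorted somatic SNV catalogs.

A :class:`MutationCatalog` wraps a pandas DataFrame with one row per
single-nucleotide variant and a precomputed 96-channel context index.
It is the in-memory container every stage of the pipeline consumes; the
full binary N x 96 indicator matrix of the model is never materialized —
per-segment channel count vectors are the sufficient statistic.
"""

from __future__ import annotations

from typing import Iterable

import numpy as np
import pandas as pd

from .model import N_CHANNELS

#: required catalog columns, in output order
CORE_COLUMNS = ["sample_id", "chrom", "pos", "ref", "alt", "channel"]
OPTIONAL_COLUMNS = ["ccf", "signal"]

_PRIMARY_CONTIGS = {str(i) for i in range(1, 23)} | {"X", "Y"}


def chrom_sort_key(chrom: str) -> tuple[int, int, str]:
    """Natural ordering for contig names: 1..22, X, Y, MT, then others."""
    c = chrom[3:] if chrom.lower().startswith("chr") else chrom
    if c.isdigit():
        return (0, int(c), "")
    special = {"X": 23, "Y": 24, "M": 25, "MT": 25}
    if c.upper() in special:
        return (0, special[c.upper()], "")
    return (1, 0, c)


def is_primary_contig(chrom: str) -> bool:
    c = chrom[3:] if chrom.lower().startswith("chr") else chrom
    return c.upper() in _PRIMARY_CONTIGS


class MutationCatalog:
    """A sorted catalog of SNVs with 96-channel context indices.

    Parameters
    ----------
    df :
        DataFrame with at least :data:`CORE_COLUMNS`.  Rows are sorted
        by (sample, contig, position) on construction; duplicate
        (sample, chrom, pos, alt) rows are rejected.
    """

    def __init__(self, df: pd.DataFrame):
        missing = [c for c in CORE_COLUMNS if c not in df.columns]
        if missing:
            raise ValueError(f"catalog is missing columns: {missing}")
        df = df.copy()
        for col in OPTIONAL_COLUMNS:
            if col not in df.columns:
                df[col] = np.nan
        df["pos"] = df["pos"].astype(np.int64)
        df["channel"] = df["channel"].astype(np.int64)
        if ((df["channel"] < 0) | (df["channel"] >= N_CHANNELS)).any():
            raise ValueError("channel indices must lie in 0..95")
        if (df["ref"] == df["alt"]).any():
            raise ValueError("catalog contains records with ref == alt")
        key = df["chrom"].map(chrom_sort_key)
        df = (
            df.assign(_ck=key)
            .sort_values(["sample_id", "_ck", "pos"], kind="mergesort")
            .drop(columns="_ck")
            .reset_index(drop=True)
        )
        dup = df.duplicated(subset=["sample_id", "chrom", "pos", "alt"])
        if dup.any():
            raise ValueError(
                f"{int(dup.sum())} duplicate (sample, chrom, pos, alt) records"
            )
        self.df = df

    # -- basic protocol -------------------------------------------------
    def __len__(self) -> int:
        return len(self.df)

    @property
    def n(self) -> int:
        return len(self.df)

    @property
    def samples(self) -> list[str]:
        return list(dict.fromkeys(self.df["sample_id"]))

    def sample_sizes(self) -> dict[str, int]:
        return self.df.groupby("sample_id", sort=False).size().to_dict()

    @property
    def has_ccf(self) -> bool:
        return bool(self.df["ccf"].notna().any())

    @property
    def has_signal(self) -> bool:
        return bool(self.df["signal"].notna().any())

    def channels(self) -> np.ndarray:
        return self.df["channel"].to_numpy()

    def count_vector(self, index: Iterable[int] | slice | None = None) -> np.ndarray:
        """96-channel count vector of the whole catalog or a row subset."""
        ch = self.df["channel"].to_numpy()
        if index is not None:
            ch = ch[index]
        return np.bincount(ch, minlength=N_CHANNELS).astype(np.int64)

    def groupby_sample_chrom(self):
        """Yield ``(sample_id, chrom, start_row, end_row)`` blocks in order."""
        df = self.df
        ids = df["sample_id"].to_numpy()
        chroms = df["chrom"].to_numpy()
        if len(df) == 0:
            return
        start = 0
        for i in range(1, len(df) + 1):
            if i == len(df) or ids[i] != ids[start] or chroms[i] != chroms[start]:
                yield ids[start], chroms[start], start, i
                start = i

    def subset_rows(self, rows: np.ndarray) -> "MutationCatalog":
        return MutationCatalog(self.df.iloc[rows].reset_index(drop=True))

    def flag_nonprimary(self) -> pd.Series:
        """Boolean mask of records on non-primary contigs (kept, flagged)."""
        return ~self.df["chrom"].map(is_primary_contig)

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return (
            f"MutationCatalog(n={self.n}, samples={len(self.samples)}, "
            f"ccf={self.has_ccf}, signal={self.has_signal})"
        )
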