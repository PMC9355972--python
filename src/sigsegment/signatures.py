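"""Signature probability matrices (COSMIC-style) and derived quantities."""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .channels import CHANNEL_LABELS, CPG_TRANSITION_CHANNELS, parse_channel_label
from .model import N_CHANNELS

_ROW_SUM_TOL = 1e-3


@dataclass
class SignatureMatrix:
    """A set of mutational signatures as rows of channel probabilities.

    Attributes
    ----------
    signature_ids :
        One identifier per signature, e.g. ``SBS1``.
    probs :
        ``V x 96`` array; each row is a probability distribution over the
        canonical channel ordering (rows re-normalized on construction if
        they are within 1e-3 of one).
    """

    signature_ids: list[str]
    probs: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        self.probs = np.asarray(self.probs, dtype=float)
        if self.probs.ndim != 2 or self.probs.shape[1] != N_CHANNELS:
            raise ValueError(f"probs must be V x {N_CHANNELS}")
        if len(self.signature_ids) != self.probs.shape[0]:
            raise ValueError("signature_ids length does not match probs rows")
        if self.probs.shape[0] < 1:
            raise ValueError("need at least one signature")
        if (self.probs < 0).any():
            raise ValueError("signature matrix contains negative entries")
        sums = self.probs.sum(axis=1)
        bad = np.abs(sums - 1.0) > _ROW_SUM_TOL
        if bad.any():
            ids = [self.signature_ids[i] for i in np.where(bad)[0]]
            raise ValueError(f"signature rows do not sum to 1: {ids}")
        self.probs = self.probs / sums[:, None]

    @property
    def n_signatures(self) -> int:
        return self.probs.shape[0]

    def subset(self, ids: list[str]) -> "SignatureMatrix":
        index = {s: i for i, s in enumerate(self.signature_ids)}
        missing = [s for s in ids if s not in index]
        if missing:
            raise KeyError(f"unknown signatures: {missing}")
        rows = [index[s] for s in ids]
        return SignatureMatrix(list(ids), self.probs[rows])


def _looks_like_channel(label: str) -> bool:
    try:
        parse_channel_label(str(label))
        return True
    except Exception:
        return False


def read_signature_matrix(path: str | Path | io.IOBase) -> SignatureMatrix:
    """Read a tab-separated signature matrix in COSMIC Ver. 2 layout.

    Accepts either orientation: 96 channel rows with one column per
    signature (the COSMIC download, with its ``Substitution Type`` /
    ``Trinucleotide`` / ``Somatic Mutation Type`` label columns), or the
    transpose with one row per signature and channel-labelled columns.
    Channels are re-indexed into the canonical ordering regardless of
    file order.
    """
    df = pd.read_csv(path, sep="\t")
    df = df.dropna(axis=1, how="all")  # COSMIC files carry trailing empty columns

    cols = [str(c) for c in df.columns]
    if any(_looks_like_channel(c) for c in cols):
        # transposed layout: signatures in rows
        chan_cols = [c for c in df.columns if _looks_like_channel(c)]
        if len(chan_cols) != N_CHANNELS:
            raise ValueError(
                f"expected {N_CHANNELS} channel columns, found {len(chan_cols)}"
            )
        label_cols = [c for c in df.columns if c not in chan_cols]
        if label_cols:
            ids = df[label_cols[0]].astype(str).tolist()
        else:
            ids = [f"S{i + 1}" for i in range(len(df))]
        order = np.argsort([parse_channel_label(str(c)) for c in chan_cols])
        probs = df[chan_cols].to_numpy(dtype=float)[:, order]
        return SignatureMatrix(ids, probs)

    # channel-row layout: find the column holding channel labels
    chan_col = None
    for c in df.columns:
        if df[c].astype(str).map(_looks_like_channel).all():
            chan_col = c
            break
    if chan_col is None:
        raise ValueError(
            "could not locate channel labels (e.g. 'A[C>A]A') in rows or columns"
        )
    if len(df) != N_CHANNELS:
        raise ValueError(f"expected {N_CHANNELS} channel rows, found {len(df)}")
    channels = df[chan_col].astype(str).map(parse_channel_label).to_numpy()
    if len(set(channels.tolist())) != N_CHANNELS:
        raise ValueError("duplicate or missing channel labels")
    value_cols = [
        c
        for c in df.columns
        if c != chan_col and pd.api.types.is_numeric_dtype(df[c])
    ]
    if not value_cols:
        raise ValueError("no numeric signature columns found")
    probs = np.zeros((len(value_cols), N_CHANNELS))
    probs[:, channels] = df[value_cols].to_numpy(dtype=float).T
    ids = [_normalize_signature_id(str(c)) for c in value_cols]
    return SignatureMatrix(ids, probs)


def _normalize_signature_id(name: str) -> str:
    """Map COSMIC column headers like ``Signature 1`` onto ``SBS1``."""
    name = name.strip()
    low = name.lower()
    if low.startswith("signature"):
        tail = name[len("signature"):].strip(" ._-")
        if tail:
            return f"SBS{tail}"
    return name


def write_signature_matrix(sig: SignatureMatrix, path: str | Path) -> None:
    """Write a signature matrix in the transposed (signature-row) layout."""
    df = pd.DataFrame(sig.probs, columns=list(CHANNEL_LABELS))
    df.insert(0, "signature", sig.signature_ids)
    df.to_csv(path, sep="\t", index=False)


def cpg_transition_mass(sig: SignatureMatrix) -> pd.Series:
    """Per-signature probability mass on the four NpCpG C>T channels.

    This is the quantity behind statements like "C>T at CpG accounts for
    44.7% of SBS1": the summed probability of the ``A[C>T]G``,
    ``C[C>T]G``, ``G[C>T]G`` and ``T[C>T]G`` channels, reported as a
    fraction per signature.
    """
    mass = sig.probs[:, list(CPG_TRANSITION_CHANNELS)].sum(axis=1)
    return pd.Series(mass, index=sig.signature_ids, name="cpg_ct_mass")
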