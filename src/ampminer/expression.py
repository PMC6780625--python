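"""TPM (transcripts per million) quantification from read-count tables.

TPM length-normalises raw counts so values are comparable across genes
and libraries: for gene i with count c_i and effective length l_i,

    rate_i = c_i / l_i          TPM_i = 1e6 * rate_i / sum_j rate_j

so per-tissue TPM values sum to one million whenever any count is
nonzero. Effective length is taken as the CDS length (no fragment-length
correction). A gene counts as detected in a tissue when its TPM exceeds
the threshold (default 0, i.e. any expression at all).
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

LENGTH_COLUMN = "length"


def read_counts(path: str | Path) -> pd.DataFrame:
    """Read a counts TSV (``gene_id  length  <tissue columns...>``),
    indexed by gene_id."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    if LENGTH_COLUMN not in df.columns:
        raise ValueError(f"counts table must have a '{LENGTH_COLUMN}' column")
    return df


def _split(table: pd.DataFrame) -> tuple[pd.Series, pd.DataFrame]:
    if LENGTH_COLUMN not in table.columns:
        raise ValueError(f"counts table must have a '{LENGTH_COLUMN}' column")
    lengths = table[LENGTH_COLUMN].astype(float)
    counts = table.drop(columns=[LENGTH_COLUMN]).astype(float)
    if (lengths <= 0).any():
        bad = list(table.index[lengths <= 0])
        raise ValueError(f"non-positive effective lengths for: {bad}")
    if (counts < 0).any().any():
        raise ValueError("counts must be non-negative")
    return lengths, counts


def compute_tpm(table: pd.DataFrame) -> pd.DataFrame:
    """TPM per gene per tissue. A tissue with all-zero counts yields all
    zero TPM (not an error)."""
    lengths, counts = _split(table)
    rates = counts.div(lengths, axis=0)
    totals = rates.sum(axis=0)
    tpm = rates.div(totals.where(totals > 0, np.nan), axis=1) * 1e6
    return tpm.fillna(0.0)


def detect_expressed(
    tpm: pd.DataFrame, subset=None, threshold: float = 0.0
) -> pd.Series:
    """Per-tissue counts of genes with TPM strictly above ``threshold``.

    ``subset`` restricts to a gene list (e.g. the putative AMP catalog);
    unknown ids are an error, listed explicitly.
    """
    sub = tpm
    if subset is not None:
        subset = list(subset)
        unknown = sorted(set(subset) - set(tpm.index))
        if unknown:
            raise KeyError(f"gene ids not in TPM table: {unknown}")
        sub = tpm.loc[subset]
    return (sub > threshold).sum(axis=0)


def top_n(
    tpm: pd.DataFrame, subset=None, tissue: str = None, n: int = 20
) -> pd.DataFrame:
    """Top-``n`` genes by TPM in one tissue, descending; ties break by
    gene name ascending. TPM is reported to 2 decimals."""
    if n < 1:
        raise ValueError("n must be >= 1")
    if tissue not in tpm.columns:
        raise KeyError(f"unknown tissue: {tissue}")
    sub = tpm
    if subset is not None:
        subset = list(subset)
        unknown = sorted(set(subset) - set(tpm.index))
        if unknown:
            raise KeyError(f"gene ids not in TPM table: {unknown}")
        sub = tpm.loc[subset]
    order = sorted(sub.index, key=lambda g: (-sub.at[g, tissue], str(g)))[:n]
    return pd.DataFrame(
        {"gene": order, "tpm": [round(float(sub.at[g, tissue]), 2) for g in order]}
    )
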