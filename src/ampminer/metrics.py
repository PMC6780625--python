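"""Assembly summary statistics: Nx contiguity, genome fractions, and
pseudochromosome-table totals.

All statistics operate on plain sequences of lengths (bases) or on a
chromosome table with columns ``chromosome``, ``length_bp``, ``n_genes``,
``n_scaffolds``. Nx is defined on the length set's own total, following
assembler convention, not on an external genome-size denominator.
"""

from __future__ import annotations

import re
from typing import Iterable, Mapping, Sequence

import pandas as pd

from ._util import round_half_away

CHROMOSOME_TABLE_COLUMNS = ("chromosome", "length_bp", "n_genes", "n_scaffolds")


def _check_lengths(lengths: Sequence[int]) -> list[int]:
    out = [int(x) for x in lengths]
    if not out:
        raise ValueError("length set is empty")
    if any(x <= 0 for x in out):
        raise ValueError("lengths must be positive")
    return out


def nx_stat(lengths: Sequence[int], x: float = 50) -> int:
    """Nx statistic: the smallest length L such that sequences of length
    >= L cover at least x% of the total.

    N50 and N90 are the conventional contiguity measures for contig and
    scaffold sets.
    """
    if not 0 < x < 100:
        raise ValueError(f"x must be in (0, 100), got {x}")
    ls = sorted(_check_lengths(lengths), reverse=True)
    total = sum(ls)
    cum = 0
    for length in ls:
        cum += length
        # integer comparison avoids float threshold wobble
        if cum * 100 >= x * total:
            return length
    return ls[-1]  # pragma: no cover - unreachable, cum == total at the end


def count_over(lengths: Iterable[int], threshold: int) -> int:
    """Number of sequences strictly longer than ``threshold`` bases."""
    if threshold < 0:
        raise ValueError("threshold must be >= 0")
    return sum(1 for x in lengths if x > threshold)


def genome_fraction(part_bases: int, whole_bases: int, decimals: int = 1) -> float:
    """Percentage of the genome covered by a feature class (e.g. repeats,
    transposable elements), from summed base counts."""
    if whole_bases <= 0:
        raise ValueError("whole_bases must be positive")
    if part_bases < 0:
        raise ValueError("part_bases must be non-negative")
    return round_half_away(100.0 * part_bases / whole_bases, decimals)


def annotation_support_fraction(supported: int, total: int) -> float:
    """Percentage of genes supported by functional-annotation evidence,
    to 2 decimals."""
    if total <= 0:
        raise ValueError("total must be positive")
    if supported > total:
        raise ValueError("supported exceeds total")
    return round_half_away(100.0 * supported / total, 2)


def chromosome_table_summary(rows: pd.DataFrame | Iterable[Mapping]) -> dict:
    """Totals and means over a pseudochromosome table.

    Returns total length (bp), total genes, total scaffolds, mean
    chromosome length in Mb (2 decimals), mean scaffolds per chromosome
    (both floor and exact), and the largest / smallest chromosomes.
    """
    df = rows if isinstance(rows, pd.DataFrame) else pd.DataFrame(list(rows))
    missing = set(CHROMOSOME_TABLE_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"chromosome table missing columns: {sorted(missing)}")
    if df.empty:
        raise ValueError("chromosome table is empty")
    if (df[["length_bp", "n_genes", "n_scaffolds"]] < 0).any().any():
        raise ValueError("counts must be non-negative")

    total_length = int(df["length_bp"].sum())
    total_genes = int(df["n_genes"].sum())
    total_scaffolds = int(df["n_scaffolds"].sum())
    n = len(df)
    largest = df.loc[df["length_bp"].idxmax()]
    smallest = df.loc[df["length_bp"].idxmin()]
    return {
        "n_chromosomes": n,
        "total_length_bp": total_length,
        "total_genes": total_genes,
        "total_scaffolds": total_scaffolds,
        "mean_length_mb": round_half_away(total_length / n / 1e6, 2),
        "mean_scaffolds_floor": total_scaffolds // n,
        "mean_scaffolds_exact": total_scaffolds / n,
        "largest": {
            "chromosome": str(largest["chromosome"]),
            "length_bp": int(largest["length_bp"]),
        },
        "smallest": {
            "chromosome": str(smallest["chromosome"]),
            "length_bp": int(smallest["length_bp"]),
        },
    }


def natural_chromosome_key(name: str) -> tuple:
    """Sort key placing Chr2 before Chr10."""
    parts = re.split(r"(\d+)", str(name))
    return tuple(int(p) if p.isdigit() else p for p in parts)
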