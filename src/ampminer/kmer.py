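"""K-mer depth profiling and genome-size estimation from unassembled reads.

The survey-sequencing estimator: count every k-mer window of the reads
under its canonical form (the lexicographic minimum of the k-mer and its
reverse complement, since reads are unstranded), build the histogram of
distinct k-mers by depth, take the depth of the main histogram peak as the
per-base sequencing depth, and estimate

    genome size  ~=  total k-mer occurrences / peak depth.

The low-depth error peak (singleton k-mers created by sequencing errors)
is excluded by a simple ``min_depth`` cutoff rather than valley detection.
Counting is in-memory and vectorised; it is intended for desk-scale inputs
(up to ~1e7 k-mer windows), not production-scale survey data.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np

from ._util import round_half_away

DEFAULT_K = 17

_BASE_CODE = np.full(256, -1, dtype=np.int8)
for _i, _b in enumerate("ACGT"):
    _BASE_CODE[ord(_b)] = _i
    _BASE_CODE[ord(_b.lower())] = _i


class PeakNotFoundError(ValueError):
    """Raised when the depth histogram has no mass at or above min_depth."""


@dataclass(frozen=True)
class KmerHistogram:
    """Distinct-k-mer counts by depth plus total k-mer occurrences."""

    k: int
    depth_counts: Mapping[int, int]
    total_kmer_occurrences: int

    def __post_init__(self):
        if any(d < 1 or c < 0 for d, c in self.depth_counts.items()):
            raise ValueError("depths must be >= 1 and counts >= 0")
        conserved = sum(d * c for d, c in self.depth_counts.items())
        if conserved != self.total_kmer_occurrences:
            raise ValueError(
                "histogram mass does not match total occurrences: "
                f"{conserved} != {self.total_kmer_occurrences}"
            )


@dataclass(frozen=True)
class GenomeSizeEstimate:
    total_kmer_occurrences: int
    peak_depth: int
    size_bases: int

    @property
    def size_gb(self) -> float:
        """Size in Gb, rounded to 3 decimals for reporting."""
        return round_half_away(self.size_bases / 1e9, 3)


def _iter_fastq(path: str | Path) -> Iterable[str]:
    """Yield sequences from a FASTQ file (plain or gzip)."""
    path = Path(path)
    opener = gzip.open if path.suffix == ".gz" else open
    with opener(path, "rt") as fh:
        for i, line in enumerate(fh):
            if i % 4 == 1:
                yield line.strip()


def count_kmers(reads: str | Path | Iterable[str], k: int = DEFAULT_K) -> KmerHistogram:
    """Count canonical k-mers from reads and build the depth histogram.

    ``reads`` may be a FASTQ path (plain or ``.gz``) or any iterable of
    sequence strings. Windows containing non-ACGT characters are skipped;
    a read of length L contributes at most L - k + 1 windows.
    """
    if k % 2 == 0 or not 11 <= k <= 31:
        raise ValueError(f"k must be odd and in [11, 31], got {k}")
    if isinstance(reads, (str, Path)):
        reads = _iter_fastq(reads)

    # Concatenate reads with a single 'N' separator: every window crossing
    # a read boundary contains the separator and is discarded with the
    # other N-containing windows, so per-read window counts are exact.
    blob = "N".join(reads)
    if len(blob) < k:
        return KmerHistogram(k=k, depth_counts={}, total_kmer_occurrences=0)

    b = _BASE_CODE[np.frombuffer(blob.encode("ascii"), dtype=np.uint8)]
    invalid = (b < 0).astype(np.float64)
    base = np.where(b < 0, 0, b).astype(np.float64)

    # Rolling 2-bit encodings via correlation; 4**17 < 2**53 so float64
    # arithmetic is exact and castable back to int64.
    pow_fwd = 4.0 ** np.arange(k - 1, -1, -1)  # code of the forward k-mer
    pow_rev = 4.0 ** np.arange(k)  # weights of the reverse complement
    fwd = np.correlate(base, pow_fwd)
    rc = np.correlate(3.0 - base, pow_rev)
    n_bad = np.correlate(invalid, np.ones(k))
    valid = n_bad < 0.5

    canonical = np.minimum(fwd, rc)[valid].astype(np.int64)
    total = int(canonical.size)
    if total == 0:
        return KmerHistogram(k=k, depth_counts={}, total_kmer_occurrences=0)

    _, per_kmer_depth = np.unique(canonical, return_counts=True)
    depths, n_distinct = np.unique(per_kmer_depth, return_counts=True)
    depth_counts = {int(d): int(c) for d, c in zip(depths, n_distinct)}
    return KmerHistogram(k=k, depth_counts=depth_counts, total_kmer_occurrences=total)


def find_peak_depth(hist: KmerHistogram, min_depth: int = 3) -> int:
    """Depth of the main histogram peak, ignoring depths below ``min_depth``
    (the sequencing-error peak). Ties break toward the smaller depth."""
    best_depth, best_count = None, -1
    for depth in sorted(hist.depth_counts):
        if depth < min_depth:
            continue
        count = hist.depth_counts[depth]
        if count > best_count:
            best_depth, best_count = depth, count
    if best_depth is None or best_count <= 0:
        raise PeakNotFoundError(f"no histogram mass at depth >= {min_depth}")
    return best_depth


def size_from_totals(total_kmer_occurrences: int, peak_depth: int) -> GenomeSizeEstimate:
    """Genome size = total k-mer occurrences / peak depth, rounded to the
    nearest base. Takes the two survey totals directly."""
    if peak_depth < 1:
        raise ValueError(f"peak_depth must be >= 1, got {peak_depth}")
    size = int(round_half_away(total_kmer_occurrences / peak_depth))
    return GenomeSizeEstimate(
        total_kmer_occurrences=total_kmer_occurrences,
        peak_depth=peak_depth,
        size_bases=size,
    )


def estimate_genome_size(hist: KmerHistogram, peak_depth: int) -> GenomeSizeEstimate:
    """Genome-size estimate from a k-mer histogram at the given peak depth."""
    return size_from_totals(hist.total_kmer_occurrences, peak_depth)


def fold_coverage(total_sequenced_bases: float, genome_size: float) -> float:
    """Sequencing depth as total bases over genome size, to 2 decimals."""
    if genome_size <= 0:
        raise ValueError("genome_size must be positive")
    return round_half_away(total_sequenced_bases / genome_size, 2)


def profile_reads(
    reads: str | Path | Iterable[str], k: int = DEFAULT_K, min_depth: int = 3
) -> dict:
    """Convenience wrapper: histogram -> peak -> size estimate, as a report."""
    hist = count_kmers(reads, k=k)
    peak = find_peak_depth(hist, min_depth=min_depth)
    est = estimate_genome_size(hist, peak)
    return {
        "k": k,
        "total_kmer_occurrences": hist.total_kmer_occurrences,
        "peak_depth": peak,
        "size_bases": est.size_bases,
        "size_gb": est.size_gb,
        "histogram": hist,
    }
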