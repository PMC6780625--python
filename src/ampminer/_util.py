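"""Small shared helpers: rounding and sequence plumbing."""

from __future__ import annotations

from decimal import ROUND_HALF_UP, Decimal

_RC = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def revcomp(seq: str) -> str:
    """Reverse complement of a nucleotide string (N-safe)."""
    return seq.translate(_RC)[::-1]


def round_half_away(x: float, ndigits: int = 0) -> float:
    """Round half away from zero at ``ndigits`` decimals.

    Python's built-in ``round`` is banker's rounding; reported percentages
    and ratios here follow the half-away-from-zero convention instead so
    printed values at a given precision are reproducible.
    """
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))
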