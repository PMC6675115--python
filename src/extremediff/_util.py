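"""Small shared helpers."""

from __future__ import annotations

import re
from decimal import ROUND_HALF_UP, Decimal


def round_half_up(x: float, ndigits: int = 2) -> float:
    """Round with ties away from zero (table-printing convention).

    Python's built-in round() is banker's rounding; summary tables here
    use ordinary half-up rounding (e.g. 4,560,712.5 -> 4,560,713).
    """
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


_CHROM_NUM = re.compile(r"(\d+)")


def chrom_sort_key(chrom: str) -> tuple:
    """Natural ordering for chromosome names: chr2 before chr10, X after numbers."""
    parts = _CHROM_NUM.split(chrom)
    return tuple(int(p) if p.isdigit() else p for p in parts)
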