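"""Deterministic decimal rounding helpers.

Python's built-in ``round`` uses banker's rounding; the display conventions in
this package (one-decimal scores, whole-step interval bounds) need explicit,
documented behaviour instead.
"""

import math
from decimal import ROUND_HALF_UP, Decimal


def round_half_up(x: float, ndigits: int = 0) -> float:
    """Round ``x`` to ``ndigits`` decimals, ties away from zero-half upward.

    round_half_up(2.5) == 3.0, round_half_up(14.857, 1) == 14.9.
    """
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


def truncate_int(x: float) -> int:
    """Drop the fractional part (floor for the non-negative values used here)."""
    return math.floor(x)


def half_up_int(x: float) -> int:
    return int(round_half_up(x, 0))
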