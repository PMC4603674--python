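"""Half-up decimal rounding used for all reported tables.

Python's built-in ``round`` is banker's rounding; published tables in this
domain round half away from zero, so 0.875 prints as 0.88 at 2 decimals.
"""

from decimal import ROUND_HALF_UP, Decimal

__all__ = ["round_half_up"]


def round_half_up(value: float, ndigits: int = 2) -> float:
    """Round ``value`` to ``ndigits`` decimals, ties away from zero."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(float(value))).quantize(q, rounding=ROUND_HALF_UP))
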