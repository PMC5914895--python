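"""Half-up rounding used for all reported money and percent figures.

Python's built-in ``round`` is banker's rounding; reports here follow the
commercial convention (0.5 always rounds away from zero for positive
values), so a dedicated helper is used everywhere a number is printed.
Internal arithmetic stays at full float precision.
"""

from decimal import ROUND_HALF_UP, Decimal

__all__ = ["round_half_up"]


def round_half_up(x: float, ndigits: int = 0) -> float:
    """Round ``x`` to ``ndigits`` decimals, ties away from zero.

    >>> round_half_up(7492.5)
    7493.0
    >>> round_half_up(2.345, 2)
    2.35
    """
    exp = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(float(x))).quantize(exp, rounding=ROUND_HALF_UP))
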