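"""Decimal round-half-up, used for every reported percentage.

Vital-statistics tables round 71.85 to 71.9; Python's builtin ``round`` uses
round-half-even (71.8) and binary floats make the halfway case ambiguous.
Going through ``repr`` recovers the shortest decimal representation of the
float before quantizing, so values that are exact halves in decimal round up.
"""

from decimal import ROUND_HALF_UP, Decimal

__all__ = ["round_half_up"]


def round_half_up(x: float, ndigits: int = 1) -> float:
    """Round ``x`` to ``ndigits`` decimal places, halves away from zero.

    >>> round_half_up(71.85)
    71.9
    >>> round_half_up(88.29268, 0)
    88.0
    """
    quantum = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(float(x))).quantize(quantum, rounding=ROUND_HALF_UP))
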