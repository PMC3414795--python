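"""Half-up decimal rounding, matching how count-derived percentages are
conventionally printed in sequencing reports (13.07%, 55.41%, ...).

Python's built-in ``round`` is banker's rounding; these helpers round
half-way cases away from zero, and ``percent`` stays in exact rational
arithmetic until the final rounding so no float representation error can
flip a boundary case.
"""
from __future__ import annotations

from decimal import ROUND_HALF_UP, Decimal
from fractions import Fraction

__all__ = ["round_half_up", "percent"]


def round_half_up(value: float, decimals: int = 2) -> float:
    """Round a float to `decimals` places, ties away from zero."""
    quantum = Decimal(1).scaleb(-decimals)
    return float(Decimal(repr(float(value))).quantize(quantum, rounding=ROUND_HALF_UP))


def percent(numerator: int, denominator: int, decimals: int = 2) -> float:
    """100 * numerator / denominator, rounded half-up, computed exactly.

    Both arguments must be integers; the division and the tie-break are done
    with :class:`fractions.Fraction` so e.g. 14309/109489 -> 13.07 regardless
    of binary float rounding.
    """
    frac = Fraction(100 * numerator, denominator)
    scale = 10**decimals
    sign = 1 if frac >= 0 else -1
    shifted = abs(frac) * scale + Fraction(1, 2)
    return sign * (shifted.numerator // shifted.denominator) / scale
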