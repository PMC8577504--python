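"""Half-up decimal rounding used for every reported percentage."""

from __future__ import annotations

from decimal import ROUND_HALF_UP, Decimal


def round_half_up(value: float, ndigits: int = 2) -> float:
    """Round ``value`` to ``ndigits`` decimals with ties going away from zero.

    Python's built-in ``round`` uses banker's rounding; reported percentages
    instead follow the half-up convention (e.g. 0.125 -> 0.13 at 2 digits).
    """
    quantum = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(float(value))).quantize(quantum, rounding=ROUND_HALF_UP))


def percent(numerator: float, denominator: float, ndigits: int = 2) -> float | None:
    """``100 * numerator / denominator`` rounded half-up; None if undefined."""
    if denominator == 0:
        return None
    return round_half_up(100.0 * numerator / denominator, ndigits)
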