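"""Small shared numeric helpers."""

from __future__ import annotations

from decimal import ROUND_HALF_UP, Decimal


def round_half_up(value: float, ndigits: int = 1) -> float:
    """Round with ties away from zero, the convention used for reported
    percentages (e.g. 78.26 -> 78.3, 77.2727 -> 77.3).

    Python's built-in ``round`` is banker's rounding, which would report
    87.45 as 87.4; clinical reporting rounds half up.
    """
    quantum = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(value)).quantize(quantum, rounding=ROUND_HALF_UP))


def percent(numerator: float, denominator: float, ndigits: int = 1) -> float | None:
    """Percentage rounded half-up, or None when the denominator is zero
    (undefined, never reported as 0)."""
    if denominator == 0:
        return None
    return round_half_up(100.0 * numerator / denominator, ndigits)
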