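"""Small shared helpers: rounding and package-level errors."""

from __future__ import annotations

from decimal import ROUND_HALF_UP, Decimal


class HealthTrajError(Exception):
    """Base class for all errors raised by healthtraj."""


def round_half_away(x: float, ndigits: int = 0) -> float:
    """Round half away from zero (4.05 -> 4.1, -4.05 -> -4.1).

    Python's built-in ``round`` uses banker's rounding; percentage tables in
    clinical reporting conventionally round halves away from zero, so all
    user-facing percentages go through this helper.
    """
    q = Decimal(1).scaleb(-ndigits)
    d = Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP)
    return float(d)


def percent(numerator: float, denominator: float, ndigits: int = 1) -> float:
    """Percentage rounded half-away-from-zero to ``ndigits`` decimals."""
    return round_half_away(100.0 * numerator / denominator, ndigits)
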