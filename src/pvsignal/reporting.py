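"""Rounding rules and the human-readable study report.

All percentages in rendered reports are rounded half-away-from-zero at a
fixed number of decimals, so printed ratios can be recomputed exactly from
the underlying counts.
"""
from __future__ import annotations

from decimal import ROUND_HALF_UP, Decimal
from typing import Optional, Sequence


def round_half_away(x: float | int | Decimal, decimals: int = 2) -> float:
    """Round half away from zero (5 always rounds outward)."""
    q = Decimal(1).scaleb(-decimals)
    return float(Decimal(str(x)).quantize(q, rounding=ROUND_HALF_UP))


def percent(part: float | int, whole: float | int, decimals: int = 2) -> float:
    """100 * part / whole, rounded half away from zero.

    Integer inputs are divided exactly in decimal arithmetic before
    rounding, so printed percentages are reproducible from the counts.
    """
    if whole == 0:
        raise ZeroDivisionError("percentage of an empty denominator")
    value = Decimal(str(part)) * 100 / Decimal(str(whole))
    q = Decimal(1).scaleb(-decimals)
    return float(value.quantize(q, rounding=ROUND_HALF_UP))


def fmt_estimate(value: Optional[float], decimals: int = 2) -> str:
    """Two-decimal display value, or "NA" for an absent estimate."""
    if value is None:
        return "NA"
    return f"{round_half_away(value, decimals):.{decimals}f}"


def quartiles(values: Sequence[float]) -> tuple[float, float, float]:
    """(Q1, median, Q3) by linear interpolation on the sorted values."""
    xs = sorted(values)
    if not xs:
        raise ValueError("quartiles of an empty sequence")

    def q(p: float) -> float:
        h = (len(xs) - 1) * p
        lo = int(h)
        hi = min(lo + 1, len(xs) - 1)
        return xs[lo] + (h - lo) * (xs[hi] - xs[lo])

    return q(0.25), q(0.5), q(0.75)
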