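"""One-decimal truncation arithmetic shared by evaluation and analytics.

All percentages in this package are *truncated* (floored) to one decimal
place, never rounded: 91.17... prints as 91.1.  Computation is done on exact
rationals so that values lying exactly on a tenth are never floored past it
by floating-point noise.
"""

from __future__ import annotations

from fractions import Fraction
from math import floor
from numbers import Rational


def trunc1(value: float | Fraction) -> float:
    """Truncate ``value`` to one decimal place (toward zero for positives).

    Accepts floats or exact rationals; rationals are truncated exactly.
    """
    frac = Fraction(value) if isinstance(value, Rational) else Fraction(*value.as_integer_ratio())
    return floor(frac * 10) / 10


def percent(count: int, denominator: int) -> float:
    """``100 * count / denominator`` truncated to one decimal place.

    Raises ``ZeroDivisionError`` on a zero denominator: a percentage of an
    empty denominator is a caller error, not 0.0.
    """
    if denominator == 0:
        raise ZeroDivisionError("percentage over a zero denominator")
    return trunc1(Fraction(100 * count, denominator))


def percent_fraction(count: int, denominator: int) -> Fraction:
    """Exact (untruncated) percentage as a rational, for chained arithmetic."""
    if denominator == 0:
        raise ZeroDivisionError("percentage over a zero denominator")
    return Fraction(100 * count, denominator)
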