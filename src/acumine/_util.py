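"""Exact-rational presentation helpers.

All published statistics are ratios of small integers; they are carried as
:class:`fractions.Fraction` until the last moment and rounded half-up at
the displayed precision (the convention that maps 25/130 to 19.2% and an
exact lift of 1.0125 to 1.01).
"""

from __future__ import annotations

from decimal import ROUND_HALF_UP, Decimal, localcontext
from fractions import Fraction
from numbers import Rational


def round_half_up(value: Rational | float, ndigits: int = 2) -> float:
    """Round to ``ndigits`` decimals with ties away from zero."""
    if isinstance(value, Rational):
        with localcontext() as ctx:
            ctx.prec = 50
            dec = Decimal(int(value.numerator)) / Decimal(int(value.denominator))
    else:
        dec = Decimal(repr(value))
    quantum = Decimal(1).scaleb(-ndigits)
    return float(dec.quantize(quantum, rounding=ROUND_HALF_UP))


def pct(numerator: int, denominator: int, ndigits: int = 2) -> float:
    """``numerator/denominator`` as a percentage, rounded half-up."""
    if denominator == 0:
        raise ZeroDivisionError("percentage with zero denominator")
    return round_half_up(Fraction(numerator * 100, denominator), ndigits)
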