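"""Shared helpers: decimal half-up display rounding.

Python's built-in ``round`` is banker's rounding; printed values in cohort
reports use decimal half-up at a fixed precision, so all display rounding
goes through :func:`round_half_up`.
"""

from __future__ import annotations

from decimal import ROUND_HALF_UP, Decimal
from fractions import Fraction


def round_half_up(x: float | Fraction, ndigits: int = 0) -> float:
    """Round ``x`` to ``ndigits`` decimal places, ties away from zero.

    Fractions are divided in decimal arithmetic (28 significant digits) so
    the half-up decision is made on the exact decimal expansion rather than
    on a binary float.
    """
    if isinstance(x, Fraction):
        d = Decimal(x.numerator) / Decimal(x.denominator)
    else:
        d = Decimal(repr(float(x)))
    exp = Decimal(1).scaleb(-ndigits)
    return float(d.quantize(exp, rounding=ROUND_HALF_UP))


def format_fixed(x: float | Fraction, ndigits: int) -> str:
    """Half-up rounded fixed-point display string (e.g. ``0.00161``)."""
    return f"{round_half_up(x, ndigits):.{ndigits}f}"
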