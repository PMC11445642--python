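"""Exact euro arithmetic at cent precision.

All monetary quantities in the costing engine are held as an integer number
of cents, so sums and scalar multiples never accumulate binary floating
point drift.  Quantities that arise from non-integral arithmetic (pro-rata
pack pricing, per-minute staff rates) are quantized to the cent with
round-half-up, and euro *presentation* values (the whole-euro figures shown
in reports) are obtained with round-half-up as well — the convention that
reproduces standard printed costing tables from cent-precision inputs.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from fractions import Fraction
from typing import Union

__all__ = ["MoneyEUR", "ValidationError", "round_half_up_int"]

_CENT = Decimal("0.01")
_EURO = Decimal("1")

Numeric = Union[int, str, float, Decimal]


class ValidationError(ValueError):
    """An input violates a domain invariant; the message names the field."""


def round_half_up_int(value: Union[Decimal, Fraction, float]) -> int:
    """Round to the nearest integer, halves away from zero."""
    if isinstance(value, Fraction):
        value = Decimal(value.numerator) / Decimal(value.denominator)
    elif not isinstance(value, Decimal):
        value = Decimal(repr(value)) if isinstance(value, float) else Decimal(value)
    return int(value.quantize(_EURO, rounding=ROUND_HALF_UP))


@dataclass(frozen=True, order=True)
class MoneyEUR:
    """A euro amount stored as integer cents.

    Parameters
    ----------
    cents:
        The amount in euro cents.  ``MoneyEUR.parse("98.20")`` is the usual
        entry point for human-readable amounts.
    """

    cents: int

    # -- constructors ------------------------------------------------------
    @classmethod
    def parse(cls, value: Numeric) -> "MoneyEUR":
        """Build from a euro amount (string, Decimal, int or float).

        Floats are routed through ``repr`` so that literals like 98.20 mean
        what they say; amounts with sub-cent precision are rejected rather
        than silently rounded.
        """
        if isinstance(value, MoneyEUR):
            return value
        if isinstance(value, float):
            dec = Decimal(repr(value))
        else:
            dec = Decimal(value)
        cents = dec * 100
        if cents != cents.to_integral_value():
            raise ValidationError(f"amount {value!r} has sub-cent precision")
        return cls(int(cents))

    @classmethod
    def zero(cls) -> "MoneyEUR":
        return cls(0)

    # -- arithmetic --------------------------------------------------------
    def __add__(self, other: "MoneyEUR") -> "MoneyEUR":
        return MoneyEUR(self.cents + other.cents)

    def __sub__(self, other: "MoneyEUR") -> "MoneyEUR":
        return MoneyEUR(self.cents - other.cents)

    def __mul__(self, k: int) -> "MoneyEUR":
        if not isinstance(k, int):
            raise TypeError("MoneyEUR supports exact multiplication by int only; "
                            "use .times() for ratios")
        return MoneyEUR(self.cents * k)

    __rmul__ = __mul__

    def __neg__(self) -> "MoneyEUR":
        return MoneyEUR(-self.cents)

    def __bool__(self) -> bool:
        return self.cents != 0

    def times(self, ratio: Union[Fraction, Decimal, int]) -> "MoneyEUR":
        """Scale by an exact ratio, quantizing half-up to the cent."""
        if isinstance(ratio, Fraction):
            exact = Fraction(self.cents) * ratio
            dec = Decimal(exact.numerator) / Decimal(exact.denominator)
        else:
            dec = Decimal(self.cents) * Decimal(ratio)
        return MoneyEUR(int(dec.quantize(_EURO, rounding=ROUND_HALF_UP)))

    # -- views -------------------------------------------------------------
    @property
    def euros(self) -> Decimal:
        """Exact decimal euro value (cent precision)."""
        return Decimal(self.cents) / 100

    def present_euros(self) -> int:
        """Whole-euro presentation value, round-half-up."""
        return round_half_up_int(self.euros)

    def __str__(self) -> str:
        return f"€{self.euros:,.2f}"

    def __repr__(self) -> str:
        return f"MoneyEUR({self.euros:.2f})"


def msum(amounts) -> MoneyEUR:
    """Sum an iterable of MoneyEUR (empty sum is €0.00)."""
    total = 0
    for a in amounts:
        total += a.cents
    return MoneyEUR(total)
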