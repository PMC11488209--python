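"""Exact money arithmetic in integer cents (2022 CAD).

All monetary quantities inside the package are integer cents; floats enter
only in Monte Carlo sampling, where exactness is not meaningful. Rounding is
round-half-up at every published-figure boundary, matching how fee schedules
and economic-evaluation tables are conventionally displayed.
"""

from __future__ import annotations

from decimal import ROUND_HALF_UP, Decimal

Cents = int


def round_half_up(x: float, ndigits: int = 0) -> float:
    """Round with ties away from zero upward (not banker's rounding)."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


def to_cents(dollars: float | str | Decimal) -> Cents:
    """Convert a dollar amount to integer cents, round-half-up."""
    if isinstance(dollars, float):
        dollars = repr(dollars)
    return int(Decimal(dollars).scaleb(2).quantize(Decimal(1), rounding=ROUND_HALF_UP))


def cents_to_dollars(cents: Cents) -> float:
    return cents / 100.0


def format_cents(cents: Cents) -> str:
    """Fixed 2-decimal text, e.g. 3082 -> '30.82'."""
    sign = "-" if cents < 0 else ""
    c = abs(cents)
    return f"{sign}{c // 100}.{c % 100:02d}"


def format_dollars_whole(cents: Cents) -> str:
    """Whole-dollar display with thousands separators, e.g. 24441900 -> '244,419'."""
    return f"{int(round_half_up(cents / 100.0)):,}"
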