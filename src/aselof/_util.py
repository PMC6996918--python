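"""Small shared helpers."""

from __future__ import annotations

from decimal import Decimal, ROUND_HALF_UP


def round_half_up(value: float, ndigits: int = 1) -> float:
    """Round half away from zero to ``ndigits`` decimals (printed-table
    convention), unlike banker's rounding of the builtin ``round``."""
    q = Decimal(10) ** -ndigits
    return float(Decimal(repr(float(value))).quantize(q, rounding=ROUND_HALF_UP))
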