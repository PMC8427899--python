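"""Small shared helpers."""

from __future__ import annotations

from decimal import ROUND_HALF_UP, Decimal


def round_half_up(x: float, ndigits: int = 0) -> float:
    """Round with ties going away from zero, as printed lab reports do.

    Python's built-in ``round`` uses banker's rounding, which disagrees with
    hand-rounded tabulated values exactly at ties (e.g. 0.225 -> 0.22 instead
    of 0.23).
    """
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))
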