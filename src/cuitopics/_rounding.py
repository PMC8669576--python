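"""Round-half-away-from-zero helpers for printed percentages and ratios."""

from decimal import Decimal, ROUND_HALF_UP


def round_half_away(x: float, ndigits: int) -> float:
    """Round with ties going away from zero (the convention of printed tables).

    Python's built-in ``round`` is banker's rounding, which disagrees with
    how summary tables are conventionally printed (e.g. 14.95 -> 15.0).
    """
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))
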