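"""Half-up rounding used at every presentation boundary.

Internal arithmetic is never rounded; reports round proportions to 3 decimals
and means/SDs/percentages to 1 decimal, half-up (0.6445 -> 0.645), matching
the convention of clinical tables. Python's builtin ``round`` is banker's
rounding, hence this helper.
"""

from decimal import ROUND_HALF_UP, Decimal


def round_half_up(x: float, ndigits: int) -> float:
    """Round ``x`` to ``ndigits`` decimals, ties away from zero."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))
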