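"""Half-up decimal rounding for presentation of percentages and counts."""

from decimal import ROUND_HALF_UP, Decimal

__all__ = ["round_half_up"]


def round_half_up(x: float, ndigits: int = 0) -> float:
    """Round ``x`` to ``ndigits`` decimals with ties going away from zero.

    Python's built-in ``round`` uses banker's rounding; published tables in
    epidemiology round half up (34.5 -> 35), so displayed values go through
    this helper.  Only the shortest decimal representation of the float is
    considered, so 0.1-style binary artefacts do not flip ties.
    """
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))
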