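"""Shared helpers: deterministic rounding and text canonicalisation.

Rounding contract used throughout the result tables: prescribing ratios are
rounded half-up to 4 decimals, displayed rates and ranked risks half-up to
integers, combined-risk percentages half-up to 1 decimal.  Python's built-in
round() is banker's rounding, so everything goes through Decimal.
"""

from __future__ import annotations

import re
from decimal import Decimal, ROUND_HALF_UP


def round_half_up(x: float, ndigits: int = 0) -> float:
    """Round half away from zero at ``ndigits`` decimal places.

    Returns an ``int`` when ``ndigits == 0``.
    """
    quantum = Decimal(1).scaleb(-ndigits)
    d = x if isinstance(x, Decimal) else Decimal(repr(float(x)))
    out = d.quantize(quantum, rounding=ROUND_HALF_UP)
    return int(out) if ndigits == 0 else float(out)


_WS = re.compile(r"\s+")


def collapse_ws(s: str) -> str:
    """Case-fold, trim, and collapse internal whitespace runs to one space."""
    return _WS.sub(" ", s.casefold()).strip()
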