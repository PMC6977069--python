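"""Small shared helpers: percent rounding conventions."""

from __future__ import annotations

import math


def round_half_away(x: float, ndigits: int = 0) -> float:
    """Round half away from zero (unlike Python's banker's rounding)."""
    if math.isnan(x):
        return x
    factor = 10.0**ndigits
    return math.copysign(math.floor(abs(x) * factor + 0.5), x) / factor


def round_percent(fraction: float) -> float:
    """Convert a fraction to a percentage under the display convention.

    Percentages >= 10 are rounded half-away-from-zero to the nearest
    integer; percentages below 10 keep one decimal place.
    """
    pct = fraction * 100.0
    if math.isnan(pct):
        return pct
    if abs(pct) >= 10.0:
        return round_half_away(pct, 0)
    return round_half_away(pct, 1)
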