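"""Reporting helpers: count/percentage formatting conventions.

Percentages are rounded half-away-from-zero; values below 10% keep one
decimal place ("4.8%") while larger values are printed as integers
("36%"). Counts carry thousands separators.
"""

from __future__ import annotations

import math


def round_half_away(x: float, ndigits: int = 0) -> float | int:
    """Round with ties going away from zero (so 12.5 -> 13, -12.5 -> -13)."""
    scale = 10**ndigits
    y = math.floor(abs(x) * scale + 0.5) / scale * (1 if x >= 0 else -1)
    return int(y) if ndigits == 0 else y


def format_count(n: int) -> str:
    return f"{n:,}"


def format_percent(numerator: float, denominator: float) -> str:
    """Percentage string in the survey's mixed style.

    One decimal below 10% ("4.8%"), integer otherwise ("36%"); rounding is
    half-away-from-zero in both regimes.
    """
    if denominator == 0:
        return "n/a"
    pct = 100.0 * numerator / denominator
    if abs(pct) < 10.0:
        value = round_half_away(pct, 1)
        return f"{value:.1f}%"
    return f"{round_half_away(pct)}%"


def format_count_percent(numerator: int, denominator: int) -> str:
    """E.g. ``"23,988 (36%)"`` or ``"3,219 (4.8%)"``."""
    return f"{format_count(numerator)} ({format_percent(numerator, denominator)})"
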