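"""Display rounding for percentages in reports and summaries.

Underlying values are never rounded; these helpers produce the presentation
strings only.  Percentages at or above 2% are shown to the nearest integer
("81%", "4%"); smaller values keep one decimal so they do not vanish
("1.1%", "0.1%").  P-values below 1e-15 are clipped to "<1e-15".
"""

from __future__ import annotations

P_VALUE_FLOOR = 1e-15


def format_percent(value: float, decimals: int | None = None) -> str:
    """Format a percentage for display (no trailing '%' sign).

    ``decimals`` overrides the automatic rule (integer at >= 2%, one decimal
    below).
    """
    if decimals is None:
        decimals = 0 if value >= 2.0 else 1
    text = f"{value:.{decimals}f}"
    return text


def format_ci(low_pct: float, high_pct: float) -> str:
    """Format a confidence interval on the percent scale, e.g. '0.1% to 4%'."""
    return f"{format_percent(low_pct)}% to {format_percent(high_pct)}%"


def format_p_value(p: float) -> str:
    """Full precision above the floor; '<1e-15' below it."""
    if p < P_VALUE_FLOOR:
        return "<1e-15"
    return f"{p:.4g}"
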