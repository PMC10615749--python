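"""Small shared helpers: display rounding and Markdown tables."""

from __future__ import annotations

import math
from typing import Iterable, Sequence


def round_half_up(x: float, ndigits: int = 0) -> float:
    """Round with ties away from zero (the convention used for all
    displayed moments, cut-points and whole percents).

    Python's built-in ``round`` uses banker's rounding; printed tables in
    this domain round 0.5 up, so 86.205 -> 86.21 and 35.75% -> 36%.
    """
    if not math.isfinite(x):
        return x
    scale = 10.0 ** ndigits
    scaled = x * scale
    # nudge by a few ulps so values that are conceptually exact halves but
    # stored just below (e.g. 2.675 * 100 = 267.49999...) still round up
    nudge = math.copysign(abs(scaled) * 1e-12 + 1e-12, scaled)
    rounded = math.floor(abs(scaled + nudge) + 0.5) * math.copysign(1.0, scaled)
    out = rounded / scale
    return out if ndigits > 0 else float(int(out))


def whole_percent(count: float, total: float) -> int:
    """Half-up whole-percent share of ``count`` in ``total``."""
    if total <= 0:
        raise ValueError("total must be positive")
    return int(round_half_up(100.0 * count / total))


def markdown_table(header: Sequence[str], rows: Iterable[Sequence[object]]) -> str:
    """Render a GitHub-style Markdown table (no external dependency)."""
    head = "| " + " | ".join(str(h) for h in header) + " |"
    sep = "|" + "|".join(" --- " for _ in header) + "|"
    body = ["| " + " | ".join(str(c) for c in row) + " |" for row in rows]
    return "\n".join([head, sep, *body])
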