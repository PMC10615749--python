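"""Three-level severity assignment per composite and overall.

Each composite score is classified against a pair of cut-points as
normal/mild (score >= moderate cut), moderate (>= severe cut, < moderate
cut) or severe (< severe cut). A child's overall level is the worst level
over their non-missing composites; a child with no observed composite is
excluded from overall denominators.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from ._utils import whole_percent
from .exceptions import InsufficientDataError, ValidationError
from .reference_norms import COMPOSITES, SeverityBands

SCORE_MIN, SCORE_MAX = 40, 160


class SeverityLevel(enum.IntEnum):
    """Ordered impairment levels; higher value = more severe."""

    NORMAL_MILD = 0
    MODERATE = 1
    SEVERE = 2

    @property
    def label(self) -> str:
        return {0: "normal_mild", 1: "moderate", 2: "severe"}[int(self)]


#: distinguished marker for an unscored composite (never compares)
MISSING = None

LEVELS = (SeverityLevel.NORMAL_MILD, SeverityLevel.MODERATE, SeverityLevel.SEVERE)


def classify_composite(
    score: Optional[float], bands: SeverityBands
) -> Optional[SeverityLevel]:
    """Classify one composite score against a band pair.

    Returns None for a missing score. The normal/mild boundary is
    inclusive: a score exactly at the moderate cut is normal/mild.
    """
    if score is None or (isinstance(score, float) and np.isnan(score)):
        return MISSING
    if not SCORE_MIN <= score <= SCORE_MAX:
        raise ValidationError(
            f"score {score} outside the valid composite range "
            f"[{SCORE_MIN}, {SCORE_MAX}]"
        )
    if score >= bands.moderate_cut:
        return SeverityLevel.NORMAL_MILD
    if score >= bands.severe_cut:
        return SeverityLevel.MODERATE
    return SeverityLevel.SEVERE


def overall_level(
    levels: Sequence[Optional[SeverityLevel]],
) -> Optional[SeverityLevel]:
    """Worst severity across the non-missing per-composite levels.

    Returns None when every level is missing (the child is excluded from
    overall denominators).
    """
    observed = [lv for lv in levels if lv is not None]
    if not observed:
        return None
    return max(observed)


@dataclass(frozen=True)
class ClassificationTable:
    """Per-child severity levels under one band source.

    ``frame`` has one row per child with columns child_id, center_id,
    source, cognitive, language, motor, overall — level columns hold
    SeverityLevel or None.
    """

    source: str
    frame: pd.DataFrame

    def level_counts(self, column: str = "overall") -> dict[SeverityLevel, int]:
        """Counts per level among children observed for ``column``."""
        col = self.frame[column]
        observed = col[col.notna()]
        return {lv: int((observed == lv).sum()) for lv in LEVELS}

    def denominator(self, column: str = "overall") -> int:
        return int(self.frame[column].notna().sum())

    def dichotomized_counts(self, column: str = "overall") -> tuple[int, int]:
        """(normal/mild, moderate-or-severe) counts on the same denominator."""
        counts = self.level_counts(column)
        return (
            counts[SeverityLevel.NORMAL_MILD],
            counts[SeverityLevel.MODERATE] + counts[SeverityLevel.SEVERE],
        )


def level_percents(counts: Mapping[SeverityLevel, int] | Sequence[int]) -> list[int]:
    """Whole-percent shares (half-up) of level counts against their sum."""
    if isinstance(counts, Mapping):
        values = [counts[lv] for lv in LEVELS]
    else:
        values = list(counts)
    total = sum(values)
    if total <= 0:
        raise ValidationError("cannot compute percents of an empty table")
    return [whole_percent(v, total) for v in values]


def classify_cohort(
    records: "pd.DataFrame | Sequence",
    bands_by_composite: Mapping[str, SeverityBands],
    source: str,
) -> ClassificationTable:
    """Classify every child in a cohort under one band source.

    ``records`` is a DataFrame with child_id, center_id and the three
    composite columns (or a sequence of AssessmentRecord). Bands must be
    supplied for all three composites. Children with every composite
    missing keep a row but contribute to no denominator.
    """
    missing_bands = [c for c in COMPOSITES if c not in bands_by_composite]
    if missing_bands:
        raise ValidationError(f"bands missing for composites: {missing_bands}")

    if not isinstance(records, pd.DataFrame):
        from .cohort_synth import records_to_frame

        records = records_to_frame(records)
    if records.empty:
        raise InsufficientDataError("empty cohort: nothing to classify")

    rows = []
    for _, rec in records.iterrows():
        levels = {
            comp: classify_composite(
                None if pd.isna(rec[comp]) else float(rec[comp]),
                bands_by_composite[comp],
            )
            for comp in COMPOSITES
        }
        rows.append(
            {
                "child_id": rec["child_id"],
                "center_id": rec["center_id"],
                "source": source,
                **levels,
                "overall": overall_level([levels[c] for c in COMPOSITES]),
            }
        )
    frame = pd.DataFrame(rows, dtype=object)
    return ClassificationTable(source=source, frame=frame)


def summary_table(table: ClassificationTable) -> pd.DataFrame:
    """Counts and whole-percents per level, per composite and overall."""
    rows = []
    for column in (*COMPOSITES, "overall"):
        counts = table.level_counts(column)
        pcts = level_percents(counts)
        for lv, pct in zip(LEVELS, pcts):
            rows.append(
                {
                    "analysis": column,
                    "source": table.source,
                    "level": lv.label,
                    "n": counts[lv],
                    "percent": pct,
                    "denominator": table.denominator(column),
                }
            )
    return pd.DataFrame(rows)
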