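"""Demographic comparison tables: sample vs source population.

Recruiting a healthy term-reference sample two years after birth is prone
to selection: the achieved sample can differ from all term births at the
same hospitals on insurance, education, race/ethnicity. This module holds
the category-count tables for such comparisons and reproduces the rounded
whole-percent convention of printed tables, where each share is rounded
half-up against the printed column total and differences are taken on the
rounded shares (round-then-subtract).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import pandas as pd

from ._utils import markdown_table, round_half_up, whole_percent
from .exceptions import ValidationError


@dataclass(frozen=True)
class CategoryCountTable:
    """Counts per category for one variable in two columns.

    ``population_total`` / ``sample_total`` are the printed column Ns and
    may exceed the category sums (tables sometimes carry unknowns or
    reporting gaps); percentages are always taken against the totals.
    """

    variable: str
    categories: tuple[str, ...]
    population_counts: tuple[int, ...]
    sample_counts: tuple[int, ...]
    population_total: Optional[int] = None
    sample_total: Optional[int] = None

    def __post_init__(self) -> None:
        k = len(self.categories)
        if len(self.population_counts) != k or len(self.sample_counts) != k:
            raise ValidationError("count vectors must match the category labels")
        if any(c < 0 for c in self.population_counts + self.sample_counts):
            raise ValidationError("counts must be non-negative")
        object.__setattr__(
            self,
            "population_total",
            self.population_total
            if self.population_total is not None
            else sum(self.population_counts),
        )
        object.__setattr__(
            self,
            "sample_total",
            self.sample_total
            if self.sample_total is not None
            else sum(self.sample_counts),
        )
        if sum(self.population_counts) > self.population_total:
            raise ValidationError("population counts exceed the column total")
        if sum(self.sample_counts) > self.sample_total:
            raise ValidationError("sample counts exceed the column total")


def percent_table(table: CategoryCountTable) -> pd.DataFrame:
    """Whole-percent shares (half-up, against the printed column totals)."""
    if table.population_total <= 0 or table.sample_total <= 0:
        raise ValidationError("column totals must be positive")
    rows = []
    for cat, pop, smp in zip(
        table.categories, table.population_counts, table.sample_counts
    ):
        rows.append(
            {
                "variable": table.variable,
                "category": cat,
                "population_n": pop,
                "population_pct": whole_percent(pop, table.population_total),
                "sample_n": smp,
                "sample_pct": whole_percent(smp, table.sample_total),
            }
        )
    return pd.DataFrame(rows)


def percent_difference(
    table: CategoryCountTable, category: str, rounded: bool = True
) -> float:
    """Signed percentage-point gap (sample - population) for one category.

    By default the difference is taken between the whole-percent rounded
    shares (the convention of printed reports); ``rounded=False`` instead
    rounds the exact percentage difference, which can differ by a point.
    """
    if category not in table.categories:
        raise ValidationError(
            f"category {category!r} not present in variable {table.variable!r}"
        )
    i = table.categories.index(category)
    if rounded:
        return float(
            whole_percent(table.sample_counts[i], table.sample_total)
            - whole_percent(table.population_counts[i], table.population_total)
        )
    exact = 100.0 * (
        table.sample_counts[i] / table.sample_total
        - table.population_counts[i] / table.population_total
    )
    return round_half_up(exact)


def comparison_report(tables: Sequence[CategoryCountTable]) -> str:
    """Markdown report of all variables with rounded shares and deltas."""
    parts = []
    for t in tables:
        pct = percent_table(t)
        rows = [
            (
                r["category"],
                f"{r['population_n']} ({r['population_pct']})",
                f"{r['sample_n']} ({r['sample_pct']})",
                f"{r['sample_pct'] - r['population_pct']:+d}",
            )
            for _, r in pct.iterrows()
        ]
        parts.append(f"### {t.variable}\n")
        parts.append(
            markdown_table(
                [
                    "Category",
                    f"Population n (%) [N={t.population_total}]",
                    f"Sample n (%) [N={t.sample_total}]",
                    "Delta (pp)",
                ],
                rows,
            )
        )
        parts.append("")
    return "\n".join(parts)


def table_from_frame(frame: pd.DataFrame) -> list[CategoryCountTable]:
    """Build tables from a tidy CSV frame with columns variable, category,
    population_count, sample_count and optional *_total columns."""
    required = {"variable", "category", "population_count", "sample_count"}
    missing = required - set(frame.columns)
    if missing:
        raise ValidationError(f"count table missing columns: {sorted(missing)}")
    out = []
    for var, grp in frame.groupby("variable", sort=False):
        pop_total = (
            int(grp["population_total"].iloc[0])
            if "population_total" in grp and grp["population_total"].notna().any()
            else None
        )
        smp_total = (
            int(grp["sample_total"].iloc[0])
            if "sample_total" in grp and grp["sample_total"].notna().any()
            else None
        )
        out.append(
            CategoryCountTable(
                variable=str(var),
                categories=tuple(str(c) for c in grp["category"]),
                population_counts=tuple(int(c) for c in grp["population_count"]),
                sample_counts=tuple(int(c) for c in grp["sample_count"]),
                population_total=pop_total,
                sample_total=smp_total,
            )
        )
    return out
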