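"""Corpus-level reporting: frequency tables, attribute tables, yearly trends.

Every percentage is truncated to one decimal (the same convention as the
evaluation metrics) and always recomputes from an explicit count and
denominator carried alongside it — tables never print a percent whose
arithmetic cannot be checked from their own columns.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .corpus import AbstractRecord
from .lexicon import ClassificationSchema
from .normalize import HierarchyAssignment, StandardizedDesign
from .rounding import percent

__all__ = [
    "FrequencyTable",
    "TrendSeries",
    "tabulate_attributes",
    "tabulate_designs",
    "trend_by_year",
]


@dataclass
class FrequencyTable:
    """Counts with truncated percents of one explicit denominator."""

    rows: pd.DataFrame  # columns: label, group, count, percent
    denominator: int

    def to_csv(self, path) -> None:
        self.rows.to_csv(path, index=False)


@dataclass
class TrendSeries:
    """Per-year category counts and truncated proportions."""

    rows: pd.DataFrame  # columns: year, category, count, proportion
    excluded_years: list[int]

    def to_csv(self, path) -> None:
        self.rows.to_csv(path, index=False)


def tabulate_designs(
    designs: list[StandardizedDesign], denominator: int
) -> FrequencyTable:
    """Lower-level and high-level design frequencies over ``denominator``.

    ``denominator`` is the count percents are taken over (e.g. all corpus
    abstracts for the with-design share, or all with-design abstracts for
    node shares); it must not be smaller than the design list.
    """
    if denominator == 0:
        raise ValueError("zero denominator")
    if denominator < len(designs):
        raise ValueError("denominator smaller than the number of designs")
    rows = []
    high_counts: dict[str, int] = {}
    low_counts: dict[tuple[str, str], int] = {}
    for sd in designs:
        high_counts[sd.high_level] = high_counts.get(sd.high_level, 0) + 1
        label = sd.lower_level if sd.lower_level else "(unclassified)"
        key = (label, sd.high_level)
        low_counts[key] = low_counts.get(key, 0) + 1
    for node, count in sorted(high_counts.items(), key=lambda kv: (-kv[1], kv[0])):
        rows.append(
            {"label": node, "group": "high_level", "count": count,
             "percent": percent(count, denominator)}
        )
    for (label, node), count in sorted(
        low_counts.items(), key=lambda kv: (-kv[1], kv[0])
    ):
        rows.append(
            {"label": label, "group": node, "count": count,
             "percent": percent(count, denominator)}
        )
    columns = ["label", "group", "count", "percent"]
    return FrequencyTable(
        rows=pd.DataFrame(rows, columns=columns), denominator=denominator
    )


def tabulate_attributes(
    designs: list[StandardizedDesign], node: str, schema: ClassificationSchema
) -> FrequencyTable:
    """Attribute frequencies among ``node`` designs that carry >=1
    attribute; the denominator is the number of such designs."""
    if node not in schema.nodes:
        raise ValueError(f"unknown high-level node {node!r}")
    bearing = [sd for sd in designs if sd.high_level == node and sd.attributes]
    counts: dict[str, int] = {}
    for sd in bearing:
        for attr in sd.attributes:
            counts[attr] = counts.get(attr, 0) + 1
    denominator = len(bearing)
    rows = [
        {"label": attr, "group": node, "count": count,
         "percent": percent(count, denominator)}
        for attr, count in sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))
    ]
    columns = ["label", "group", "count", "percent"]
    return FrequencyTable(
        rows=pd.DataFrame(rows, columns=columns), denominator=denominator
    )


def trend_by_year(
    records: list[AbstractRecord],
    designs: list[StandardizedDesign],
    assignments: list[HierarchyAssignment],
    year_range: tuple[int, int] | None = None,
) -> TrendSeries:
    """Per-year article counts, extracted-design counts and tier
    proportions (tier proportions are over that year's extracted designs).

    Records outside ``year_range`` (or without a year) are excluded and
    reported in ``excluded_years``.
    """
    tier_by_pmid = {a.pmid: a.tier for a in assignments}
    year_by_pmid = {r.pmid: r.pub_year for r in records}
    excluded: set[int] = set()

    def in_range(year: int | None) -> bool:
        if year is None:
            return False
        if year_range and not (year_range[0] <= year <= year_range[1]):
            excluded.add(year)
            return False
        return True

    articles: dict[int, int] = {}
    for r in records:
        if in_range(r.pub_year):
            articles[r.pub_year] = articles.get(r.pub_year, 0) + 1
    per_year_tier: dict[int, dict[str, int]] = {}
    for sd in designs:
        year = year_by_pmid.get(sd.pmid)
        if not in_range(year):
            continue
        tier = tier_by_pmid.get(sd.pmid, "unmappable")
        per_year_tier.setdefault(year, {})[tier] = (
            per_year_tier.get(year, {}).get(tier, 0) + 1
        )
    rows = []
    for year in sorted(articles):
        tiers = per_year_tier.get(year, {})
        n_designs = sum(tiers.values())
        rows.append(
            {"year": year, "category": "articles", "count": articles[year],
             "proportion": 100.0}
        )
        rows.append(
            {"year": year, "category": "with_design", "count": n_designs,
             "proportion": percent(n_designs, articles[year])}
        )
        for tier, count in sorted(tiers.items()):
            rows.append(
                {"year": year, "category": tier, "count": count,
                 "proportion": percent(count, n_designs) if n_designs else 0.0}
            )
    columns = ["year", "category", "count", "proportion"]
    return TrendSeries(
        rows=pd.DataFrame(rows, columns=columns), excluded_years=sorted(excluded)
    )
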