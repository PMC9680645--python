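"""Retrospective life-chart mood ratings at monthly resolution.

The NIMH Life-Chart Method (LCM) rates mania and depression severity per
calendar month.  This module holds the chart container, point-in-time
severity lookup for labeling transactions, and episode-structure summaries
(an *episode* is a maximal run of consecutive months at the same non-none
severity).
"""

from __future__ import annotations

import csv
import enum
import warnings
from dataclasses import dataclass, field
from datetime import date
from pathlib import Path
from typing import Iterable, Iterator

from .errors import ConfigError, RangeError

__all__ = [
    "Severity",
    "MonthRating",
    "LifeChart",
    "EpisodeStats",
    "EpisodeSummary",
    "severity_at",
    "episode_summary",
    "case_study_lifechart",
    "read_lifechart_csv",
    "write_lifechart_csv",
]


class Severity(enum.Enum):
    """Mood-symptom severity rating, ordered none < mild < moderate < severe."""

    NONE = "none"
    MILD = "mild"
    MODERATE = "moderate"
    SEVERE = "severe"

    def __lt__(self, other: "Severity") -> bool:
        order = list(type(self))
        return order.index(self) < order.index(other)

    @property
    def symptomatic(self) -> bool:
        return self is not Severity.NONE


def month_floor(d: date) -> date:
    """First day of the month containing *d*."""
    return d.replace(day=1)


def next_month(m: date) -> date:
    if m.month == 12:
        return date(m.year + 1, 1, 1)
    return date(m.year, m.month + 1, 1)


def month_index(m: date) -> int:
    return m.year * 12 + (m.month - 1)


@dataclass(frozen=True)
class MonthRating:
    """One month's mania and depression ratings."""

    month: date  # first day of the month
    mania: Severity
    depression: Severity = Severity.NONE

    def __post_init__(self) -> None:
        if self.month.day != 1:
            object.__setattr__(self, "month", month_floor(self.month))


class LifeChart:
    """Contiguous, month-sorted sequence of :class:`MonthRating`.

    Parameters
    ----------
    ratings
        One rating per month.  Any order; sorted on construction.  Months
        must be contiguous and unique.
    """

    def __init__(self, ratings: Iterable[MonthRating]):
        rs = sorted(ratings, key=lambda r: r.month)
        if not rs:
            raise ConfigError("life chart must contain at least one month")
        months = [r.month for r in rs]
        if len(set(months)) != len(months):
            raise ConfigError("duplicate month rating in life chart")
        for a, b in zip(months, months[1:]):
            if next_month(a) != b:
                raise ConfigError(f"life chart months not contiguous: gap after {a:%Y-%m}")
        self.ratings: list[MonthRating] = rs

    @property
    def span(self) -> tuple[date, date]:
        """(first month, last month), both as first-of-month dates."""
        return self.ratings[0].month, self.ratings[-1].month

    def __len__(self) -> int:
        return len(self.ratings)

    def __iter__(self) -> Iterator[MonthRating]:
        return iter(self.ratings)

    def contains(self, d: date) -> bool:
        lo, hi = self.span
        return lo <= month_floor(d) <= hi

    def rating_for(self, d: date) -> MonthRating:
        m = month_floor(d)
        lo, _ = self.span
        idx = month_index(m) - month_index(lo)
        if not 0 <= idx < len(self.ratings):
            raise RangeError(f"date {d} outside life-chart span")
        return self.ratings[idx]


def severity_at(chart: LifeChart, d: date, policy: str = "strict") -> Severity:
    """Mania severity of the month containing *d*.

    ``policy='strict'`` raises :class:`RangeError` for out-of-span dates;
    ``policy='lenient'`` returns ``Severity.NONE`` with a warning.
    """
    if policy not in ("strict", "lenient"):
        raise ConfigError(f"unknown out-of-span policy {policy!r}")
    try:
        return chart.rating_for(d).mania
    except RangeError:
        if policy == "lenient":
            warnings.warn(f"date {d} outside life-chart span; labeled none", stacklevel=2)
            return Severity.NONE
        raise


@dataclass(frozen=True)
class EpisodeStats:
    episode_count: int
    total_months: int


@dataclass(frozen=True)
class EpisodeSummary:
    """Episode counts and month totals per non-none mania severity."""

    by_severity: dict[Severity, EpisodeStats] = field(default_factory=dict)

    def __getitem__(self, sev: Severity) -> EpisodeStats:
        return self.by_severity.get(sev, EpisodeStats(0, 0))


def episode_summary(chart: LifeChart, dimension: str = "mania") -> EpisodeSummary:
    """Run-length summary of the chart's episode structure.

    A severity change (including to/from none) breaks a run; adjacent months
    at different non-none severities therefore count as separate episodes.
    """
    levels = [getattr(r, dimension) for r in chart.ratings]
    counts: dict[Severity, int] = {}
    months: dict[Severity, int] = {}
    prev: Severity | None = None
    for lev in levels:
        if lev is not Severity.NONE:
            months[lev] = months.get(lev, 0) + 1
            if lev is not prev:
                counts[lev] = counts.get(lev, 0) + 1
        prev = lev
    return EpisodeSummary(
        {sev: EpisodeStats(counts[sev], months[sev]) for sev in counts}
    )


# The case-study chart: 24 months spanning 2017-2018 with two mild runs
# totaling 5 months and five moderate runs totaling 9 months, no depression.
# Run placement within the span is a fixed, documented choice (the aggregate
# structure is what analyses depend on); the episode tapers off in late 2018.
_CASE_STUDY_MANIA = [
    # 2017
    "none", "mild", "mild", "none", "moderate", "moderate",
    "none", "moderate", "moderate", "none", "moderate", "moderate",
    # 2018
    "none", "mild", "mild", "mild", "none", "moderate",
    "moderate", "none", "moderate", "none", "none", "none",
]


def case_study_lifechart() -> LifeChart:
    """Packaged 24-month case-study chart (2017-01 through 2018-12)."""
    start = date(2017, 1, 1)
    ratings = []
    m = start
    for sev in _CASE_STUDY_MANIA:
        ratings.append(MonthRating(m, Severity(sev)))
        m = next_month(m)
    return LifeChart(ratings)


def read_lifechart_csv(path: str | Path) -> LifeChart:
    """Read a chart CSV with columns month (YYYY-MM), mania, depression."""
    ratings = []
    with open(path, newline="") as fh:
        for row in csv.DictReader(fh):
            try:
                year, month = map(int, row["month"].split("-"))
                ratings.append(
                    MonthRating(
                        date(year, month, 1),
                        Severity(row["mania"].strip().lower()),
                        Severity(row.get("depression", "none").strip().lower()),
                    )
                )
            except (KeyError, ValueError) as exc:
                raise ConfigError(f"invalid life-chart row {row!r}: {exc}") from exc
    return LifeChart(ratings)


def write_lifechart_csv(chart: LifeChart, path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["month", "mania", "depression"])
        for r in chart:
            w.writerow([f"{r.month:%Y-%m}", r.mania.value, r.depression.value])
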