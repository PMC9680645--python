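"""Per-period frequency/volume series and the monthly credit-transaction share.

*Frequency* is the number of transactions in a period; *volume* is the sum
of normalized amounts.  Resampling zero-fills every calendar period in the
span (required downstream: the zero-expenditure-run interval scheme reads
empty days off the daily series).  Weekly bins anchor on Monday by default.
"""

from __future__ import annotations

import csv
import enum
import warnings
from dataclasses import dataclass
from datetime import date, timedelta
from pathlib import Path
from typing import Sequence

import pandas as pd

from .errors import ConfigError
from .ledger_ingest import Account
from .lifechart import LifeChart, Severity, month_floor, next_month, severity_at
from .preprocess import LabeledTransaction

__all__ = [
    "Grain",
    "FeaturePeriod",
    "CreditRatioPoint",
    "resample",
    "credit_ratio_monthly",
    "features_to_frame",
    "write_features_csv",
    "read_features_csv",
    "plot_feature_series",
]


class Grain(enum.Enum):
    DAILY = "daily"
    WEEKLY = "weekly"
    MONTHLY = "monthly"


@dataclass(frozen=True)
class FeaturePeriod:
    period_start: date
    grain: Grain
    frequency: int
    volume: float
    severity: Severity
    partial: bool = False  # period extends beyond the analysis span (censored)


@dataclass(frozen=True)
class CreditRatioPoint:
    month: date  # first day of month
    credit_pct: float  # percentage of transactions (by count) on credit


def _week_start(d: date, anchor: int) -> date:
    """Start of the week containing *d* for a week anchored on weekday *anchor*."""
    return d - timedelta(days=(d.weekday() - anchor) % 7)


def _period_severity(
    start: date, grain: Grain, chart: LifeChart | None, policy: str,
    span: tuple[date, date],
) -> Severity:
    if chart is None:
        return Severity.NONE
    if grain is Grain.DAILY or grain is Grain.MONTHLY:
        return severity_at(chart, start, policy=policy)
    # weekly: month containing the majority of the period's in-span days
    # (partial edge weeks are clipped to the span), ties to the earlier month
    lo, hi = span
    days = [
        d for d in (start + timedelta(days=i) for i in range(7)) if lo <= d <= hi
    ]
    counts: dict[date, int] = {}
    for d in days:
        m = month_floor(d)
        counts[m] = counts.get(m, 0) + 1
    best = max(sorted(counts), key=lambda m: counts[m])  # sorted → earlier wins ties
    return severity_at(chart, best, policy=policy)


def resample(
    txns: Sequence[LabeledTransaction],
    grain: Grain,
    chart: LifeChart | None = None,
    span: tuple[date, date] | None = None,
    week_anchor: int = 0,
    policy: str = "strict",
) -> list[FeaturePeriod]:
    """Aggregate transactions into contiguous zero-filled calendar periods.

    Parameters
    ----------
    txns
        Labeled, date-sortable transactions.
    grain
        Daily, weekly or monthly binning.  Weekly bins start on
        ``week_anchor`` (0 = Monday); edge periods may be partial.
    chart
        Source of period severity labels.  Daily and monthly periods take
        their month's rating; a weekly period spanning a month boundary
        takes the rating of the month holding the majority of its days.
        Without a chart every period is labeled none.
    span
        Inclusive date range to cover; defaults to the transactions' range.
    """
    if span is None:
        if not txns:
            return []
        dates = [t.date for t in txns]
        span = (min(dates), max(dates))
    lo, hi = span
    if lo > hi:
        raise ConfigError("span start after span end")

    if grain is Grain.DAILY:
        starts = pd.date_range(lo, hi, freq="D").date
        key = lambda d: d  # noqa: E731
    elif grain is Grain.WEEKLY:
        first = _week_start(lo, week_anchor)
        last = _week_start(hi, week_anchor)
        starts = pd.date_range(first, last, freq="7D").date
        key = lambda d: _week_start(d, week_anchor)  # noqa: E731
    else:
        starts = [d.date() for d in pd.date_range(month_floor(lo), month_floor(hi), freq="MS")]
        key = month_floor

    freq: dict[date, int] = {s: 0 for s in starts}
    vol: dict[date, float] = {s: 0.0 for s in starts}
    for t in txns:
        k = key(t.date)
        if k not in freq:
            raise ConfigError(f"transaction date {t.date} outside span {span}")
        freq[k] += 1
        vol[k] += t.norm_amount

    def _is_partial(s: date) -> bool:
        if grain is Grain.DAILY:
            return False
        end = s + timedelta(days=6) if grain is Grain.WEEKLY else (
            next_month(s) - timedelta(days=1)
        )
        return s < lo or end > hi

    return [
        FeaturePeriod(
            period_start=s,
            grain=grain,
            frequency=freq[s],
            volume=vol[s],
            severity=_period_severity(s, grain, chart, policy, (lo, hi)),
            partial=_is_partial(s),
        )
        for s in starts
    ]


def credit_ratio_monthly(txns: Sequence[LabeledTransaction]) -> list[CreditRatioPoint]:
    """Monthly percentage of transactions (by count) made on the credit account.

    Months inside the transaction span with zero transactions are omitted
    with a warning; ratios there are undefined.
    """
    if not txns:
        return []
    total: dict[date, int] = {}
    credit: dict[date, int] = {}
    for t in txns:
        m = month_floor(t.date)
        total[m] = total.get(m, 0) + 1
        credit[m] = credit.get(m, 0) + (1 if t.account is Account.CREDIT else 0)
    months = sorted(total)
    all_months = [d.date() for d in pd.date_range(months[0], months[-1], freq="MS")]
    empty = [m for m in all_months if m not in total]
    if empty:
        warnings.warn(
            f"{len(empty)} month(s) with zero transactions omitted from credit ratio",
            stacklevel=2,
        )
    return [
        CreditRatioPoint(month=m, credit_pct=100.0 * credit[m] / total[m])
        for m in months
    ]


def features_to_frame(periods: Sequence[FeaturePeriod]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "period_start": [p.period_start for p in periods],
            "frequency": [p.frequency for p in periods],
            "volume": [p.volume for p in periods],
            "severity": [p.severity.value for p in periods],
        }
    )


def write_features_csv(periods: Sequence[FeaturePeriod], path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["period_start", "frequency", "volume", "severity", "partial"])
        for p in periods:
            w.writerow([p.period_start.isoformat(), p.frequency, repr(p.volume),
                        p.severity.value, int(p.partial)])


def read_features_csv(path: str | Path, grain: Grain) -> list[FeaturePeriod]:
    out = []
    with open(path, newline="") as fh:
        for row in csv.DictReader(fh):
            out.append(
                FeaturePeriod(
                    period_start=date.fromisoformat(row["period_start"]),
                    grain=grain,
                    frequency=int(row["frequency"]),
                    volume=float(row["volume"]),
                    severity=Severity(row["severity"]),
                    partial=bool(int(row.get("partial", 0))),
                )
            )
    return out


_SEVERITY_SHADE = {
    Severity.MILD: "#b9e3b2",
    Severity.MODERATE: "#f4e3a1",
    Severity.SEVERE: "#f4b9a1",
}


def plot_feature_series(
    periods: Sequence[FeaturePeriod],
    endpoint: str = "frequency",
    ax=None,
    flagged: Sequence[date] = (),
):
    """Plot a feature series with severity bands shaded; returns the axes.

    Requires matplotlib (optional dependency).
    """
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(10, 3))
    xs = [p.period_start for p in periods]
    ys = [getattr(p, endpoint) for p in periods]
    ax.plot(xs, ys, lw=1, color="#33557a")
    for p in periods:
        shade = _SEVERITY_SHADE.get(p.severity)
        if shade:
            width = {"daily": 1, "weekly": 7, "monthly": 31}[p.grain.value]
            ax.axvspan(p.period_start, p.period_start + timedelta(days=width),
                       color=shade, alpha=0.5, lw=0)
    for d in flagged:
        ax.axvline(d, color="crimson", ls=":", lw=1)
    ax.set_ylabel(endpoint)
    return ax
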