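"""Burstiness of expenditure timing, B = (r - 1)/(r + 1) with r = sigma/tau.

r is the coefficient of variation of inter-event intervals: tau the mean,
sigma the (population) standard deviation.  B = -1 for perfectly regular
timing (sigma = 0), B = 0 for a memoryless (exponential) process, and
B -> 1 in the limit of extreme dispersion.

Two interval schemes are supported, both at day resolution (statements list
transactions by date only):

* scheme D — day differences between successive transactions (same-day
  pairs contribute zero-valued intervals);
* scheme C — lengths of maximal runs of consecutive days with zero
  expenditure, read off the zero-filled daily frequency series.

Both are computed overall and per symptomatic phase (transactions grouped
by the severity of their month, optionally with mild and moderate merged
into a single symptomatic phase).
"""

from __future__ import annotations

import csv
import enum
import math
from dataclasses import dataclass
from datetime import date
from pathlib import Path
from typing import Sequence

import numpy as np

from .errors import InsufficientDataError, UndefinedStatisticError
from .features import FeaturePeriod
from .lifechart import Severity
from .preprocess import LabeledTransaction

__all__ = [
    "Scheme",
    "IntervalSample",
    "BurstinessResult",
    "intervals_D",
    "intervals_C",
    "burstiness",
    "burstiness_by_phase",
    "write_burstiness_csv",
]


class Scheme(enum.Enum):
    D = "D"  # successive-transaction day differences
    C = "C"  # zero-expenditure run lengths


@dataclass(frozen=True)
class IntervalSample:
    scheme: Scheme
    intervals: tuple[float, ...]

    @property
    def n(self) -> int:
        return len(self.intervals)


@dataclass(frozen=True)
class BurstinessResult:
    """B statistic with its ingredients; ``defined`` is False when the
    phase had too few intervals (or tau = 0) to support the statistic."""

    scheme: Scheme
    phase: str  # 'none' / 'mild' / 'moderate' / 'symptomatic' / 'overall'
    n: int
    tau: float
    sigma: float
    r: float
    B: float
    defined: bool = True

    @classmethod
    def undefined(cls, scheme: Scheme, phase: str, n: int) -> "BurstinessResult":
        nan = float("nan")
        return cls(scheme=scheme, phase=phase, n=n, tau=nan, sigma=nan,
                   r=nan, B=nan, defined=False)


def intervals_D(dates: Sequence[date]) -> IntervalSample:
    """Successive day differences of a date-sorted transaction stream."""
    if len(dates) < 3:
        raise InsufficientDataError(
            f"scheme D needs at least 3 transactions (2 intervals), got {len(dates)}"
        )
    ds = sorted(dates)
    deltas = tuple(float((b - a).days) for a, b in zip(ds, ds[1:]))
    return IntervalSample(Scheme.D, deltas)


def intervals_C(
    daily: Sequence[FeaturePeriod], include_edges: bool = True
) -> IntervalSample:
    """Lengths of maximal zero-expenditure runs in a zero-filled daily series.

    ``include_edges=False`` drops zero-runs touching either end of the span
    (they are censored: the true gap extends beyond the observation window).
    """
    runs: list[int] = []
    current = 0
    touches_start = True
    edge_flags: list[bool] = []
    for p in daily:
        if p.frequency == 0:
            current += 1
        else:
            if current:
                runs.append(current)
                edge_flags.append(touches_start)
            current = 0
            touches_start = False
    if current:
        runs.append(current)
        edge_flags.append(True)  # touches the end
    if not include_edges:
        runs = [r for r, edge in zip(runs, edge_flags) if not edge]
    if len(runs) < 2:
        raise InsufficientDataError(
            f"scheme C needs at least 2 zero-expenditure runs, got {len(runs)}"
        )
    return IntervalSample(Scheme.C, tuple(float(r) for r in runs))


def burstiness(sample: IntervalSample, ddof: int = 0, phase: str = "overall") -> BurstinessResult:
    """Evaluate B = (r - 1)/(r + 1), r = sigma/tau, on an interval sample.

    sigma is the population (n-denominator) standard deviation by default;
    ``ddof=1`` switches to the sample form for sensitivity analysis.
    """
    if sample.n < 2:
        raise InsufficientDataError(f"need >= 2 intervals, got {sample.n}")
    x = np.asarray(sample.intervals, dtype=float)
    tau = float(x.mean())
    if tau == 0.0:
        raise UndefinedStatisticError("all intervals zero: tau = 0, r undefined")
    sigma = float(x.std(ddof=ddof))
    r = sigma / tau
    B = (r - 1.0) / (r + 1.0)
    return BurstinessResult(scheme=sample.scheme, phase=phase, n=sample.n,
                            tau=tau, sigma=sigma, r=r, B=B)


def burstiness_from_r(r: float) -> float:
    """B as a function of the coefficient of variation alone."""
    if r < 0:
        raise ValueError("r must be non-negative")
    if math.isinf(r):
        return 1.0
    return (r - 1.0) / (r + 1.0)


def _phase_of(severity: Severity, merge: bool) -> str:
    if merge:
        return "symptomatic" if severity.symptomatic else "none"
    return severity.value


def burstiness_by_phase(
    txns: Sequence[LabeledTransaction],
    daily: Sequence[FeaturePeriod],
    scheme: Scheme,
    merge: bool = False,
    ddof: int = 0,
    include_edges: bool = True,
) -> list[BurstinessResult]:
    """B per symptomatic phase plus the overall value.

    Scheme D groups the transaction stream by phase and computes intervals
    within each phase's own subsequence (cross-phase gaps are not assigned
    to either phase).  Scheme C does the analogous grouping on the daily
    series.  Phases with too few intervals yield results flagged undefined
    rather than raising.
    """
    phases = ["none", "symptomatic"] if merge else ["none", "mild", "moderate"]
    results: list[BurstinessResult] = []
    for phase in phases:
        try:
            if scheme is Scheme.D:
                dates = [t.date for t in txns if _phase_of(t.severity, merge) == phase]
                sample = intervals_D(dates)
            else:
                sub = [p for p in daily if _phase_of(p.severity, merge) == phase]
                sample = intervals_C(sub, include_edges=include_edges)
            results.append(burstiness(sample, ddof=ddof, phase=phase))
        except (InsufficientDataError, UndefinedStatisticError):
            results.append(BurstinessResult.undefined(scheme, phase, 0))
    try:
        if scheme is Scheme.D:
            sample = intervals_D([t.date for t in txns])
        else:
            sample = intervals_C(daily, include_edges=include_edges)
        results.append(burstiness(sample, ddof=ddof, phase="overall"))
    except (InsufficientDataError, UndefinedStatisticError):
        results.append(BurstinessResult.undefined(scheme, "overall", 0))
    return results


def write_burstiness_csv(results: Sequence[BurstinessResult], path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["scheme", "phase", "n", "tau", "sigma", "r", "B", "defined"])
        for res in results:
            w.writerow([res.scheme.value, res.phase, res.n, res.tau, res.sigma,
                        res.r, res.B, res.defined])
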