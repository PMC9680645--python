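"""Heteroscedasticity-robust comparison of feature means across phases.

Welch's one-way ANOVA and the Games-Howell post-hoc procedure are the
appropriate pair when group sizes are unbalanced and variances unequal —
exactly the situation for mood-phase groupings of daily spending features,
where symptomatic months are a minority of the span.  Both statistics are
implemented from their defining formulas; only the studentized-range and F
distribution tails come from scipy.

Welch's F for k groups with sizes n_i, means m_i, sample variances s_i^2:

    w_i = n_i / s_i^2,  W = sum w_i,  m_w = sum w_i m_i / W
    A = sum w_i (m_i - m_w)^2 / (k - 1)
    L = sum (1 - w_i/W)^2 / (n_i - 1)
    F = A / (1 + 2(k-2)/(k^2-1) L),   df1 = k-1,   df2 = (k^2-1) / (3L)

Games-Howell for a pair (i, j) uses the Welch-Satterthwaite df and refers
q = |m_i - m_j| / sqrt((s_i^2/n_i + s_j^2/n_j)/2) to the studentized-range
distribution with k groups.
"""

from __future__ import annotations

import csv
import itertools
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import DegenerateVarianceError, InsufficientDataError
from .features import FeaturePeriod
from .lifechart import Severity

__all__ = [
    "GroupSample",
    "WelchResult",
    "GamesHowellResult",
    "welch_anova",
    "games_howell",
    "phase_groups",
    "phase_summary",
    "write_inference_csv",
]


@dataclass(frozen=True)
class GroupSample:
    """One phase's observations with cached summary statistics."""

    label: str
    values: tuple[float, ...]
    n: int = field(init=False)
    mean: float = field(init=False)
    variance: float = field(init=False)  # sample (n-1) variance

    def __post_init__(self) -> None:
        x = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "n", x.size)
        object.__setattr__(self, "mean", float(x.mean()) if x.size else float("nan"))
        object.__setattr__(
            self, "variance", float(x.var(ddof=1)) if x.size >= 2 else float("nan")
        )


@dataclass(frozen=True)
class WelchResult:
    F: float
    df1: float
    df2: float
    p: float


@dataclass(frozen=True)
class GamesHowellResult:
    pair: tuple[str, str]
    mean_diff: float
    se: float
    df: float
    q: float
    ci_low: float
    ci_high: float
    p_adj: float


def _validate(groups: Sequence[GroupSample]) -> None:
    if len(groups) < 2:
        raise InsufficientDataError("need at least 2 groups")
    for g in groups:
        if g.n < 2:
            raise InsufficientDataError(f"group {g.label!r} has n={g.n} < 2")
        if g.variance == 0:
            raise DegenerateVarianceError(
                f"group {g.label!r} has zero variance; Welch weights undefined"
            )


def welch_anova(groups: Sequence[GroupSample]) -> WelchResult:
    """Welch's heteroscedastic one-way ANOVA across the given groups."""
    _validate(groups)
    k = len(groups)
    n = np.array([g.n for g in groups], dtype=float)
    m = np.array([g.mean for g in groups])
    v = np.array([g.variance for g in groups])
    w = n / v
    W = w.sum()
    mw = (w * m).sum() / W
    A = (w * (m - mw) ** 2).sum() / (k - 1)
    L = ((1 - w / W) ** 2 / (n - 1)).sum()
    F = A / (1 + 2 * (k - 2) / (k**2 - 1) * L)
    df1 = float(k - 1)
    df2 = (k**2 - 1) / (3 * L)
    p = float(stats.f.sf(F, df1, df2))
    return WelchResult(F=float(F), df1=df1, df2=float(df2), p=p)


def games_howell(
    groups: Sequence[GroupSample], alpha: float = 0.05
) -> list[GamesHowellResult]:
    """Games-Howell pairwise contrasts with studentized-range p-values and CIs."""
    _validate(groups)
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    k = len(groups)
    out = []
    for gi, gj in itertools.combinations(groups, 2):
        vi, vj = gi.variance / gi.n, gj.variance / gj.n
        diff = gi.mean - gj.mean
        se2 = vi + vj
        df = se2**2 / (vi**2 / (gi.n - 1) + vj**2 / (gj.n - 1))
        se_q = np.sqrt(se2 / 2.0)  # studentized-range scaling
        q = abs(diff) / se_q
        p = float(stats.studentized_range.sf(q, k, df))
        q_crit = float(stats.studentized_range.ppf(1 - alpha, k, df))
        half = q_crit * se_q
        out.append(
            GamesHowellResult(
                pair=(gi.label, gj.label),
                mean_diff=float(diff),
                se=float(np.sqrt(se2)),
                df=float(df),
                q=float(q),
                ci_low=float(diff - half),
                ci_high=float(diff + half),
                p_adj=min(p, 1.0),
            )
        )
    return out


def _phase_label(severity: Severity, merge: bool) -> str:
    if merge:
        return "symptomatic" if severity.symptomatic else "none"
    return severity.value


def phase_groups(
    periods: Sequence[FeaturePeriod], endpoint: str = "frequency", merge: bool = False
) -> list[GroupSample]:
    """Group a feature series by phase label, in none -> worse order.

    Phases absent from the series are omitted (a group needs observations).
    """
    order = ["none", "symptomatic"] if merge else [s.value for s in Severity]
    buckets: dict[str, list[float]] = {}
    for p in periods:
        buckets.setdefault(_phase_label(p.severity, merge), []).append(
            float(getattr(p, endpoint))
        )
    return [GroupSample(lab, tuple(buckets[lab])) for lab in order if lab in buckets]


def phase_summary(
    periods: Sequence[FeaturePeriod], merge: bool = False, decimals: int | None = 2
) -> pd.DataFrame:
    """Per-phase mean frequency and mean volume, one column per phase."""
    if not periods:
        raise InsufficientDataError("no feature periods")
    freq = {g.label: g.mean for g in phase_groups(periods, "frequency", merge)}
    vol = {g.label: g.mean for g in phase_groups(periods, "volume", merge)}
    table = pd.DataFrame([freq, vol], index=["frequency", "volume"])
    if decimals is not None:
        table = table.round(decimals)
    return table


def write_inference_csv(
    endpoint: str,
    grouping: str,
    welch: WelchResult,
    pairs: Sequence[GamesHowellResult],
    path: str | Path,
    append: bool = False,
) -> None:
    """Tidy results table: one omnibus row then one row per pairwise contrast."""
    mode = "a" if append else "w"
    write_header = not (append and Path(path).exists())
    with open(path, mode, newline="") as fh:
        w = csv.writer(fh)
        if write_header:
            w.writerow(["endpoint", "grouping", "row", "pair", "F_or_q", "df1", "df2",
                        "mean_diff", "ci_low", "ci_high", "p"])
        w.writerow([endpoint, grouping, "welch", "", welch.F, welch.df1, welch.df2,
                    "", "", "", welch.p])
        for r in pairs:
            w.writerow([endpoint, grouping, "games_howell", f"{r.pair[0]}|{r.pair[1]}",
                        r.q, 1, r.df, r.mean_diff, r.ci_low, r.ci_high, r.p_adj])
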