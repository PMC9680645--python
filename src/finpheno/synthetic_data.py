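"""Mood-episode-modulated synthetic ledgers, life charts and statement exports.

The generator emulates the study conditions every pipeline stage assumes:
a 24-month, two-account (checking + credit) personal ledger averaging
about five expenditures per day, with hypomanic episodes laid out as two
mild runs totaling five months and five moderate runs totaling nine
months.  Phase effects are multiplicative on the daily expenditure rate;
the default multipliers are the ratios of the case study's phase mean
daily frequencies (5.49/5.23 mild, 5.34/5.23 moderate), i.e. deliberately small,
near-null effects — tests that need a detectable signal inflate them
explicitly.  Amounts are log-normal (right-skewed positive spending);
the credit-account probability rises with severity to emulate the
credit-shift dynamic.

Two inter-event laws are available: ``poisson`` (memoryless daily counts;
at low rates the day-grain stream has burstiness near 0) and
``heavy_tailed`` (a renewal process with Lomax/Pareto-II inter-event
times whose tail parameter pushes day-grain burstiness into the positive
regime observed for real spending).

``write_statement_files`` emits one delimited export per month and can
inject the table-extraction artifacts the ingest parser must absorb
(continuation rows, in-file account-section markers); every profile
round-trips losslessly through the parser.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from datetime import date, timedelta
from decimal import Decimal, ROUND_HALF_EVEN
from pathlib import Path
from typing import Sequence

import numpy as np
import yaml

from .errors import ConfigError
from .ledger_ingest import Account, Direction, Ledger, StatementDialect, Transaction
from .lifechart import (
    LifeChart,
    MonthRating,
    Severity,
    case_study_lifechart,
    month_floor,
    next_month,
)

__all__ = [
    "SyntheticConfig",
    "GroundTruth",
    "generate_lifechart",
    "generate_ledger",
    "write_statement_files",
    "statement_dialect",
]

# Case-study phase mean daily frequencies used for rate calibration.
_FREQ_NONE = 5.23
_FREQ_MILD = 5.49
_FREQ_MODERATE = 5.34

_MERCHANTS = [
    "AMAZON MKTP US*{code} SEATTLE WA",
    "GROCERY OUTLET #{num}",
    "SHELL OIL {num} SPRINGFIELD",
    "STARBUCKS STORE {num}",
    "NETFLIX.COM SUBSCRIPTION RENEWAL {code}",
    "UBER TRIP {code} HELP.UBER.COM",
    "TARGET T-{num} SPRINGFIELD",
    "RESTAURANT DEPOT PURCHASE {num} DOWNTOWN BRANCH LOCATION",
    "ONLINE ELECTRONICS SUPERSTORE ORDER {code} EXPEDITED SHIPPING SERVICE",
    "PHARMACY {num} RX COPAY",
]


@dataclass(frozen=True)
class SyntheticConfig:
    """Study-condition parameters for the generator.

    Defaults encode the case-study conditions: 24 months starting 2017-01,
    base rate calibrated to the none-phase mean daily frequency, phase
    multipliers at the case-study ratios, credit probability increasing with
    severity.
    """

    start: date = date(2017, 1, 1)
    months: int = 24
    base_daily_rate: float = _FREQ_NONE
    phase_rate_multipliers: dict[Severity, float] = field(
        default_factory=lambda: {
            Severity.MILD: _FREQ_MILD / _FREQ_NONE,
            Severity.MODERATE: _FREQ_MODERATE / _FREQ_NONE,
        }
    )
    # per-phase log-normal amount law (meanlog, sdlog) in currency units
    amount_law: dict[Severity, tuple[float, float]] = field(
        default_factory=lambda: {
            Severity.NONE: (3.1, 1.0),
            Severity.MILD: (3.2, 1.0),
            Severity.MODERATE: (3.3, 1.1),
        }
    )
    credit_prob: dict[Severity, float] = field(
        default_factory=lambda: {
            Severity.NONE: 0.25,
            Severity.MILD: 0.35,
            Severity.MODERATE: 0.40,
        }
    )
    interval_law: str = "poisson"  # 'poisson' | 'heavy_tailed'
    tail_shape: float = 2.2  # Lomax shape alpha for heavy_tailed mode
    income_per_month: int = 2
    income_law: tuple[float, float] = (7.3, 0.25)  # lognormal meanlog, sdlog
    mild_runs: tuple[int, ...] = (2, 3)
    moderate_runs: tuple[int, ...] = (2, 2, 2, 2, 1)
    randomize_placement: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.months < 2:
            raise ConfigError("span must cover at least 2 months")
        if self.base_daily_rate < 0:
            raise ConfigError("base_daily_rate must be non-negative")
        for sev, p in self.credit_prob.items():
            if not 0 <= p <= 1:
                raise ConfigError(f"credit_prob[{sev.value}] outside [0, 1]")
        if self.interval_law not in ("poisson", "heavy_tailed"):
            raise ConfigError(f"unknown interval_law {self.interval_law!r}")
        if self.interval_law == "heavy_tailed" and self.tail_shape <= 2:
            raise ConfigError("tail_shape must exceed 2 (finite variance)")
        if sum(self.mild_runs) + sum(self.moderate_runs) + max(
            len(self.mild_runs) + len(self.moderate_runs) - 1, 0
        ) > self.months:
            raise ConfigError("episode runs (with separators) exceed the span")

    @classmethod
    def from_yaml(cls, path: str | Path, seed: int | None = None) -> "SyntheticConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "start" in raw and isinstance(raw["start"], str):
            raw["start"] = date.fromisoformat(raw["start"])
        for key in ("phase_rate_multipliers", "amount_law", "credit_prob"):
            if key in raw:
                raw[key] = {Severity(k): v for k, v in raw[key].items()}
        for key in ("mild_runs", "moderate_runs", "income_law"):
            if key in raw:
                raw[key] = tuple(raw[key])
        if "amount_law" in raw:
            raw["amount_law"] = {k: tuple(v) for k, v in raw["amount_law"].items()}
        if seed is not None:
            raw["seed"] = seed
        return cls(**raw)


@dataclass
class GroundTruth:
    """Bookkeeping emitted alongside the ledger for recovery tests."""

    txn_phases: list[Severity]  # per expenditure transaction, ledger order
    daily_rate: np.ndarray  # true expenditure rate per day of span
    episode_windows: list[tuple[date, date, Severity]]  # inclusive month windows
    n_expenditure: int
    n_income: int
    counts_by_phase: dict[Severity, int]
    counts_by_account: dict[Account, int]


def _default_chart(config: SyntheticConfig) -> LifeChart:
    if (
        config.start == date(2017, 1, 1)
        and config.months == 24
        and sorted(config.mild_runs) == [2, 3]
        and sorted(config.moderate_runs) == [1, 2, 2, 2, 2]
    ):
        return case_study_lifechart()
    # generic deterministic layout: alternate runs separated by single none
    # months, placed from the second month onward
    sev_runs = [(Severity.MILD, r) for r in config.mild_runs] + [
        (Severity.MODERATE, r) for r in config.moderate_runs
    ]
    sev_runs.sort(key=lambda t: -t[1])
    levels = [Severity.NONE] * config.months
    pos = 1
    for sev, run in sev_runs:
        if pos + run > config.months:
            raise ConfigError("cannot place episode runs in span")
        for i in range(run):
            levels[pos + i] = sev
        pos += run + 1
    return _chart_from_levels(config.start, levels)


def _chart_from_levels(start: date, levels: Sequence[Severity]) -> LifeChart:
    ratings, m = [], month_floor(start)
    for lev in levels:
        ratings.append(MonthRating(m, lev))
        m = next_month(m)
    return LifeChart(ratings)


def generate_lifechart(
    config: SyntheticConfig, rng: np.random.Generator | None = None
) -> LifeChart:
    """Life chart with the configured episode aggregates.

    Default placement is the fixed packaged layout; with
    ``randomize_placement`` runs are placed uniformly at random subject to
    the constraint that runs of the same severity stay separated (so the
    episode counts and month totals are invariant across seeds).
    """
    if not config.randomize_placement:
        return _default_chart(config)
    rng = np.random.default_rng(config.seed) if rng is None else rng
    blocks = [(Severity.MILD, r) for r in config.mild_runs] + [
        (Severity.MODERATE, r) for r in config.moderate_runs
    ]
    n_none = config.months - sum(r for _, r in blocks)
    if n_none < 0:
        raise ConfigError("episode months exceed span")
    for _ in range(10_000):
        order = list(rng.permutation(len(blocks)))
        # distribute the none months into len(blocks)+1 gaps
        cuts = np.sort(rng.integers(0, n_none + 1, size=len(blocks)))
        gaps = np.diff(np.concatenate([[0], cuts, [n_none]]))
        levels: list[Severity] = []
        ok = True
        prev_sev: Severity | None = None
        for gap, bi in zip(gaps, order):
            levels.extend([Severity.NONE] * int(gap))
            sev, run = blocks[bi]
            if gap == 0 and prev_sev is sev:
                ok = False
                break
            levels.extend([sev] * run)
            prev_sev = sev
        if not ok:
            continue
        levels.extend([Severity.NONE] * int(gaps[-1]))
        return _chart_from_levels(config.start, levels)
    raise ConfigError("could not place episode runs without merging same-severity runs")


def _span_days(chart: LifeChart) -> list[date]:
    lo, hi_month = chart.span
    hi = next_month(hi_month) - timedelta(days=1)
    return [lo + timedelta(days=i) for i in range((hi - lo).days + 1)]


def _daily_counts(
    rates: np.ndarray, config: SyntheticConfig, rng: np.random.Generator
) -> np.ndarray:
    if config.interval_law == "poisson":
        return rng.poisson(rates)
    # heavy-tailed renewal: Lomax inter-event times with mean matched to the
    # local rate; event times accumulated in continuous days then floored
    counts = np.zeros(rates.size, dtype=int)
    alpha = config.tail_shape
    t = 0.0
    horizon = float(rates.size)
    while True:
        day = min(int(t), rates.size - 1)
        rate = rates[day]
        if rate <= 0:
            # skip ahead to the next active day
            nxt = np.nonzero(rates[day + 1:] > 0)[0]
            if nxt.size == 0:
                break
            t = float(day + 1 + nxt[0])
            continue
        scale = (alpha - 1.0) / rate  # Lomax mean = scale/(alpha-1) = 1/rate
        dt = scale * (np.power(1.0 - rng.random(), -1.0 / alpha) - 1.0)
        t += dt
        if t >= horizon:
            break
        counts[int(t)] += 1
    return counts


def _amount(meanlog: float, sdlog: float, rng: np.random.Generator) -> Decimal:
    raw = float(rng.lognormal(meanlog, sdlog))
    cents = Decimal(str(round(max(raw, 0.01), 2))).quantize(
        Decimal("0.01"), rounding=ROUND_HALF_EVEN
    )
    return cents if cents > 0 else Decimal("0.01")


def _description(rng: np.random.Generator) -> str:
    tpl = _MERCHANTS[int(rng.integers(len(_MERCHANTS)))]
    return tpl.format(
        code="".join(rng.choice(list("ABCDEFGHJKMNPQRSTUVWXYZ23456789"), size=6)),
        num=int(rng.integers(100, 9999)),
    )


def generate_ledger(
    chart: LifeChart, config: SyntheticConfig
) -> tuple[Ledger, GroundTruth]:
    """Draw a phase-modulated transaction ledger over the chart's span."""
    rng = np.random.default_rng(config.seed)
    days = _span_days(chart)
    sev_by_day = [chart.rating_for(d).mania for d in days]
    mult = np.array(
        [config.phase_rate_multipliers.get(s, 1.0) for s in sev_by_day]
    )
    rates = config.base_daily_rate * mult
    counts = _daily_counts(rates, config, rng)

    txns: list[Transaction] = []
    phases: list[Severity] = []
    counts_by_phase: dict[Severity, int] = {}
    counts_by_account: dict[Account, int] = {Account.CHECKING: 0, Account.CREDIT: 0}
    for day, sev, k in zip(days, sev_by_day, counts):
        meanlog, sdlog = config.amount_law.get(sev, config.amount_law[Severity.NONE])
        p_credit = config.credit_prob.get(sev, config.credit_prob[Severity.NONE])
        for _ in range(int(k)):
            account = Account.CREDIT if rng.random() < p_credit else Account.CHECKING
            txns.append(
                Transaction(
                    date=day,
                    description=_description(rng),
                    amount=_amount(meanlog, sdlog, rng),
                    account=account,
                    direction=Direction.EXPENDITURE,
                )
            )
            phases.append(sev)
            counts_by_phase[sev] = counts_by_phase.get(sev, 0) + 1
            counts_by_account[account] += 1

    n_income = 0
    m = chart.span[0]
    im, isd = config.income_law
    for _ in range(len(chart)):
        month_days = [d for d in days if month_floor(d) == m]
        for _ in range(config.income_per_month):
            day = month_days[int(rng.integers(len(month_days)))]
            txns.append(
                Transaction(
                    date=day,
                    description=f"DIRECT DEPOSIT PAYROLL {int(rng.integers(10**6, 10**7))}",
                    amount=_amount(im, isd, rng),
                    account=Account.CHECKING,
                    direction=Direction.INCOME,
                )
            )
            n_income += 1
        m = next_month(m)

    # episode windows (inclusive month ranges) from the chart
    windows: list[tuple[date, date, Severity]] = []
    run_start: date | None = None
    prev = Severity.NONE
    for r in chart:
        if r.mania is not prev:
            if prev is not Severity.NONE and run_start is not None:
                windows.append((run_start, r.month - timedelta(days=1), prev))
            run_start = r.month if r.mania is not Severity.NONE else None
            prev = r.mania
    if prev is not Severity.NONE and run_start is not None:
        end = next_month(chart.span[1]) - timedelta(days=1)
        windows.append((run_start, end, prev))

    ledger = Ledger(tuple(txns))
    truth = GroundTruth(
        txn_phases=phases,
        daily_rate=rates,
        episode_windows=windows,
        n_expenditure=len(phases),
        n_income=n_income,
        counts_by_phase=counts_by_phase,
        counts_by_account=counts_by_account,
    )
    return ledger, truth


def statement_dialect() -> StatementDialect:
    """Dialect matching the exports produced by :func:`write_statement_files`."""
    return StatementDialect(
        date_col=0,
        description_col=1,
        amount_col=2,
        date_format="%Y-%m-%d",
        account_marker=r"^ACCOUNT:\s*(?P<account>\w+)",
        sign_convention="negative_expenditure",
    )


def _split_description(desc: str, width: int = 24) -> list[str]:
    """Greedy word-wrap preserving single spaces, for continuation rows."""
    words = desc.split(" ")
    chunks: list[str] = []
    current = ""
    for w in words:
        if current and len(current) + 1 + len(w) > width:
            chunks.append(current)
            current = w
        else:
            current = f"{current} {w}" if current else w
    if current:
        chunks.append(current)
    return chunks


def write_statement_files(
    ledger: Ledger, out_dir: str | Path, quirk_profile: str = "camelot"
) -> list[Path]:
    """Emit one delimited statement export per calendar month.

    ``quirk_profile='none'`` writes plain one-row-per-transaction files
    (account-section markers only); ``'camelot'`` additionally wraps long
    descriptions onto continuation rows, reproducing table-extraction
    layout artifacts.  Every profile parses back to the originating
    transactions exactly.
    """
    if quirk_profile not in ("none", "camelot"):
        raise ConfigError(f"unknown quirk profile {quirk_profile!r}")
    if not len(ledger):
        raise ConfigError("cannot write statements for an empty ledger")
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    by_month: dict[date, list[Transaction]] = {}
    for t in ledger:
        by_month.setdefault(month_floor(t.date), []).append(t)
    paths = []
    for m in sorted(by_month):
        path = out / f"statement_{m:%Y_%m}.csv"
        lines: list[str] = []
        month_txns = by_month[m]
        for account in (Account.CHECKING, Account.CREDIT):
            acct_txns = [t for t in month_txns if t.account is account]
            if not acct_txns:
                continue
            lines.append(f"ACCOUNT: {account.value.upper()},,")
            for t in acct_txns:
                sign = -1 if t.direction is Direction.EXPENDITURE else 1
                amount = str(sign * t.amount)
                desc = t.description
                if quirk_profile == "camelot" and len(desc) > 24:
                    first, *rest = _split_description(desc)
                    lines.append(f"{t.date.isoformat()},{_q(first)},{amount}")
                    for chunk in rest:
                        lines.append(f",{_q(chunk)},")
                else:
                    lines.append(f"{t.date.isoformat()},{_q(desc)},{amount}")
        path.write_text("\n".join(lines) + "\n")
        paths.append(path)
    return paths


def _q(cell: str) -> str:
    if "," in cell or '"' in cell:
        return '"' + cell.replace('"', '""') + '"'
    return cell


def write_ground_truth_json(truth: GroundTruth, path: str | Path) -> None:
    import json

    payload = {
        "n_expenditure": truth.n_expenditure,
        "n_income": truth.n_income,
        "counts_by_phase": {s.value: c for s, c in truth.counts_by_phase.items()},
        "counts_by_account": {a.value: c for a, c in truth.counts_by_account.items()},
        "episode_windows": [
            [a.isoformat(), b.isoformat(), s.value] for a, b, s in truth.episode_windows
        ],
        "txn_phases": [s.value for s in truth.txn_phases],
        "daily_rate": [float(r) for r in truth.daily_rate],
    }
    with open(path, "w") as fh:
        json.dump(payload, fh)
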