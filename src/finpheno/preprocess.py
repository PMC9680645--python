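"""Privacy-preserving transform and severity labeling of a ledger.

The transform drops everything that could identify the account holder:
income rows are excluded, free-text descriptions removed, and amounts
min-max rescaled to [0, 1] independently per account so no raw monetary
value survives.  The labeled output attaches each transaction's month-level
mania severity from the life chart, plus the merged binary
(none/symptomatic) label used by the two-group analyses.
"""

from __future__ import annotations

import csv
import logging
import warnings
from dataclasses import dataclass, replace
from datetime import date
from pathlib import Path
from typing import Sequence

from .errors import ConfigError
from .ledger_ingest import Account, Direction, Ledger
from .lifechart import LifeChart, Severity, severity_at

__all__ = [
    "NormalizedTransaction",
    "NormalizedLedger",
    "LabeledTransaction",
    "filter_expenditure",
    "strip_descriptions",
    "normalize_amounts",
    "label_ledger",
    "preprocess_ledger",
    "write_labeled_csv",
    "read_labeled_csv",
]

log = logging.getLogger(__name__)

LABELED_SCHEMA_VERSION = 1


@dataclass(frozen=True)
class NormalizedTransaction:
    """A transaction after per-account min-max rescaling (amount in [0, 1])."""

    date: date
    description: str
    amount: float
    account: Account
    direction: Direction


@dataclass(frozen=True)
class NormalizedLedger:
    transactions: tuple[NormalizedTransaction, ...]

    def __post_init__(self) -> None:
        txns = tuple(sorted(self.transactions, key=lambda t: t.date))
        object.__setattr__(self, "transactions", txns)

    @property
    def span(self) -> tuple[date, date]:
        if not self.transactions:
            raise ValueError("empty ledger has no span")
        return self.transactions[0].date, self.transactions[-1].date

    def __len__(self) -> int:
        return len(self.transactions)

    def __iter__(self):
        return iter(self.transactions)


@dataclass(frozen=True)
class LabeledTransaction:
    """Final analysis record: date, account, normalized amount, severity."""

    date: date
    account: Account
    norm_amount: float
    severity: Severity

    @property
    def severity_merged(self) -> str:
        """Binary phase label: 'symptomatic' iff severity is not none."""
        return "symptomatic" if self.severity.symptomatic else "none"


def filter_expenditure(ledger: Ledger) -> Ledger:
    """Keep expenditure transactions only; income rows are excluded."""
    kept = tuple(t for t in ledger if t.direction is Direction.EXPENDITURE)
    removed = len(ledger) - len(kept)
    log.info("filter_expenditure: removed %d income transactions", removed)
    if not kept:
        warnings.warn("ledger contains no expenditure transactions", stacklevel=2)
    return Ledger(kept)


def strip_descriptions(ledger: Ledger) -> Ledger:
    """Blank every transaction description; no other field is touched."""
    return Ledger(tuple(replace(t, description="") for t in ledger))


def normalize_amounts(
    ledger: Ledger | NormalizedLedger, method: str = "minmax"
) -> NormalizedLedger:
    """Rescale amounts to [0, 1] independently per account.

    ``method='minmax'`` maps each account's minimum to 0 and maximum to 1:
    x' = (x - min) / (max - min).  An account with a single distinct amount
    maps to 0 everywhere (with a warning).  ``method='divide_by_max'`` is
    the sensitivity-analysis alternative x' = x / max.
    """
    if method not in ("minmax", "divide_by_max"):
        raise ConfigError(f"unknown normalization method {method!r}")
    by_account: dict[Account, list[float]] = {}
    for t in ledger:
        by_account.setdefault(t.account, []).append(float(t.amount))
    bounds: dict[Account, tuple[float, float]] = {}
    for acct, values in by_account.items():
        lo, hi = min(values), max(values)
        if lo == hi:
            warnings.warn(
                f"account {acct.value!r} has a single distinct amount; "
                "normalized values all map to 0",
                stacklevel=2,
            )
        bounds[acct] = (lo, hi)
    out = []
    for t in ledger:
        lo, hi = bounds[t.account]
        x = float(t.amount)
        if method == "minmax":
            norm = 0.0 if hi == lo else (x - lo) / (hi - lo)
        else:
            norm = 0.0 if hi == 0 else x / hi
        out.append(
            NormalizedTransaction(
                date=t.date,
                description=t.description,
                amount=norm,
                account=t.account,
                direction=t.direction,
            )
        )
    return NormalizedLedger(tuple(out))


def label_ledger(
    ledger: NormalizedLedger, chart: LifeChart, policy: str = "strict"
) -> list[LabeledTransaction]:
    """Attach the life chart's month-level mania severity to each transaction."""
    return [
        LabeledTransaction(
            date=t.date,
            account=t.account,
            norm_amount=t.amount,
            severity=severity_at(chart, t.date, policy=policy),
        )
        for t in ledger
    ]


def preprocess_ledger(
    ledger: Ledger, chart: LifeChart, policy: str = "strict", method: str = "minmax"
) -> list[LabeledTransaction]:
    """Full privacy pipeline: filter -> strip -> normalize -> label."""
    return label_ledger(
        normalize_amounts(strip_descriptions(filter_expenditure(ledger)), method=method),
        chart,
        policy=policy,
    )


def write_labeled_csv(txns: Sequence[LabeledTransaction], path: str | Path) -> None:
    """Write the privacy-preserving labeled dataset (no descriptions, no raw amounts)."""
    with open(path, "w", newline="") as fh:
        fh.write(f"# finpheno labeled schema v{LABELED_SCHEMA_VERSION}\n")
        w = csv.writer(fh)
        w.writerow(["date", "account", "norm_amount", "severity"])
        for t in txns:
            w.writerow([t.date.isoformat(), t.account.value, repr(t.norm_amount), t.severity.value])


def read_labeled_csv(path: str | Path) -> list[LabeledTransaction]:
    txns = []
    with open(path, newline="") as fh:
        first = fh.readline()
        if not first.startswith("#"):
            fh.seek(0)
        for row in csv.DictReader(fh):
            txns.append(
                LabeledTransaction(
                    date=date.fromisoformat(row["date"]),
                    account=Account(row["account"]),
                    norm_amount=float(row["norm_amount"]),
                    severity=Severity(row["severity"]),
                )
            )
    return txns
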