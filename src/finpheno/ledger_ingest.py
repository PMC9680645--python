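"""Parse delimited bank-statement exports into a clean transaction ledger.

Statement exports produced by table extraction from digitized statements
carry three layout artifacts this parser must absorb: a single transaction
may span multiple physical rows (continuation rows), a single file may
contain sections for multiple accounts (marked by header rows), and one
account's history spans many monthly files.  The parser is driven by an
explicit :class:`StatementDialect`; nothing is guessed from locale.

Amounts are kept as exact :class:`decimal.Decimal` until the analysis
stages to avoid cent-level binary-float drift.
"""

from __future__ import annotations

import csv
import enum
import json
import logging
import re
from collections import Counter
from dataclasses import dataclass, field, replace
from datetime import date, datetime
from decimal import Decimal, InvalidOperation
from pathlib import Path
from typing import Iterable, Sequence

import yaml

from .errors import FormatError

__all__ = [
    "Account",
    "Direction",
    "RawStatementRow",
    "Transaction",
    "Ledger",
    "StatementDialect",
    "RowError",
    "ParseResult",
    "parse_statement_file",
    "assemble_ledger",
    "read_statement_csv",
    "read_ledger_csv",
    "write_ledger_csv",
    "write_ledger_jsonl",
]

log = logging.getLogger(__name__)


class Account(enum.Enum):
    CHECKING = "checking"
    CREDIT = "credit"


class Direction(enum.Enum):
    EXPENDITURE = "expenditure"
    INCOME = "income"


@dataclass(frozen=True)
class RawStatementRow:
    """One physical row of a statement export, before interpretation."""

    source_file: str
    row_index: int
    cells: tuple[str, ...]

    def __post_init__(self) -> None:
        if self.row_index < 0:
            raise ValueError("row_index must be non-negative")
        if len(self.cells) < 1:
            raise ValueError("row must have at least one cell")


@dataclass(frozen=True)
class Transaction:
    """A single dated, account-labeled monetary record.

    ``amount`` is a positive magnitude; ``direction`` carries the sign
    convention (expenditure vs income).
    """

    date: date
    description: str
    amount: Decimal
    account: Account
    direction: Direction

    def __post_init__(self) -> None:
        if self.amount == 0:
            raise ValueError("transaction amount must be non-zero")
        if self.amount < 0:
            raise ValueError("amount is a positive magnitude; use direction for sign")


@dataclass(frozen=True)
class Ledger:
    """Date-sorted transaction sequence with its inclusive date span."""

    transactions: tuple[Transaction, ...]

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
class StatementDialect:
    """Column mapping and parsing conventions for one export format.

    ``sign_convention`` states how expenditures are distinguished from
    income in the amount column: ``"negative_expenditure"`` (expenditures
    carry a minus sign) or ``"positive_expenditure"``.
    ``date_format`` is a strptime pattern; if it lacks a year directive,
    ``default_year`` must be set.
    """

    date_col: int = 0
    description_col: int = 1
    amount_col: int = 2
    date_format: str = "%Y-%m-%d"
    default_year: int | None = None
    account_marker: str = r"^ACCOUNT:\s*(?P<account>\w+)"
    default_account: Account | None = None
    sign_convention: str = "negative_expenditure"
    has_header: bool = False

    def __post_init__(self) -> None:
        if self.sign_convention not in ("negative_expenditure", "positive_expenditure"):
            raise FormatError(f"unknown sign convention {self.sign_convention!r}")
        if "%Y" not in self.date_format and "%y" not in self.date_format:
            if self.default_year is None:
                raise FormatError(
                    "date_format has no year directive; default_year is required"
                )

    @classmethod
    def from_yaml(cls, path: str | Path) -> "StatementDialect":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "default_account" in raw and raw["default_account"] is not None:
            raw["default_account"] = Account(raw["default_account"])
        return cls(**raw)

    def parse_date(self, text: str) -> date:
        fmt = self.date_format
        if "%Y" in fmt or "%y" in fmt:
            return datetime.strptime(text.strip(), fmt).date()
        d = datetime.strptime(text.strip(), fmt).date()
        return d.replace(year=self.default_year)


_AMOUNT_CLEAN = re.compile(r"[,$\s]")


def _parse_amount(text: str) -> Decimal:
    t = _AMOUNT_CLEAN.sub("", text)
    neg = False
    if t.startswith("(") and t.endswith(")"):
        t = t[1:-1]
        neg = True
    value = Decimal(t)
    return -value if neg else value


@dataclass(frozen=True)
class RowError:
    """A record-level parse failure: the offending row and the reason."""

    row: RawStatementRow
    reason: str


@dataclass
class ParseResult:
    """Transactions parsed from one statement file plus collected row errors."""

    transactions: list[Transaction]
    errors: list[RowError] = field(default_factory=list)
    n_logical_records: int = 0


def _cell(row: RawStatementRow, idx: int) -> str:
    return row.cells[idx].strip() if idx < len(row.cells) else ""


def parse_statement_file(
    rows: Sequence[RawStatementRow], dialect: StatementDialect
) -> ParseResult:
    """Interpret one statement file's rows under *dialect*.

    Continuation rows (empty date and amount cells, non-empty description)
    are appended to the preceding transaction's description.  Rows matching
    the account-marker pattern switch the account label for subsequent rows.
    A file containing transaction rows before any marker, with no dialect
    default account, is a fatal :class:`FormatError`; a row whose amount
    parses but whose date does not is collected as a :class:`RowError` and
    skipped.
    """
    marker = re.compile(dialect.account_marker)
    account = dialect.default_account
    result = ParseResult(transactions=[])
    body = rows[1:] if dialect.has_header and rows else rows

    for row in body:
        joined = " ".join(c.strip() for c in row.cells if c.strip())
        m = marker.match(joined)
        if m:
            try:
                account = Account(m.group("account").strip().lower())
            except ValueError as exc:
                raise FormatError(
                    f"{row.source_file}:{row.row_index}: unknown account "
                    f"label in marker row {joined!r}"
                ) from exc
            continue

        date_cell = _cell(row, dialect.date_col)
        desc_cell = _cell(row, dialect.description_col)
        amount_cell = _cell(row, dialect.amount_col)

        if not date_cell and not amount_cell:
            if not desc_cell:
                continue  # fully blank row
            # continuation row: extends the previous transaction's description
            if not result.transactions:
                result.errors.append(RowError(row, "continuation row with no preceding transaction"))
                result.n_logical_records += 1
                continue
            prev = result.transactions[-1]
            merged = (prev.description + " " + desc_cell).strip()
            result.transactions[-1] = replace(prev, description=merged)
            continue

        result.n_logical_records += 1
        if not date_cell or not amount_cell:
            result.errors.append(RowError(row, "row has only one of date/amount"))
            continue
        try:
            signed = _parse_amount(amount_cell)
        except InvalidOperation:
            result.errors.append(RowError(row, f"unparseable amount {amount_cell!r}"))
            continue
        try:
            when = dialect.parse_date(date_cell)
        except ValueError:
            result.errors.append(RowError(row, f"unparseable date {date_cell!r}"))
            continue
        if signed == 0:
            result.errors.append(RowError(row, "zero amount"))
            continue
        if account is None:
            raise FormatError(
                f"{row.source_file}:{row.row_index}: transaction row before any "
                "account marker and dialect has no default account"
            )
        if dialect.sign_convention == "negative_expenditure":
            direction = Direction.EXPENDITURE if signed < 0 else Direction.INCOME
        else:
            direction = Direction.EXPENDITURE if signed > 0 else Direction.INCOME
        result.transactions.append(
            Transaction(
                date=when,
                description=desc_cell,
                amount=abs(signed),
                account=account,
                direction=direction,
            )
        )
    return result


def _txn_key(t: Transaction) -> tuple:
    return (t.date, t.amount, t.account, t.direction, t.description)


def assemble_ledger(per_file_transactions: Iterable[Sequence[Transaction]]) -> Ledger:
    """Join per-file transaction lists into one globally date-sorted ledger.

    Identical rows appearing in more than one file (overlapping statement
    periods) are deduplicated by taking, per identical record, the maximum
    multiplicity seen in any single file — repeated identical purchases
    *within* one file are genuine and kept.
    """
    merged: Counter = Counter()
    order: dict[tuple, Transaction] = {}
    deduped = 0
    for file_txns in per_file_transactions:
        seen = Counter(_txn_key(t) for t in file_txns)
        for t in file_txns:
            order.setdefault(_txn_key(t), t)
        for key, count in seen.items():
            if merged[key] > 0:
                deduped += min(merged[key], count)
            merged[key] = max(merged[key], count)
    if deduped:
        log.warning("deduplicated %d identical rows across overlapping files", deduped)
    txns = [order[key] for key, count in merged.items() for _ in range(count)]
    return Ledger(tuple(txns))


def read_statement_csv(path: str | Path) -> list[RawStatementRow]:
    """Read one statement export as raw rows (no interpretation)."""
    path = Path(path)
    rows = []
    with open(path, newline="") as fh:
        for i, cells in enumerate(csv.reader(fh)):
            if not cells:
                cells = [""]
            rows.append(RawStatementRow(path.name, i, tuple(cells)))
    return rows


_LEDGER_COLUMNS = ["date", "account", "direction", "amount", "description"]


def write_ledger_csv(ledger: Ledger, path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(_LEDGER_COLUMNS)
        for t in ledger:
            w.writerow(
                [t.date.isoformat(), t.account.value, t.direction.value,
                 str(t.amount), t.description]
            )


def read_ledger_csv(path: str | Path) -> Ledger:
    txns = []
    with open(path, newline="") as fh:
        for row in csv.DictReader(fh):
            txns.append(
                Transaction(
                    date=date.fromisoformat(row["date"]),
                    description=row["description"],
                    amount=Decimal(row["amount"]),
                    account=Account(row["account"]),
                    direction=Direction(row["direction"]),
                )
            )
    return Ledger(tuple(txns))


def write_ledger_jsonl(ledger: Ledger, path: str | Path) -> None:
    with open(path, "w") as fh:
        for t in ledger:
            fh.write(json.dumps({
                "date": t.date.isoformat(),
                "account": t.account.value,
                "direction": t.direction.value,
                "amount": str(t.amount),
                "description": t.description,
            }) + "\n")
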