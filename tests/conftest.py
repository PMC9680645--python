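from datetime import date

import numpy as np
import pytest

from finpheno.ledger_ingest import Account, Direction, Ledger, Transaction
from finpheno.lifechart import case_study_lifechart
from finpheno.synthetic_data import SyntheticConfig, generate_ledger

from decimal import Decimal


@pytest.fixture(scope="session")
def chart():
    return case_study_lifechart()


@pytest.fixture(scope="session")
def default_config():
    return SyntheticConfig(seed=20170101)


@pytest.fixture(scope="session")
def synthetic(chart, default_config):
    """A default-condition synthetic ledger with its ground truth."""
    return generate_ledger(chart, default_config)


@pytest.fixture
def rng():
    return np.random.default_rng(0)


def make_txn(
    d=date(2017, 1, 15),
    description="COFFEE SHOP",
    amount="4.50",
    account=Account.CHECKING,
    direction=Direction.EXPENDITURE,
):
    return Transaction(
        date=d,
        description=description,
        amount=Decimal(amount),
        account=account,
        direction=direction,
    )


@pytest.fixture
def small_ledger():
    """Ten expenditures + three income rows across two accounts and months."""
    txns = []
    amounts = ["10.00", "20.00", "30.00", "5.00", "12.50", "7.25", "40.00",
               "3.10", "22.00", "15.75"]
    for i, a in enumerate(amounts):
        txns.append(
            make_txn(
                d=date(2017, 1 + i % 2, 3 + i),
                description=f"MERCHANT {i}",
                amount=a,
                account=Account.CREDIT if i % 3 == 0 else Account.CHECKING,
            )
        )
    for i in range(3):
        txns.append(
            make_txn(
                d=date(2017, 1, 10 + i),
                description="PAYROLL",
                amount="1500.00",
                direction=Direction.INCOME,
            )
        )
    return Ledger(tuple(txns))
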