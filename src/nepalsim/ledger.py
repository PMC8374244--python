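"""Accounts and the transaction ledger.

Every rupee entering or leaving an in-model account passes through
:meth:`Ledger.post`, so the cash delta of any account over any interval
equals the signed sum of its ledger entries — money conservation is
checkable, not assumed.  Intra-village transfers post two balancing entries;
flows to or from the outside world (markets, employers, banks, departed
villagers) are single entries under an external counterparty tag.

Debt is tracked on the account but is not cash: loans and repayments post
cash entries; interest accrual changes only the debt balance.
"""

from __future__ import annotations

from dataclasses import dataclass, field

CATEGORIES = frozenset({
    "salary", "wage", "pension", "remittance",
    "crop sale", "crop input", "animal feed", "animal trade",
    "milk", "eggs", "tomato",
    "food", "other living", "education", "festival", "meat",
    "wedding", "funeral", "dowry", "house construction",
    "oxen hire", "interest", "loan principal", "repayment",
    "bailout", "inheritance", "initial allocation", "other",
})


@dataclass
class LedgerEntry:
    day_index: int
    account_id: str
    category: str
    amount: float  # signed NPR; positive = inflow to the account


@dataclass
class Account:
    """A finance controller's books: cash, ordinary debt, reconstruction loan."""

    id: str
    cash: float = 0.0
    debt: float = 0.0
    reconstruction_loan: float = 0.0
    # one sixtieth of the original reconstruction loan, fixed at issue
    recon_instalment: float = 0.0
    meat_portions: int = 0
    # cash at the moment the ledger started recording (post-initialisation)
    opening_cash: float = 0.0

    def __post_init__(self) -> None:
        if self.meat_portions not in (0, 1, 2, 3):
            raise ValueError("meat_portions must be in 0..3")


class Ledger:
    def __init__(self) -> None:
        self.entries: list[LedgerEntry] = []

    def post(self, day_index: int, account: Account, category: str, amount: float) -> None:
        """Move `amount` NPR into (positive) or out of (negative) an account."""
        if category not in CATEGORIES:
            raise ValueError(f"unknown ledger category {category!r}")
        account.cash += amount
        self.entries.append(LedgerEntry(day_index, account.id, category, amount))

    def transfer(self, day_index: int, src: Account, dst: Account,
                 category: str, amount: float) -> None:
        """Intra-village transfer: nets to zero across the two accounts."""
        self.post(day_index, src, category, -amount)
        self.post(day_index, dst, category, amount)

    def sums_by_account(self) -> dict[str, float]:
        out: dict[str, float] = {}
        for e in self.entries:
            out[e.account_id] = out.get(e.account_id, 0.0) + e.amount
        return out


def verify_closure(accounts: dict[str, Account], ledger: Ledger,
                   tol: float = 1e-6) -> None:
    """Assert cash(t_end) - cash(t_open) equals the ledger sum per account.

    Accounts that have been closed (departed households/villagers) are
    reconciled at their recorded closing balance of zero, which the closing
    entries themselves guarantee.
    """
    sums = ledger.sums_by_account()
    for acc in accounts.values():
        delta = acc.cash - acc.opening_cash
        posted = sums.get(acc.id, 0.0)
        if abs(delta - posted) > tol:
            raise AssertionError(
                f"ledger closure violated for {acc.id}: cash delta {delta:.4f} "
                f"!= posted sum {posted:.4f}"
            )
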