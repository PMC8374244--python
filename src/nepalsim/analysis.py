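"""Run summaries and output analysis.

Eight summary statistics describe each run: final household count, mean
household size, final villager count, household debt-days over the run,
households ever in debt, total household cash, total outstanding household
loans, and the end-of-run Gini index of household cash.  The module also
provides the coefficient-of-variation-versus-replicates diagnostic used to
choose the replicate count for experiments.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
import pandas as pd

SUMMARY_STATISTICS = (
    "final_households",
    "mean_household_size",
    "final_villagers",
    "household_debt_days",
    "households_ever_in_debt",
    "total_household_cash",
    "total_household_loans",
    "cash_gini",
)

#: replicate count at which the CV curves were judged stable
RECOMMENDED_MIN_REPLICATES = 200


def gini(values: Sequence[float]) -> float:
    """Gini index as half the relative mean absolute difference.

    Negative balances (indebted households) are clamped to zero first, so
    the index stays within [0, 1]; an all-zero vector scores 0.
    """
    x = np.asarray(list(values), dtype=float)
    if x.size == 0:
        raise ValueError("gini requires a non-empty list")
    x = np.clip(x, 0.0, None)
    mean = x.mean()
    if mean == 0.0:
        return 0.0
    mad = np.abs(x[:, None] - x[None, :]).mean()
    return float(mad / (2.0 * mean))


def summarize_run(state, result) -> dict[str, float]:
    """The eight end-of-run summary statistics for one simulation."""
    households = list(state.households.values())
    n_h = len(households)
    n_v = len(state.villagers)
    cash = [h.account.cash for h in households]
    loans = [h.account.debt + h.account.reconstruction_loan for h in households]
    return {
        "final_households": float(n_h),
        "mean_household_size": float(n_v / n_h) if n_h else 0.0,
        "final_villagers": float(n_v),
        "household_debt_days": float(result.debt_days),
        "households_ever_in_debt": float(len(result.ever_in_debt)),
        "total_household_cash": float(sum(cash)),
        "total_household_loans": float(sum(loans)),
        "cash_gini": gini(cash) if cash else 0.0,
    }


def cv_vs_runs(summaries: Sequence[dict[str, float]], metric: str) -> pd.DataFrame:
    """Coefficient of variation of a metric over the first n runs, for
    n = 1..N.  CV is undefined (NaN) at n = 1 and whenever the running mean
    is zero."""
    if len(summaries) < 2:
        raise ValueError("need at least two run summaries")
    values = np.array([s[metric] for s in summaries], dtype=float)
    rows = []
    for n in range(1, len(values) + 1):
        window = values[:n]
        mean = window.mean()
        if n < 2 or mean == 0.0:
            cv = np.nan
        else:
            cv = window.std(ddof=1) / mean
        rows.append((n, cv))
    return pd.DataFrame(rows, columns=["n_runs", "cv"])


def summaries_from_household_log(df: pd.DataFrame) -> dict[str, float]:
    """Recompute the run summary from a parsed daily household log alone
    (the log is self-sufficient)."""
    last_day = df["day"].max()
    end = df[df["day"] == last_day]
    debt_days = int((df["debt"] > 0).sum())
    ever = df.loc[df["debt"] > 0, "household"].nunique()
    cash = end["cash"].to_numpy(dtype=float)
    return {
        "final_households": float(len(end)),
        "mean_household_size": float(end["members"].mean()) if len(end) else 0.0,
        "final_villagers": float(end["members"].sum()),
        "household_debt_days": float(debt_days),
        "households_ever_in_debt": float(ever),
        "total_household_cash": float(cash.sum()),
        "total_household_loans": float(
            (end["debt"] + end["reconstruction_loan"]).sum()),
        "cash_gini": gini(cash) if len(cash) else 0.0,
    }
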