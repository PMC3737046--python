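"""Prescribed daily doses, annual summaries, olanzapine equivalents, costs.

The prescribed daily dose of a fill is strength x quantity / days supply.
Annual summaries average over claims (not beneficiaries), matching how
dispensing programs tabulate dose by fill; a per-user mode averages each
beneficiary's fills first.  Cross-drug comparisons use fixed clinical
equivalence ratios to the olanzapine milligram scale.  Program cost is
the amount paid to the pharmacy net of the user's copay.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .catalogs import OLANZAPINE_EQUIVALENCE

__all__ = ["daily_dose", "annual_dose_summary", "olanzapine_equivalent",
           "annual_costs", "DoseSummary", "OLANZAPINE_EQUIVALENCE"]


def daily_dose(claims: pd.DataFrame | pd.Series) -> pd.Series | float:
    """Milligrams per day implied by each fill; errors on days_supply < 1."""
    if isinstance(claims, pd.Series):  # a single claim row
        claims = claims.to_frame().T
        scalar = True
    else:
        scalar = False
    ds = pd.to_numeric(claims["days_supply"])
    if (ds < 1).any():
        raise ValueError("days_supply must be >= 1")
    dose = (pd.to_numeric(claims["strength_mg_per_unit"])
            * pd.to_numeric(claims["quantity"]) / ds)
    return float(dose.iloc[0]) if scalar else dose


@dataclass(frozen=True)
class DoseSummary:
    drug: str
    year: int
    mean_daily_dose_mg: float
    sd: float
    n_claims: int


def annual_dose_summary(claims: pd.DataFrame, drug_name: str, year: int,
                        per_user: bool = False) -> DoseSummary:
    """Mean (SD) daily dose for one drug and calendar year.

    With ``per_user=True`` each beneficiary contributes one value (the mean
    over their fills); n then counts beneficiaries rather than claims.
    """
    dates = pd.to_datetime(claims["dispense_date"])
    sub = claims[(claims["drug_name"] == drug_name) & (dates.dt.year == year)]
    if sub.empty:
        return DoseSummary(drug_name, year, float("nan"), float("nan"), 0)
    doses = daily_dose(sub)
    if per_user:
        doses = doses.groupby(sub["beneficiary_id"]).mean()
    sd = float(doses.std(ddof=1)) if len(doses) > 1 else 0.0
    return DoseSummary(drug_name, year, float(doses.mean()), sd, int(len(doses)))


def olanzapine_equivalent(dose_mg: float, drug: str,
                          table: dict | None = None) -> float:
    """Convert a daily dose to olanzapine-equivalent milligrams."""
    table = OLANZAPINE_EQUIVALENCE if table is None else table
    if drug not in table:
        raise KeyError(f"no equivalence ratio for {drug!r}")
    ratio = table[drug]
    if ratio <= 0:
        raise ValueError(f"equivalence ratio must be positive, got {ratio}")
    return dose_mg * ratio


def annual_costs(claims: pd.DataFrame, year: int) -> tuple[float, float, int]:
    """(total_paid, per_user_mean, n_users) for one calendar year.

    total is the sum of amount_paid - copay over the year's fills, rounded
    to cents; the per-user mean divides by the number of distinct
    beneficiaries with a fill that year (NaN when there are none) and is
    left at full precision since it is a mean, not a ledger amount.
    """
    dates = pd.to_datetime(claims["dispense_date"])
    sub = claims[dates.dt.year == year]
    net = pd.to_numeric(sub["amount_paid"]) - pd.to_numeric(sub["copay"])
    total = float(np.round(net.sum(), 2))
    n_users = int(sub["beneficiary_id"].nunique())
    per_user = total / n_users if n_users else float("nan")
    return total, per_user, n_users
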