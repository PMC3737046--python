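"""Antipsychotic user-cohort construction.

Implements the new-user (incident) design with a 6-month washout,
dispensing-based quarterly prevalence per 1000 eligible beneficiaries,
the long-term-user rule (>=2 fills within 180 days totalling >=90 days
supply), duration of use, distinct-agent counts and prescriber shares.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .quarters import quarter_bounds, quarter_index, quarter_label, quarter_range

AGE_GROUPS = [(0, 5), (6, 10), (11, 15), (16, 20), (21, 25)]
AGE_GROUP_LABELS = ["0-5", "6-10", "11-15", "16-20", "21-25"]

__all__ = [
    "AGE_GROUPS", "AGE_GROUP_LABELS", "age_group", "age_on",
    "identify_incident", "prevalent_by_quarter", "rate_series",
    "classify_long_term", "LongTermFlag", "duration_of_use",
    "count_distinct_aps", "prescriber_shares", "pct", "long_acting_share",
]


def pct(numerator: float, denominator: float, decimals: int = 1) -> float:
    """Percentage share n/d*100, rounded; NaN for an empty denominator."""
    if denominator == 0:
        return float("nan")
    return round(100.0 * numerator / denominator, decimals)


def age_on(birth_dates: pd.Series, when) -> pd.Series:
    """Completed age in years on a given day."""
    delta = (pd.Timestamp(when) - pd.to_datetime(birth_dates)).dt.days
    return (delta / 365.25).astype(float).apply(np.floor).astype(int)


def age_group(ages: pd.Series) -> pd.Series:
    """Map completed ages to the five study age bands (NaN outside 0-25)."""
    bins = [-1, 5, 10, 15, 20, 25]
    return pd.cut(ages, bins=bins, labels=AGE_GROUP_LABELS)


def identify_incident(claims: pd.DataFrame, study_start, study_end,
                      pre_period_days: int = 182) -> pd.DataFrame:
    """First in-window antipsychotic fill per beneficiary, new users only.

    Beneficiaries with any antipsychotic claim in the washout window
    [study_start - pre_period_days, study_start) are excluded entirely.
    Returns columns beneficiary_id, incident_date, atc, prescriber_specialty.
    """
    start, end = pd.Timestamp(study_start), pd.Timestamp(study_end)
    if end <= start:
        raise ValueError("study_end must be after study_start")
    dates = pd.to_datetime(claims["dispense_date"])
    pre = claims[(dates >= start - pd.Timedelta(days=pre_period_days)) & (dates < start)]
    excluded = set(pre["beneficiary_id"])
    in_window = claims[dates.between(start, end) &
                       ~claims["beneficiary_id"].isin(excluded)]
    first = (in_window.sort_values(["dispense_date", "atc"])
             .groupby("beneficiary_id", as_index=False)
             .first())
    out = first[["beneficiary_id", "dispense_date", "atc", "prescriber_specialty"]]
    return out.rename(columns={"dispense_date": "incident_date"}).reset_index(drop=True)


def prevalent_by_quarter(claims: pd.DataFrame, study_start, study_end,
                         scheme: str = "fiscal") -> dict[str, set]:
    """Quarter label -> set of beneficiaries with a fill dispensed in it.

    Membership is decided by dispense date only: a 100-day supply filled in
    one quarter does not make its recipient prevalent in the next.
    """
    labels = quarter_range(study_start, study_end, scheme)
    dates = pd.to_datetime(claims["dispense_date"])
    mask = dates.between(pd.Timestamp(study_start), pd.Timestamp(study_end))
    sub = claims[mask]
    labs = dates[mask].map(lambda d: quarter_label(d, scheme))
    out: dict[str, set] = {lab: set() for lab in labels}
    for lab, grp in sub.groupby(labs):
        out[lab] = set(grp["beneficiary_id"])
    return out


def _eligible_ids_in_quarter(eligibility: pd.DataFrame, qstart, qend) -> set:
    qs, qe = pd.Timestamp(qstart), pd.Timestamp(qend)
    hit = (pd.to_datetime(eligibility["start_date"]) <= qe) & \
          (pd.to_datetime(eligibility["end_date"]) >= qs)
    return set(eligibility.loc[hit, "beneficiary_id"])


def rate_series(user_sets: dict[str, set], eligibility: pd.DataFrame,
                beneficiaries: pd.DataFrame, stratum: str = "all",
                scheme: str = "fiscal", origin: str | None = None) -> pd.DataFrame:
    """Per-quarter users, denominators and rates per 1000 for one stratum.

    ``beneficiaries`` should already be restricted to the stratum; the
    denominator for a quarter counts stratum members with at least one
    eligible day in it.  A zero denominator yields an undefined (NaN) rate,
    mirroring broken trend lines for empty cells rather than reporting 0.
    """
    ids = set(beneficiaries["id"])
    elig = eligibility[eligibility["beneficiary_id"].isin(ids)]
    labels = list(user_sets)
    origin = origin or labels[0]
    tmap = quarter_index(labels, origin)
    rows = []
    for lab in labels:
        qs, qe = quarter_bounds(lab, scheme)
        denom_ids = _eligible_ids_in_quarter(elig, qs, qe)
        users = len(user_sets[lab] & denom_ids & ids)
        denom = len(denom_ids)
        rate = 1000.0 * users / denom if denom > 0 else float("nan")
        rows.append({"stratum": stratum, "quarter": lab, "t": tmap[lab],
                     "users": users, "denominator": denom, "rate": rate,
                     "undefined": denom == 0})
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class LongTermFlag:
    beneficiary_id: str
    is_long_term: bool
    qualifying_window: tuple | None = None  # (start Timestamp, end Timestamp)


def classify_long_term(claims: pd.DataFrame, window_days: int = 180,
                       min_days_supply: int = 90) -> LongTermFlag:
    """Long-term-user rule for one beneficiary's antipsychotic claims.

    True iff some window spanning <= ``window_days`` (first to last claim
    date, inclusive) holds >= 2 claims whose days supply sums to
    >= ``min_days_supply``.  The earliest qualifying window is reported.
    Sweep over date-sorted claims; since days supply is positive, the
    widest window anchored at each start claim dominates, so only those
    need checking.
    """
    if claims.empty:
        return LongTermFlag(beneficiary_id="", is_long_term=False)
    bid = claims["beneficiary_id"].iloc[0]
    srt = claims.sort_values("dispense_date")
    dates = pd.to_datetime(srt["dispense_date"]).to_numpy()
    supply = srt["days_supply"].to_numpy(dtype=float)
    n = len(dates)
    span = np.timedelta64(window_days, "D")
    for i in range(n):
        j = i
        run = 0.0
        while j < n and dates[j] - dates[i] <= span:
            run += supply[j]
            j += 1
        if j - i >= 2 and run >= min_days_supply:
            return LongTermFlag(bid, True,
                                (pd.Timestamp(dates[i]), pd.Timestamp(dates[j - 1])))
    return LongTermFlag(bid, False)


def classify_long_term_all(claims: pd.DataFrame, window_days: int = 180,
                           min_days_supply: int = 90) -> pd.DataFrame:
    """Vectorized wrapper: one LongTermFlag row per beneficiary with claims."""
    rows = []
    for bid, grp in claims.groupby("beneficiary_id"):
        flag = classify_long_term(grp, window_days, min_days_supply)
        rows.append({"beneficiary_id": bid, "is_long_term": flag.is_long_term,
                     "window_start": flag.qualifying_window[0] if flag.qualifying_window else pd.NaT,
                     "window_end": flag.qualifying_window[1] if flag.qualifying_window else pd.NaT})
    return pd.DataFrame(rows, columns=["beneficiary_id", "is_long_term",
                                       "window_start", "window_end"])


def duration_of_use(claims: pd.DataFrame, membership_days: int,
                    min_membership_days: int = 365) -> float | None:
    """Days from first fill to last fill plus its supply; None if the
    beneficiary was in the cohort under ``min_membership_days``.

    All antipsychotics are pooled; overlapping supplies are not truncated
    and gaps are not subtracted (first-to-last-coverage definition).
    """
    if membership_days < min_membership_days:
        return None
    if claims.empty:
        return 0.0
    srt = claims.sort_values("dispense_date")
    first = pd.to_datetime(srt["dispense_date"].iloc[0])
    last = pd.to_datetime(srt["dispense_date"].iloc[-1])
    return float((last - first).days + srt["days_supply"].iloc[-1])


def count_distinct_aps(claims: pd.DataFrame, catalog=None) -> int:
    """Number of distinct antipsychotic substances in one beneficiary's claims."""
    atcs = set(claims["atc"])
    if catalog is not None:
        atcs &= set(catalog.codes)
    return len(atcs)


def prescriber_shares(incident: pd.DataFrame) -> tuple[pd.DataFrame, float]:
    """Specialty counts/shares among incident fills with a known prescriber.

    Returns (table with columns specialty, n, share_pct) and the fraction
    of incident fills for which the prescriber field was populated.
    """
    total = len(incident)
    known = incident[incident["prescriber_specialty"] != "unknown"]
    availability = len(known) / total if total else 0.0
    counts = known["prescriber_specialty"].value_counts()
    table = pd.DataFrame({
        "specialty": counts.index,
        "n": counts.to_numpy(),
        "share_pct": [pct(c, len(known)) for c in counts.to_numpy()],
    })
    return table.reset_index(drop=True), availability


def long_acting_share(claims: pd.DataFrame, user_ids: set) -> float:
    """Percent of users with >=1 long-acting-injectable fill (DIN-flagged)."""
    lai_users = set(claims.loc[claims["din"].astype(str).str.endswith("-LAI"),
                               "beneficiary_id"])
    return pct(len(lai_users & user_ids), len(user_ids))
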