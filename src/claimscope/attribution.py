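"""Most-attributable-diagnosis procedure for antipsychotic users.

Prescription claims carry no indication, so the diagnosis most plausibly
behind an antipsychotic start is inferred from dated diagnoses near the
incident fill, resolved stepwise: hospital-discharge (DAD) diagnoses
outrank physician-billing (MSI) ones; within MSI, psychiatrist diagnoses
outrank other providers; among what survives, the lowest hierarchy level
number (psychosis = 1 ... other = 10) wins.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass

import pandas as pd

from .catalogs import DiagnosisHierarchy, classify_icd

logger = logging.getLogger(__name__)

_SOURCE_RANK = {"DAD": 0, "MSI": 1}
_PROVIDER_RANK = {"not_applicable": 0, "psychiatrist": 0, "other_physician": 1}


@dataclass(frozen=True)
class AttributionResult:
    beneficiary_id: str
    attributed_level: int | None
    deciding_rule: str | None  # single_dx | db_priority | provider_priority | level_priority
    source_db: str | None
    n_candidates: int
    representative_date: pd.Timestamp | None = None


def collect_candidates(beneficiary_id: str, incident_date, diagnoses: pd.DataFrame,
                       hierarchy: DiagnosisHierarchy,
                       window_before: int = 90, window_after: int = 90) -> pd.DataFrame:
    """Level-resolvable diagnoses within the attribution window.

    The window is [incident - window_before, incident + window_after] days,
    inclusive.  Codes that do not map to any hierarchy level are dropped
    (with a debug log) — they are not evidence for or against any level.
    """
    inc = pd.Timestamp(incident_date)
    sub = diagnoses[diagnoses["beneficiary_id"] == beneficiary_id]
    dates = pd.to_datetime(sub["service_date"])
    sub = sub[dates.between(inc - pd.Timedelta(days=window_before),
                            inc + pd.Timedelta(days=window_after))].copy()
    if sub.empty:
        return sub.assign(level=pd.Series(dtype=int))
    levels = [classify_icd(c, v, hierarchy)
              for c, v in zip(sub["code"], sub["icd_version"])]
    unmapped = sum(lv is None for lv in levels)
    if unmapped:
        logger.debug("dropped %d unmapped diagnosis codes for %s",
                     unmapped, beneficiary_id)
    sub["level"] = levels
    return sub[sub["level"].notna()].astype({"level": int})


def attribute(candidates: pd.DataFrame, beneficiary_id: str | None = None) -> AttributionResult:
    """Resolve one beneficiary's candidate diagnoses to a single level.

    Order-independent: equivalent to scoring every candidate by the tuple
    (source rank, provider rank, level) and taking the lexicographic
    minimum.  ``deciding_rule`` records the first step that actually
    discriminated among the candidates.
    """
    bid = beneficiary_id or (candidates["beneficiary_id"].iloc[0]
                             if len(candidates) else "")
    n = len(candidates)
    if n == 0:
        return AttributionResult(bid, None, None, None, 0)

    pool = candidates
    rule = "single_dx" if n == 1 else None
    has_dad = (pool["source_db"] == "DAD").any()
    if has_dad:
        restricted = pool[pool["source_db"] == "DAD"]
        if rule is None and len(restricted) < len(pool):
            rule = "db_priority"
        pool = restricted
    else:
        psych = pool[pool["provider"] == "psychiatrist"]
        if len(psych):
            if rule is None and len(psych) < len(pool):
                rule = "provider_priority"
            pool = psych
    if rule is None:
        rule = "level_priority"
    best_level = int(pool["level"].min())
    winners = pool[pool["level"] == best_level]
    rep_date = pd.to_datetime(winners["service_date"]).min()
    src = winners.loc[pd.to_datetime(winners["service_date"]).idxmin(), "source_db"]
    return AttributionResult(bid, best_level, rule, src, n, rep_date)


def attribute_all(users: pd.DataFrame, diagnoses: pd.DataFrame,
                  hierarchy: DiagnosisHierarchy, claims: pd.DataFrame | None = None,
                  mode: str = "incident_window",
                  window_before: int = 90, window_after: int = 90) -> pd.DataFrame:
    """Run attribution for every user row (beneficiary_id, incident_date).

    ``mode='incident_window'`` uses the symmetric +/- window; with
    ``mode='to_last_fill'`` the after-window extends to the beneficiary's
    last antipsychotic fill date (``claims`` required).
    """
    if mode not in ("incident_window", "to_last_fill"):
        raise ValueError(f"unknown attribution mode: {mode!r}")
    last_fill = None
    if mode == "to_last_fill":
        if claims is None:
            raise ValueError("mode='to_last_fill' requires the claims table")
        last_fill = (pd.to_datetime(claims["dispense_date"])
                     .groupby(claims["beneficiary_id"]).max())
    dx_by_bid = dict(tuple(diagnoses.groupby("beneficiary_id")))
    rows = []
    for r in users.itertuples():
        inc = pd.Timestamp(r.incident_date)
        after = window_after
        if last_fill is not None and r.beneficiary_id in last_fill.index:
            after = max(window_after, (last_fill[r.beneficiary_id] - inc).days)
        sub = dx_by_bid.get(r.beneficiary_id)
        if sub is None:
            res = AttributionResult(r.beneficiary_id, None, None, None, 0)
        else:
            cand = collect_candidates(r.beneficiary_id, inc, sub,
                                      hierarchy, window_before, after)
            res = attribute(cand, r.beneficiary_id)
        rows.append({"beneficiary_id": res.beneficiary_id,
                     "attributed_level": res.attributed_level,
                     "deciding_rule": res.deciding_rule,
                     "source_db": res.source_db,
                     "n_candidates": res.n_candidates})
    return pd.DataFrame(rows, columns=["beneficiary_id", "attributed_level",
                                       "deciding_rule", "source_db", "n_candidates"])


def attribution_table(results: pd.DataFrame, hierarchy: DiagnosisHierarchy) -> pd.DataFrame:
    """Per-level counts and shares over users with a resolved level.

    Users without any in-window mappable diagnosis are excluded from the
    share denominator but reported via the returned attrs
    (``n_total``, ``n_resolved``, ``n_unresolved``).
    """
    resolved = results[results["attributed_level"].notna()]
    counts = resolved["attributed_level"].astype(int).value_counts()
    rows = []
    for level in hierarchy.levels:
        n = int(counts.get(level, 0))
        rows.append({"level": level, "category": hierarchy.names[level], "n": n,
                     "share_pct": 100.0 * n / len(resolved) if len(resolved) else float("nan")})
    out = pd.DataFrame(rows)
    out.attrs.update(n_total=len(results), n_resolved=len(resolved),
                     n_unresolved=len(results) - len(resolved))
    return out
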