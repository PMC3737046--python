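"""Co-prescribing and incident-comorbidity windows for long-term users.

Both analyses anchor on the incident antipsychotic date: psychotropic
co-prescribing looks for class claims from 90 days before to 180 days
after it; non-psychiatric comorbidity requires a target diagnosis in the
two years after with none of that condition in the 12 months up to and
including the anchor day (washout).
"""
from __future__ import annotations

import pandas as pd

from .catalogs import ComorbidityTargets, PsychotropicClassMap

__all__ = ["coprescribed_classes", "comorbidity_flags",
           "coprescribing_table", "comorbidity_table"]


class NotLongTermError(ValueError):
    """Raised when a window analysis is requested for a non-long-term user."""


def coprescribed_classes(beneficiary_id: str, incident_date, drug_claims: pd.DataFrame,
                         class_map: PsychotropicClassMap, antipsychotic_codes: frozenset,
                         is_long_term: bool = True,
                         window_before: int = 90, window_after: int = 180) -> dict[str, bool]:
    """Per-class flags: any class claim dispensed within the window.

    Antipsychotic claims never flag a class, whatever the class map says.
    """
    if not is_long_term:
        raise NotLongTermError(
            f"co-prescribing windows are defined for long-term users only "
            f"({beneficiary_id} is not)")
    inc = pd.Timestamp(incident_date)
    sub = drug_claims[drug_claims["beneficiary_id"] == beneficiary_id]
    dates = pd.to_datetime(sub["dispense_date"])
    sub = sub[dates.between(inc - pd.Timedelta(days=window_before),
                            inc + pd.Timedelta(days=window_after))]
    flags = {c: False for c in class_map.classes}
    for atc in sub["atc"]:
        cls = class_map.classify(atc, exclude=antipsychotic_codes)
        if cls is not None:
            flags[cls] = True
    return flags


def comorbidity_flags(beneficiary_id: str, incident_date, diagnoses: pd.DataFrame,
                      targets: ComorbidityTargets, is_long_term: bool = True,
                      after_window_days: int = 730,
                      washout_days: int = 365) -> dict[str, bool]:
    """Per-condition incident-comorbidity flags with a pre-anchor washout.

    True iff a target diagnosis falls in (incident, incident + after_window]
    and no diagnosis of that condition falls in [incident - washout,
    incident].  The anchor day itself counts as washout (a same-day
    diagnosis is treated as pre-existing).
    """
    if not is_long_term:
        raise NotLongTermError(
            f"comorbidity windows are defined for long-term users only "
            f"({beneficiary_id} is not)")
    inc = pd.Timestamp(incident_date)
    sub = diagnoses[diagnoses["beneficiary_id"] == beneficiary_id]
    dates = pd.to_datetime(sub["service_date"])
    flags = {}
    for cond in targets.conditions:
        hit = [targets.matches(c, v, cond)
               for c, v in zip(sub["code"], sub["icd_version"])]
        hit = pd.Series(hit, index=sub.index)
        in_after = hit & (dates > inc) & (dates <= inc + pd.Timedelta(days=after_window_days))
        in_washout = hit & (dates >= inc - pd.Timedelta(days=washout_days)) & (dates <= inc)
        flags[cond] = bool(in_after.any() and not in_washout.any())
    return flags


def coprescribing_table(long_term_users: pd.DataFrame, drug_claims: pd.DataFrame,
                        class_map: PsychotropicClassMap, antipsychotic_codes: frozenset,
                        window_before: int = 90, window_after: int = 180) -> pd.DataFrame:
    """Flags for every long-term user (rows: beneficiary_id + one bool per class).

    ``long_term_users`` needs columns beneficiary_id and incident_date.
    """
    rows = []
    for r in long_term_users.itertuples():
        flags = coprescribed_classes(r.beneficiary_id, r.incident_date, drug_claims,
                                     class_map, antipsychotic_codes, True,
                                     window_before, window_after)
        rows.append({"beneficiary_id": r.beneficiary_id, **flags})
    cols = ["beneficiary_id"] + class_map.classes
    return pd.DataFrame(rows, columns=cols)


def comorbidity_table(long_term_users: pd.DataFrame, diagnoses: pd.DataFrame,
                      targets: ComorbidityTargets, after_window_days: int = 730,
                      washout_days: int = 365) -> pd.DataFrame:
    """Comorbidity flags for every long-term user."""
    rows = []
    for r in long_term_users.itertuples():
        flags = comorbidity_flags(r.beneficiary_id, r.incident_date, diagnoses,
                                  targets, True, after_window_days, washout_days)
        rows.append({"beneficiary_id": r.beneficiary_id, **flags})
    cols = ["beneficiary_id"] + targets.conditions
    return pd.DataFrame(rows, columns=cols)
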