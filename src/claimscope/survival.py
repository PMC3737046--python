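"""Kaplan-Meier curves and age/sex-adjusted Cox mortality comparisons.

Compares death among antipsychotic users, other benefit recipients and a
general-population comparator.  Estimation is delegated to lifelines
(product-limit estimator; Cox partial likelihood with Efron ties); this
module fixes the record layout, the contrasts and the reporting.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.exceptions import ConvergenceError

GROUPS = ("ap_user", "benefits_nonuser", "general_population")

__all__ = ["GROUPS", "HazardFit", "km_curve", "cox_fit", "records_from_group_rates"]


@dataclass(frozen=True)
class HazardFit:
    contrast: str
    hazard_ratio: float
    ci_low: float
    ci_high: float
    wald_chi2: float
    p: float

    def __post_init__(self):
        if not (self.ci_low <= self.hazard_ratio <= self.ci_high):
            raise ValueError("confidence interval must bracket the estimate")


def km_curve(records: pd.DataFrame) -> pd.DataFrame:
    """Product-limit survival curve for one group of subject records.

    ``records`` needs columns ``time`` (days from entry) and ``event``
    (True = death, False = censored).  Returns a step function as a
    DataFrame with columns time, survival.
    """
    if records.empty:
        raise ValueError("need at least one record")
    kmf = KaplanMeierFitter()
    kmf.fit(records["time"], event_observed=records["event"].astype(bool))
    sf = kmf.survival_function_
    return pd.DataFrame({"time": sf.index.to_numpy(dtype=float),
                         "survival": sf.iloc[:, 0].to_numpy()})


def km_survival_at(records: pd.DataFrame, time: float) -> float:
    """S(t) from the product-limit estimator."""
    curve = km_curve(records)
    past = curve[curve["time"] <= time]
    return float(past["survival"].iloc[-1]) if len(past) else 1.0


def cox_fit(records: pd.DataFrame, reference: str = "general_population",
            adjust: tuple = ("age_at_entry", "sex")) -> list[HazardFit]:
    """Cox proportional-hazards contrasts of each group against a reference.

    Age enters continuously (years at entry), sex as an indicator.  The
    Wald chi-square is the squared z of each group coefficient.  Raises on
    non-convergence or separation rather than returning a silent fit.
    """
    df = records.copy()
    groups = [g for g in GROUPS if g in set(df["group"])]
    if len(groups) < 2:
        raise ValueError("need records from at least two groups")
    if reference not in groups:
        raise ValueError(f"reference group {reference!r} absent from records")
    if not df["event"].any():
        raise ValueError("no events: hazard ratios are not identified")
    X = pd.DataFrame({"time": df["time"].astype(float),
                      "event": df["event"].astype(bool)})
    contrasts = [g for g in groups if g != reference]
    for g in contrasts:
        X[f"group_{g}"] = (df["group"] == g).astype(float)
    if "age_at_entry" in adjust and "age_at_entry" in df:
        X["age_at_entry"] = df["age_at_entry"].astype(float)
    if "sex" in adjust and "sex" in df:
        X["male"] = (df["sex"] == "M").astype(float)
    cph = CoxPHFitter()
    try:
        cph.fit(X, duration_col="time", event_col="event")
    except ConvergenceError as err:
        raise RuntimeError(f"Cox model failed to converge: {err}") from err
    out = []
    ci = np.exp(cph.confidence_intervals_)
    for g in contrasts:
        name = f"group_{g}"
        coef = cph.params_[name]
        se = cph.standard_errors_[name]
        z = coef / se
        out.append(HazardFit(
            contrast=f"{g}_vs_{reference}",
            hazard_ratio=float(np.exp(coef)),
            ci_low=float(ci.loc[name].iloc[0]),
            ci_high=float(ci.loc[name].iloc[1]),
            wald_chi2=float(z * z),
            p=float(cph.summary.loc[name, "p"]),
        ))
    return out


def records_from_group_rates(n: int, n_deaths: int, group: str, follow_up_days: int,
                             rng: np.random.Generator,
                             age_range: tuple = (0, 25),
                             male_fraction: float = 0.5) -> pd.DataFrame:
    """Synthetic subject-level records consistent with aggregate death counts.

    Published comparators come as group totals (population size and deaths
    over the study window); this recipe expands them into pseudo-records:
    exponential event times at the implied constant hazard, censored at the
    end of follow-up, uniform ages and a fixed male fraction.  A generator
    device for survival comparisons, not an estimator.
    """
    if n_deaths > n:
        raise ValueError("more deaths than subjects")
    # hazard solving P(death within T) = deaths/n under exponential times
    p = n_deaths / n
    lam = -np.log1p(-p) / follow_up_days if p < 1 else np.inf
    t_event = rng.exponential(1 / lam, size=n) if lam > 0 else np.full(n, np.inf)
    event = t_event <= follow_up_days
    time = np.minimum(t_event, follow_up_days)
    ages = rng.uniform(age_range[0], age_range[1] + 1, size=n)
    sex = np.where(rng.random(n) < male_fraction, "M", "F")
    return pd.DataFrame({
        "subject_id": [f"{group[:3].upper()}{i:07d}" for i in range(n)],
        "group": group, "age_at_entry": ages, "sex": sex,
        "time": time, "event": event,
    })
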