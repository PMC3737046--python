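"""End-to-end orchestration: simulate/load -> cohort -> attribution ->
exposure windows -> dosing/costs -> trends -> survival -> report bundle.

Every stage logs record counts in and out, all figure numbers are also
written as CSV, and each run emits a JSON log carrying the seed and a
hash of the effective configuration so bundles are comparable.
"""
from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import attribution, cohort, dosing, trend, windows
from .catalogs import ComorbidityTargets, PsychotropicClassMap
from .io import LinkedData, load_linked_data, write_linked_data
from .simulate import SimConfig, generate, reference_config
from .survival import cox_fit, km_curve, records_from_group_rates

logger = logging.getLogger(__name__)


class StageError(RuntimeError):
    """A pipeline stage failed; partial outputs are preserved on disk."""

    def __init__(self, stage: str, err: Exception):
        self.stage = stage
        super().__init__(f"stage {stage!r} failed: {err}")


@dataclass
class PipelineConfig:
    """Defaults reproduce the study conventions documented per module."""

    data_dir: str | None = None          # load data from here unless simulating
    simulate: bool = True
    sim: SimConfig = field(default_factory=reference_config)
    seed: int = 20071
    quarter_scheme: str = "fiscal"
    pre_period_days: int = 182
    attribution_mode: str = "incident_window"
    attribution_window_before: int = 90
    attribution_window_after: int = 90
    coprescribe_window: tuple = (90, 180)
    comorbidity_after_days: int = 730
    comorbidity_washout_days: int = 365
    long_term_window_days: int = 180
    long_term_min_supply: int = 90
    duration_min_membership: int = 365
    dose_years: tuple = (2001, 2002, 2006)
    # survival comparator synthesized from general-population aggregates,
    # scaled down so pseudo-records stay tractable
    general_population: tuple = (387202, 792)
    general_population_scale: float = 0.1
    figures: bool = False

    def config_hash(self) -> str:
        def _default(o):
            if dataclasses.is_dataclass(o):
                return dataclasses.asdict(o)
            return str(o)
        blob = json.dumps(dataclasses.asdict(self), default=_default, sort_keys=True)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def _write(df: pd.DataFrame, path: Path) -> None:
    out = df.copy()
    for col in out.columns:
        if pd.api.types.is_datetime64_any_dtype(out[col]):
            out[col] = out[col].dt.strftime("%Y-%m-%d")
        elif pd.api.types.is_float_dtype(out[col]):
            out[col] = out[col].map(lambda v: "" if pd.isna(v) else f"{v:.6g}")
    out.to_csv(path, index=False, lineterminator="\n")


def run_pipeline(config: PipelineConfig, out_dir) -> dict:
    """Run every stage and write the report bundle; returns a result dict."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    log: dict = {"seed": config.seed, "config_hash": config.config_hash(),
                 "stages": {}}
    results: dict = {"log": log}
    stage = "setup"
    try:
        # ---- data ------------------------------------------------------
        stage = "data"
        if config.simulate:
            data = generate(config.sim.replace(seed=config.seed))
            write_linked_data(data, out / "data")
        else:
            if config.data_dir is None:
                raise ValueError("data_dir required when simulate=False")
            d = Path(config.data_dir)
            data = load_linked_data({t: d / f"{t}.csv" for t in
                                     ("beneficiaries", "eligibility", "drug_claims",
                                      "diagnoses", "deaths")})
        log["stages"]["data"] = {k: len(v) for k, v in data.tables().items()}
        results["data"] = data

        start, end = config.sim.study_start, config.sim.study_end
        ap_codes = data.catalog.codes
        ap_claims = data.drug_claims[data.drug_claims["atc"].isin(ap_codes)]

        # ---- cohort ----------------------------------------------------
        stage = "cohort"
        incident = cohort.identify_incident(ap_claims, start, end,
                                            config.pre_period_days)
        # the user universe is everyone dispensed an antipsychotic in the
        # window; the washout-restricted incident cohort (a subset) anchors
        # the prescriber, attribution and exposure-window analyses
        in_window = pd.to_datetime(ap_claims["dispense_date"]).between(
            pd.Timestamp(start), pd.Timestamp(end))
        user_claims = ap_claims[in_window]
        user_ids = set(user_claims["beneficiary_id"])
        benef = data.beneficiaries
        users_tab = benef[benef["id"].isin(user_ids)].copy()
        users_tab["age"] = cohort.age_on(users_tab["birth_date"], start)
        users_tab["age_group"] = cohort.age_group(users_tab["age"])
        benef_all = benef.copy()
        benef_all["age"] = cohort.age_on(benef_all["birth_date"], start)
        benef_all["age_group"] = cohort.age_group(benef_all["age"])

        table3 = []
        for grp_label, grp in benef_all.groupby("age_group", observed=False):
            gusers = users_tab[users_tab["age_group"] == grp_label]
            row = {"age_group": grp_label, "beneficiaries": len(grp),
                   "pct_male": cohort.pct((grp["sex"] == "M").sum(), len(grp)),
                   "users": len(gusers),
                   "user_pct": cohort.pct(len(gusers), len(grp))}
            for sex in ("M", "F"):
                den = (grp["sex"] == sex).sum()
                num = (gusers["sex"] == sex).sum()
                row[f"users_{sex}"] = int(num)
                row[f"user_pct_{sex}"] = cohort.pct(num, den)
            table3.append(row)
        table3.append({"age_group": "total", "beneficiaries": len(benef_all),
                       "pct_male": cohort.pct((benef_all["sex"] == "M").sum(),
                                              len(benef_all)),
                       "users": len(users_tab),
                       "user_pct": cohort.pct(len(users_tab), len(benef_all)),
                       "users_M": int((users_tab["sex"] == "M").sum()),
                       "user_pct_M": cohort.pct((users_tab["sex"] == "M").sum(),
                                                (benef_all["sex"] == "M").sum()),
                       "users_F": int((users_tab["sex"] == "F").sum()),
                       "user_pct_F": cohort.pct((users_tab["sex"] == "F").sum(),
                                                (benef_all["sex"] == "F").sum())})
        table3 = pd.DataFrame(table3)
        _write(table3, out / "users_by_age_sex.csv")

        prevalent = cohort.prevalent_by_quarter(user_claims, start, end,
                                                config.quarter_scheme)
        rate_frames = [cohort.rate_series(prevalent, data.eligibility, benef_all,
                                          "all", config.quarter_scheme)]
        for grp_label, grp in benef_all.groupby("age_group", observed=False):
            rate_frames.append(cohort.rate_series(
                prevalent, data.eligibility, grp, str(grp_label),
                config.quarter_scheme))
        for gen in ("FGA", "SGA"):
            gen_codes = {c for c in ap_codes if data.catalog.generation(c) == gen}
            gen_claims = user_claims[user_claims["atc"].isin(gen_codes)]
            prev_g = cohort.prevalent_by_quarter(gen_claims, start, end,
                                                 config.quarter_scheme)
            rate_frames.append(cohort.rate_series(prev_g, data.eligibility,
                                                  benef_all, gen,
                                                  config.quarter_scheme))
        rates = pd.concat(rate_frames, ignore_index=True)
        _write(rates, out / "quarterly_rates.csv")

        lt = cohort.classify_long_term_all(user_claims,
                                           config.long_term_window_days,
                                           config.long_term_min_supply)
        lt_ids = set(lt.loc[lt["is_long_term"], "beneficiary_id"])
        _write(lt, out / "long_term.csv")

        memb = data.eligibility.copy()
        memb_days = ((memb["end_date"].clip(upper=pd.Timestamp(end))
                      - memb["start_date"].clip(lower=pd.Timestamp(start))).dt.days + 1)
        memb_days = memb_days.clip(lower=0).groupby(memb["beneficiary_id"]).sum()
        durations = []
        for bid, grp in user_claims.groupby("beneficiary_id"):
            d = cohort.duration_of_use(grp, int(memb_days.get(bid, 0)),
                                       config.duration_min_membership)
            durations.append({"beneficiary_id": bid,
                              "duration_days": np.nan if d is None else d,
                              "evaluable": d is not None})
        durations = pd.DataFrame(
            durations, columns=["beneficiary_id", "duration_days", "evaluable"])
        _write(durations, out / "duration.csv")

        distinct = user_claims.groupby("beneficiary_id")["atc"].nunique()
        distinct_tab = (distinct.clip(upper=4).value_counts().sort_index()
                        .rename_axis("n_distinct_aps").reset_index(name="users"))
        _write(distinct_tab, out / "distinct_aps.csv")

        shares, availability = cohort.prescriber_shares(incident)
        _write(shares, out / "prescriber_shares.csv")
        lai_pct = cohort.long_acting_share(user_claims, user_ids)
        log["stages"]["cohort"] = {
            "users": len(user_ids), "incident_users": len(incident),
            "long_term_users": len(lt_ids),
            "prescriber_availability_pct": round(100 * availability, 1),
            "lai_share_pct": lai_pct}
        results.update(incident=incident, n_users=len(user_ids), table3=table3,
                       rates=rates, long_term=lt, durations=durations)

        # ---- attribution ------------------------------------------------
        stage = "attribution"
        attr = attribution.attribute_all(
            incident, data.diagnoses, data.hierarchy, claims=user_claims,
            mode=config.attribution_mode,
            window_before=config.attribution_window_before,
            window_after=config.attribution_window_after)
        attr_tab = attribution.attribution_table(attr, data.hierarchy)
        _write(attr, out / "attribution.csv")
        _write(attr_tab, out / "attribution_shares.csv")
        log["stages"]["attribution"] = {
            "n_total": attr_tab.attrs["n_total"],
            "n_resolved": attr_tab.attrs["n_resolved"],
            "n_unresolved": attr_tab.attrs["n_unresolved"]}
        results.update(attribution=attr, attribution_shares=attr_tab)

        # duration by attributed diagnosis (the figure-6 analogue)
        dur_dx = durations.merge(attr[["beneficiary_id", "attributed_level"]],
                                 on="beneficiary_id")
        dur_dx = dur_dx[dur_dx["evaluable"] & dur_dx["attributed_level"].notna()]
        dur_by_dx = (dur_dx.groupby("attributed_level")["duration_days"]
                     .agg(n="count", median="median",
                          q1=lambda s: s.quantile(0.25),
                          q3=lambda s: s.quantile(0.75))
                     .reset_index())
        _write(dur_by_dx, out / "duration_by_diagnosis.csv")

        # ---- exposure windows -------------------------------------------
        stage = "exposure_windows"
        lt_users = incident[incident["beneficiary_id"].isin(lt_ids)]
        class_map = PsychotropicClassMap.load()
        co = windows.coprescribing_table(
            lt_users, data.drug_claims, class_map, ap_codes,
            *config.coprescribe_window)
        co_users = co.merge(users_tab[["id", "age_group"]],
                            left_on="beneficiary_id", right_on="id")
        co_rates = []
        for cls in class_map.classes:
            co_rates.append({"class": cls, "stratum": "all",
                             "n": int(co[cls].sum()),
                             "share_pct": cohort.pct(co[cls].sum(), len(co))})
            for grp_label, grp in co_users.groupby("age_group", observed=False):
                co_rates.append({"class": cls, "stratum": str(grp_label),
                                 "n": int(grp[cls].sum()),
                                 "share_pct": cohort.pct(grp[cls].sum(), len(grp))})
        _write(pd.DataFrame(co_rates), out / "coprescribing.csv")

        targets = ComorbidityTargets.load()
        como = windows.comorbidity_table(lt_users, data.diagnoses, targets,
                                         config.comorbidity_after_days,
                                         config.comorbidity_washout_days)
        como_counts = pd.DataFrame({
            "condition": targets.conditions,
            "n": [int(como[c].sum()) for c in targets.conditions]})
        _write(como_counts, out / "comorbidity.csv")
        log["stages"]["exposure_windows"] = {
            "long_term_analyzed": len(lt_users),
            "any_comorbidity": int((como[targets.conditions].any(axis=1)).sum())}
        results.update(coprescribing=co, comorbidity=como_counts)

        # ---- dosing & costs ---------------------------------------------
        stage = "dosing_costs"
        dose_rows = []
        for year in config.dose_years:
            for drug in sorted(set(user_claims["drug_name"])):
                s = dosing.annual_dose_summary(user_claims, drug, year)
                if s.n_claims:
                    dose_rows.append(dataclasses.asdict(s))
        _write(pd.DataFrame(dose_rows), out / "dose_summary.csv")

        cost_rows = []
        years = sorted(pd.to_datetime(user_claims["dispense_date"]).dt.year.unique())
        for year in years:
            total, per_user, n_users = dosing.annual_costs(user_claims, int(year))
            cost_rows.append({"year": int(year), "total_paid": total,
                              "per_user_mean": per_user, "n_users": n_users})
        _write(pd.DataFrame(cost_rows), out / "costs_by_year.csv")
        log["stages"]["dosing_costs"] = {"dose_rows": len(dose_rows),
                                         "years": len(cost_rows)}
        results.update(doses=pd.DataFrame(dose_rows), costs=pd.DataFrame(cost_rows))

        # ---- trends & association ---------------------------------------
        stage = "trend_stats"
        fits = []
        for stratum, grp in rates.groupby("stratum"):
            y = grp.sort_values("t")["rate"].to_numpy()
            finite = np.isfinite(y)
            if finite.sum() < 8:
                continue
            res = trend.fit_ar1_trend(y, t=grp.sort_values("t")["t"].to_numpy())
            fits.append({"stratum": stratum, "A": res.A, "B": res.B, "k": res.k,
                         "se_B": res.se_B, "p_trend": res.p_trend, "n": res.n,
                         "quarters_dropped": int((~finite).sum())})
        fits = pd.DataFrame(fits)
        _write(fits, out / "trend_fits.csv")

        n_m = int((benef_all["sex"] == "M").sum())
        n_f = len(benef_all) - n_m
        u_m = int((users_tab["sex"] == "M").sum())
        u_f = len(users_tab) - u_m
        assoc_row = {}
        if min(u_m, n_m - u_m, u_f, n_f - u_f) > 0:
            tab = trend.TwoByTwo(u_m, n_m - u_m, u_f, n_f - u_f)
            orx, (lo, hi) = trend.odds_ratio_woolf(tab)
            chi2, df, p = trend.chi_square_2x2(tab)
            assoc_row = {"contrast": "male_vs_female_user", "odds_ratio": orx,
                         "ci_low": lo, "ci_high": hi, "chi_square": chi2,
                         "df": df, "p": p}
        assoc = pd.DataFrame([assoc_row]) if assoc_row else pd.DataFrame(
            columns=["contrast", "odds_ratio", "ci_low", "ci_high",
                     "chi_square", "df", "p"])
        _write(assoc, out / "association.csv")
        log["stages"]["trend_stats"] = {"strata_fit": len(fits)}
        results.update(trend_fits=fits, association=assoc)

        # ---- survival ----------------------------------------------------
        stage = "survival"
        rng = np.random.default_rng(config.seed + 7)
        fu_days = (pd.Timestamp(end) - pd.Timestamp(start)).days
        death_dates = benef_all["id"].map(dict(zip(
            data.deaths["beneficiary_id"], pd.to_datetime(data.deaths["death_date"]))))
        died = death_dates.notna()
        t = np.where(died, (death_dates - pd.Timestamp(start)).dt.days, fu_days)
        recs = pd.DataFrame({
            "subject_id": benef_all["id"].to_numpy(),
            "group": np.where(benef_all["id"].isin(user_ids),
                              "ap_user", "benefits_nonuser"),
            "age_at_entry": benef_all["age"].to_numpy(dtype=float),
            "sex": benef_all["sex"].to_numpy(),
            "time": np.maximum(t.astype(float), 0.5),
            "event": died.to_numpy(),
        })
        gp_n, gp_deaths = config.general_population
        scale = config.general_population_scale
        gp = records_from_group_rates(int(gp_n * scale),
                                      int(round(gp_deaths * scale)),
                                      "general_population", fu_days, rng)
        allrecs = pd.concat([recs, gp[recs.columns]], ignore_index=True)

        km_frames = []
        for g, grp in allrecs.groupby("group"):
            c = km_curve(grp)
            c.insert(0, "group", g)
            km_frames.append(c)
        km = pd.concat(km_frames, ignore_index=True)
        _write(km, out / "survival_km.csv")
        try:
            hazards = cox_fit(allrecs)
            hz = pd.DataFrame([dataclasses.asdict(h) for h in hazards])
        except (RuntimeError, ValueError) as err:
            logger.warning("Cox stage degraded: %s", err)
            hz = pd.DataFrame(columns=["contrast", "hazard_ratio", "ci_low",
                                       "ci_high", "wald_chi2", "p"])
        _write(hz, out / "survival_cox.csv")
        log["stages"]["survival"] = {
            "records": len(allrecs), "events": int(allrecs["event"].sum())}
        results.update(survival_km=km, survival_cox=hz)

        if config.figures:
            _figures(out, rates, attr_tab, km)

    except Exception as err:  # noqa: BLE001 - annotate and re-raise with stage
        log["stages"][stage] = {"error": str(err)}
        (out / "run_log.json").write_text(json.dumps(log, indent=2, sort_keys=True))
        if isinstance(err, StageError):
            raise
        raise StageError(stage, err) from err

    (out / "run_log.json").write_text(json.dumps(log, indent=2, sort_keys=True))
    return results


def _figures(out: Path, rates: pd.DataFrame, attr_tab: pd.DataFrame,
             km: pd.DataFrame) -> None:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    plt.rcParams["svg.hashsalt"] = "claimscope"
    figdir = out / "figures"
    figdir.mkdir(exist_ok=True)
    meta = {"Date": None}

    fig, ax = plt.subplots(figsize=(7, 4))
    for stratum, grp in rates.groupby("stratum"):
        if stratum in ("FGA", "SGA", "all"):
            continue
        ax.plot(grp["t"], grp["rate"], label=stratum)
    ax.set_xlabel("quarter")
    ax.set_ylabel("users per 1000 beneficiaries")
    ax.legend(fontsize=8)
    fig.savefig(figdir / "quarterly_rates_by_age.svg", metadata=meta)
    plt.close(fig)

    fig, ax = plt.subplots(figsize=(6, 4))
    ax.bar(attr_tab["category"], attr_tab["share_pct"])
    ax.set_ylabel("% of users with a resolved diagnosis")
    ax.tick_params(axis="x", rotation=75, labelsize=7)
    fig.tight_layout()
    fig.savefig(figdir / "attribution_shares.svg", metadata=meta)
    plt.close(fig)

    fig, ax = plt.subplots(figsize=(6, 4))
    for g, grp in km.groupby("group"):
        ax.step(grp["time"], grp["survival"], where="post", label=g)
    ax.set_xlabel("days from entry")
    ax.set_ylabel("S(t)")
    ax.legend()
    fig.savefig(figdir / "survival.svg", metadata=meta)
    plt.close(fig)
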