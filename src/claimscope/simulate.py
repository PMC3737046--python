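"""Seeded generator of linked synthetic claims data.

Emulates a seven-year provincial drug-benefit linkage for beneficiaries
aged 0-25: an age/sex registry with eligibility interruptions, quarterly
antipsychotic dispensing following per-drug linear trends with AR(1)
noise (and an optional formulary step-change), multi-source diagnosis
mixtures around the incident fill, psychotropic co-prescribing, and
differential mortality.  Everything is driven by one ``SimConfig`` whose
defaults are calibrated to the published whole-period marginals (43,888
beneficiaries, ~3.9% antipsychotic users, male:female odds ratio ~2.5,
66% of users with two or more diagnoses); quarterly trend shapes are not
published numerically, so those defaults are chosen as plausible rates
consistent with the printed totals.

Quarterly claim counts per drug are Poisson with a log-linear mean:
lambda_t = n * rate_t/1000 * exp(a_t - Var(a)/2) where rate_t is the
configured linear trend and a_t a stationary AR(1) perturbation; the
variance offset keeps E[lambda_t] on the configured trend line.
"""
from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .catalogs import AtcCatalog, DiagnosisHierarchy, classify_icd
from .cohort import AGE_GROUPS
from .io import LinkedData
from .quarters import quarter_bounds, quarter_range

__all__ = ["SimConfig", "DrugTrend", "reference_config", "generate"]

_STUDY_START = "2000-10-01"
_STUDY_END = "2007-09-30"

#: tablet strength (mg), typical daily dose (mg), lognormal dose spread,
#: program cost per day of supply ($)
DRUG_PROFILES = {
    "risperidone": (1.0, 2.0, 0.6, 1.8),
    "quetiapine": (100.0, 280.0, 0.7, 2.6),
    "olanzapine": (5.0, 13.0, 0.5, 3.4),
    "haloperidol": (5.0, 5.0, 0.7, 0.4),
    "loxapine": (10.0, 25.0, 0.8, 0.6),
    "chlorpromazine": (25.0, 75.0, 0.7, 0.4),
    "methotrimeprazine": (25.0, 50.0, 0.7, 0.4),
}
_DEFAULT_PROFILE = (10.0, 20.0, 0.7, 0.8)

_COPRESCRIPTION_ATCS = {
    "antidepressant": ("N06AB03", "N06AB04", "N06AX16"),
    "mood_stabilizer": ("N03AG01", "N03AX09", "N05AN01"),
    "anxiolytic": ("N05BA01", "N05BA12"),
    "adhd_medication": ("N06BA04", "N06BA09", "C02AC01"),
}


@dataclass(frozen=True)
class DrugTrend:
    """Linear quarterly prevalence trend for one drug, per 1000 beneficiaries."""

    baseline_rate_per_1000: float
    slope_per_quarter: float
    ar1_k: float = 0.4
    noise_sd: float = 0.10


@dataclass(frozen=True)
class SimConfig:
    """Study conditions for the synthetic linkage (defaults = reference).

    Age-group vectors are ordered 0-5, 6-10, 11-15, 16-20, 21-25.  User
    fractions are per sex within age group (whole-period probability of
    being an antipsychotic user).  ``male_female_or_target`` documents the
    odds ratio the fractions imply and is checked, not sampled from.
    """

    n_beneficiaries: int = 43888
    age_group_weights: tuple = (0.337176, 0.170297, 0.152502, 0.155714, 0.184311)
    male_fraction_by_age: tuple = (0.516, 0.518, 0.476, 0.354, 0.299)
    study_start: str = _STUDY_START
    study_end: str = _STUDY_END
    ap_user_fraction_by_age_sex: dict = field(default_factory=lambda: {
        "M": (0.005, 0.044, 0.060, 0.111, 0.193),
        "F": (0.001, 0.010, 0.022, 0.034, 0.054),
    })
    male_female_or_target: float = 2.5
    drug_mix: dict = field(default_factory=lambda: {
        "risperidone": 0.45, "quetiapine": 0.20, "olanzapine": 0.15,
        "haloperidol": 0.05, "loxapine": 0.06, "chlorpromazine": 0.05,
        "methotrimeprazine": 0.04,
    })
    trend: dict = field(default_factory=lambda: {
        "risperidone": DrugTrend(1.20, 0.160),
        "quetiapine": DrugTrend(0.50, 0.090),
        "olanzapine": DrugTrend(0.90, 0.030),
        "haloperidol": DrugTrend(0.45, -0.008),
        "loxapine": DrugTrend(0.50, -0.009),
        "chlorpromazine": DrugTrend(0.35, -0.007),
        "methotrimeprazine": DrugTrend(0.20, -0.004),
    })
    formulary_step: tuple | None = ("2003-12-01", {"risperidone": 1.35})
    multi_dx_fraction: float = 0.66
    dx_source_mix: tuple = (0.36, 0.16, 0.48)  # DAD, MSI-psychiatrist, MSI-other
    coprescribe_probs: dict = field(default_factory=lambda: {
        "antidepressant": 0.42, "mood_stabilizer": 0.27,
        "anxiolytic": 0.15, "adhd_medication": 0.17,
    })
    eligibility_gap_rate: float = 0.15     # expected gaps per beneficiary-year
    death_rate_users: float = 0.00135      # deaths per person-year
    death_rate_nonusers: float = 0.00043
    seed: int = 20071
    # realism knobs beyond the headline marginals
    no_dx_fraction: float = 0.17           # users with no mappable diagnosis
    dx_outside_window_fraction: float = 0.10
    dx_level_weights: tuple = (0.31, 0.07, 0.04, 0.02, 0.10, 0.16, 0.08, 0.15, 0.005, 0.065)
    lai_fraction: float = 0.033            # users ever on a long-acting injectable
    prior_user_fraction: float = 0.03      # users with a washout-period fill
    comorbidity_rate: float = 0.05         # long-term-ish users gaining a target dx

    def validate(self) -> None:
        def _check_probs(name, vals):
            if any(not 0 <= v <= 1 for v in vals):
                raise ValueError(f"{name}: proportions must lie in [0, 1]")
        if self.n_beneficiaries <= 0:
            raise ValueError("n_beneficiaries: must be positive")
        if abs(sum(self.age_group_weights) - 1) > 1e-6:
            raise ValueError("age_group_weights: must sum to 1")
        _check_probs("age_group_weights", self.age_group_weights)
        _check_probs("male_fraction_by_age", self.male_fraction_by_age)
        for sex in ("M", "F"):
            _check_probs(f"ap_user_fraction_by_age_sex[{sex}]",
                         self.ap_user_fraction_by_age_sex[sex])
        if abs(sum(self.drug_mix.values()) - 1) > 1e-6:
            raise ValueError("drug_mix: must sum to 1")
        for drug, tr in self.trend.items():
            if not abs(tr.ar1_k) < 1:
                raise ValueError(f"trend[{drug}].ar1_k: |k| must be < 1")
            if tr.noise_sd < 0:
                raise ValueError(f"trend[{drug}].noise_sd: must be >= 0")
        _check_probs("coprescribe_probs", self.coprescribe_probs.values())
        for name in ("multi_dx_fraction", "no_dx_fraction", "lai_fraction",
                     "prior_user_fraction", "dx_outside_window_fraction",
                     "comorbidity_rate"):
            _check_probs(name, [getattr(self, name)])
        if abs(sum(self.dx_source_mix) - 1) > 1e-6:
            raise ValueError("dx_source_mix: must sum to 1")
        if pd.Timestamp(self.study_end) <= pd.Timestamp(self.study_start):
            raise ValueError("study_end: must be after study_start")

    def replace(self, **kw) -> "SimConfig":
        return dataclasses.replace(self, **kw)


def reference_config() -> SimConfig:
    """The packaged reference configuration (published-marginal calibration)."""
    return SimConfig()


def _step_multiplier(cfg: SimConfig, drug: str, qs, qe) -> float:
    """Formulary-step factor for one quarter, pro-rated within the
    quarter containing the step date."""
    if cfg.formulary_step is None:
        return 1.0
    step_date, jumps = cfg.formulary_step
    if drug not in jumps:
        return 1.0
    step = pd.Timestamp(step_date)
    qs, qe = pd.Timestamp(qs), pd.Timestamp(qe)
    if qe < step:
        return 1.0
    if qs >= step:
        return jumps[drug]
    frac = ((qe - step).days + 1) / ((qe - qs).days + 1)
    return 1.0 + (jumps[drug] - 1.0) * frac


def _build_eligibility(cfg: SimConfig, rng: np.random.Generator,
                       ids: np.ndarray) -> pd.DataFrame:
    """Base spell (washout start .. study end) with 0-2 interruptions."""
    n = len(ids)
    start = pd.Timestamp(cfg.study_start) - pd.Timedelta(days=182)
    end = pd.Timestamp(cfg.study_end)
    years = (end - pd.Timestamp(cfg.study_start)).days / 365.25
    n_gaps = np.minimum(rng.poisson(cfg.eligibility_gap_rate * years, size=n), 2)

    study_days = (end - pd.Timestamp(cfg.study_start)).days
    g1_off = rng.integers(30, max(study_days - 240, 31), size=n)
    g1_len = rng.integers(30, 121, size=n)
    g2_wait = rng.integers(60, 201, size=n)
    g2_len = rng.integers(30, 121, size=n)

    s0 = pd.Timestamp(cfg.study_start)
    g1s = s0 + pd.to_timedelta(g1_off, unit="D")
    g1e = g1s + pd.to_timedelta(g1_len, unit="D")
    g2s = g1e + pd.to_timedelta(g2_wait, unit="D")
    g2e = g2s + pd.to_timedelta(g2_len, unit="D")
    has1 = n_gaps >= 1
    has2 = (n_gaps >= 2) & (g2e < end - pd.Timedelta(days=30))

    rows = {"beneficiary_id": [], "start_date": [], "end_date": []}

    def _emit(mask, starts, ends):
        ok = mask & (np.asarray(starts) <= np.asarray(ends))
        rows["beneficiary_id"].append(ids[ok])
        rows["start_date"].append(np.asarray(starts)[ok])
        rows["end_date"].append(np.asarray(ends)[ok])

    start_arr = np.full(n, start.to_datetime64())
    end_arr = np.full(n, end.to_datetime64())
    # spell 1: base start .. (gap1 start - 1 | study end)
    e1 = np.where(has1, (g1s - pd.Timedelta(days=1)).to_numpy(), end_arr)
    _emit(np.ones(n, bool), start_arr, e1)
    # spell 2 after gap1
    s2 = (g1e + pd.Timedelta(days=1)).to_numpy()
    e2 = np.where(has2, (g2s - pd.Timedelta(days=1)).to_numpy(), end_arr)
    _emit(has1, s2, e2)
    # spell 3 after gap2
    s3 = (g2e + pd.Timedelta(days=1)).to_numpy()
    _emit(has2, s3, end_arr)

    df = pd.DataFrame({k: np.concatenate(v) for k, v in rows.items()})
    df["start_date"] = pd.to_datetime(df["start_date"])
    df["end_date"] = pd.to_datetime(df["end_date"])
    return df.sort_values(["beneficiary_id", "start_date"]).reset_index(drop=True)


def _spell_arrays(eligibility: pd.DataFrame, ids: np.ndarray):
    """(starts, ends) day-resolution int64 arrays, shape (n, max_spells)."""
    idx = {b: i for i, b in enumerate(ids)}
    max_spells = int(eligibility.groupby("beneficiary_id").size().max())
    # padding sentinels chosen far outside any day number yet safe to subtract
    pad = np.int64(1) << 40
    starts = np.full((len(ids), max_spells), pad, dtype=np.int64)
    ends = np.full((len(ids), max_spells), -pad, dtype=np.int64)
    sd = eligibility["start_date"].to_numpy().astype("datetime64[D]").astype(np.int64)
    ed = eligibility["end_date"].to_numpy().astype("datetime64[D]").astype(np.int64)
    counts = np.zeros(len(ids), dtype=int)
    for b, s, e in zip(eligibility["beneficiary_id"], sd, ed):
        i = idx[b]
        starts[i, counts[i]] = s
        ends[i, counts[i]] = e
        counts[i] += 1
    return starts, ends


def _sample_dates_in_overlap(rng, starts, ends, lo: int, hi: int) -> np.ndarray:
    """One uniform day per row from the overlap of the row's spells with
    [lo, hi]; rows with no overlap get -1."""
    os_ = np.maximum(starts, lo)
    oe = np.minimum(ends, hi)
    lens = np.maximum(oe - os_ + 1, 0)  # (rows, spells)
    tot = lens.sum(axis=1)
    out = np.full(len(starts), -1, dtype=np.int64)
    ok = tot > 0
    pick = (rng.random(len(starts)) * np.maximum(tot, 1)).astype(np.int64)
    if not ok.any():
        return out
    cum = np.cumsum(lens, axis=1)
    spell_idx = np.minimum((pick[:, None] >= cum).sum(axis=1), lens.shape[1] - 1)
    prev = np.where(spell_idx > 0,
                    np.take_along_axis(cum, np.maximum(spell_idx - 1, 0)[:, None],
                                       axis=1).ravel(), 0)
    offset = pick - prev
    chosen_start = np.take_along_axis(os_, spell_idx[:, None], axis=1).ravel()
    out[ok] = (chosen_start + offset)[ok]
    return out


def _sample_code(rng, hierarchy: DiagnosisHierarchy, level: int, version: int,
                 prefix_pool: dict) -> str:
    prefixes = prefix_pool[(version, level)]
    p = prefixes[rng.integers(len(prefixes))]
    candidate = p + str(rng.integers(0, 10))
    if classify_icd(candidate, version, hierarchy) == level:
        return candidate
    return p


def generate(config: SimConfig, seed: int | None = None) -> LinkedData:
    """Draw one linked dataset; deterministic given (config, seed)."""
    cfg = config
    cfg.validate()
    rng = np.random.default_rng(cfg.seed if seed is None else seed)
    catalog = AtcCatalog.load()
    hierarchy = DiagnosisHierarchy.load()
    name_to_atc = {v[0]: k for k, v in catalog.entries.items()}
    for drug in cfg.drug_mix:
        if drug not in name_to_atc:
            raise ValueError(f"drug_mix: unknown drug {drug!r}")

    n = cfg.n_beneficiaries
    start = pd.Timestamp(cfg.study_start)
    end = pd.Timestamp(cfg.study_end)
    start_day = start.to_datetime64().astype("datetime64[D]").astype(np.int64)
    end_day = end.to_datetime64().astype("datetime64[D]").astype(np.int64)

    # ---- registry -------------------------------------------------------
    ids = np.array([f"B{i:06d}" for i in range(n)])
    group = rng.choice(len(AGE_GROUPS), size=n, p=np.asarray(cfg.age_group_weights))
    male = rng.random(n) < np.asarray(cfg.male_fraction_by_age)[group]
    lo = np.array([g[0] for g in AGE_GROUPS], dtype=float)
    hi = np.array([g[1] for g in AGE_GROUPS], dtype=float)
    age = lo[group] + rng.random(n) * (hi[group] - lo[group] + 1.0)
    birth = start - pd.to_timedelta(np.round(age * 365.25).astype(int), unit="D")
    region = rng.choice(np.array(["HFX", "CBR", "VAL", "NOR", "SOU"]), size=n)
    beneficiaries = pd.DataFrame({
        "id": ids, "sex": np.where(male, "M", "F"),
        "birth_date": birth, "region": region,
    })

    eligibility = _build_eligibility(cfg, rng, ids)
    starts, ends = _spell_arrays(eligibility, ids)

    # ---- user selection (per age x sex fractions) -----------------------
    p_user = np.where(
        male,
        np.asarray(cfg.ap_user_fraction_by_age_sex["M"])[group],
        np.asarray(cfg.ap_user_fraction_by_age_sex["F"])[group])
    is_user = rng.random(n) < p_user
    user_idx = np.flatnonzero(is_user)
    n_users = len(user_idx)

    # ---- per-drug quarterly claims --------------------------------------
    labels = quarter_range(cfg.study_start, cfg.study_end)
    qbounds = [quarter_bounds(lab) for lab in labels]
    qs_day = np.array([pd.Timestamp(b[0]).to_datetime64().astype("datetime64[D]").astype(np.int64)
                       for b in qbounds])
    qe_day = np.array([pd.Timestamp(b[1]).to_datetime64().astype("datetime64[D]").astype(np.int64)
                       for b in qbounds])
    nq = len(labels)

    drugs = list(cfg.drug_mix)
    drug_of_user = rng.choice(len(drugs), size=n_users,
                              p=np.asarray([cfg.drug_mix[d] for d in drugs]))

    u_starts, u_ends = starts[user_idx], ends[user_idx]
    # eligibility indicator per user x quarter
    elig_uq = np.zeros((n_users, nq), dtype=bool)
    for q in range(nq):
        overlap = np.minimum(u_ends, qe_day[q]) - np.maximum(u_starts, qs_day[q]) + 1
        elig_uq[:, q] = (overlap > 0).any(axis=1)

    claim_bid: list[np.ndarray] = []
    claim_day: list[np.ndarray] = []
    claim_drug: list[np.ndarray] = []

    for di, drug in enumerate(drugs):
        tr = cfg.trend[drug]
        members = np.flatnonzero(drug_of_user == di)
        if len(members) == 0:
            continue
        # stationary AR(1) perturbation on the log mean
        a = np.empty(nq)
        var_a = tr.noise_sd ** 2 / (1 - tr.ar1_k ** 2) if tr.noise_sd > 0 else 0.0
        a[0] = rng.normal(0.0, np.sqrt(var_a)) if var_a > 0 else 0.0
        innov = rng.normal(0.0, tr.noise_sd, size=nq)
        for t in range(1, nq):
            a[t] = tr.ar1_k * a[t - 1] + innov[t]
        claimed = np.zeros(len(members), dtype=bool)
        lam_profile = np.zeros(nq)
        for q in range(nq):
            rate = max(tr.baseline_rate_per_1000 + tr.slope_per_quarter * (q + 1), 0.0)
            rate *= _step_multiplier(cfg, drug, *qbounds[q])
            lam = rate / 1000.0 * n * np.exp(a[q] - var_a / 2.0)
            lam_profile[q] = lam
            pool = members[elig_uq[members, q]]
            if len(pool) == 0 or lam <= 0:
                continue
            k = min(int(rng.poisson(lam)), len(pool))
            if k == 0:
                continue
            chosen = rng.choice(pool, size=k, replace=False)
            days = _sample_dates_in_overlap(
                rng, u_starts[chosen], u_ends[chosen], qs_day[q], qe_day[q])
            keep = days >= 0
            chosen, days = chosen[keep], days[keep]
            claimed[np.isin(members, chosen)] = True
            claim_bid.append(user_idx[chosen])
            claim_day.append(days)
            claim_drug.append(np.full(len(chosen), di))
        # rescue: flagged users never sampled get one claim so that the
        # registry user fraction equals the claims-derived one
        missing = members[~claimed]
        if len(missing):
            w = np.where(elig_uq[missing][:, :] & (lam_profile[None, :] > 0),
                         lam_profile[None, :], 0.0)
            tot = w.sum(axis=1)
            fallback = tot <= 0
            w[fallback] = elig_uq[missing][fallback].astype(float)
            tot = w.sum(axis=1)
            qsel = np.array([rng.choice(nq, p=wi / ti) for wi, ti in zip(w, tot)])
            days = np.array([
                _sample_dates_in_overlap(rng, u_starts[m][None, :], u_ends[m][None, :],
                                         qs_day[q], qe_day[q])[0]
                for m, q in zip(missing, qsel)])
            keep = days >= 0
            claim_bid.append(user_idx[missing[keep]])
            claim_day.append(days[keep])
            claim_drug.append(np.full(int(keep.sum()), di))

    bid_i = np.concatenate(claim_bid) if claim_bid else np.array([], dtype=int)
    day_i = np.concatenate(claim_day) if claim_day else np.array([], dtype=np.int64)
    drug_i = np.concatenate(claim_drug) if claim_drug else np.array([], dtype=int)

    # washout-period fills: a small share of users were already on therapy
    # before the study window and get excluded by the incident rule
    if n_users and cfg.prior_user_fraction > 0:
        prior = user_idx[rng.random(n_users) < cfg.prior_user_fraction]
        if len(prior):
            pdays = start_day - rng.integers(1, 180, size=len(prior))
            pdrug = drug_of_user[np.searchsorted(user_idx, prior)]
            bid_i = np.concatenate([bid_i, prior])
            day_i = np.concatenate([day_i, pdays])
            drug_i = np.concatenate([drug_i, pdrug])

    # ---- deaths ----------------------------------------------------------
    years = (end - start).days / 365.25
    death_day = np.full(n, np.iinfo(np.int64).max, dtype=np.int64)
    first_claim_day = np.full(n, -1, dtype=np.int64)
    if len(day_i):
        order = np.lexsort((day_i, bid_i))
        firsts = pd.Series(day_i[order]).groupby(pd.Series(bid_i[order])).min()
        first_claim_day[firsts.index.to_numpy()] = firsts.to_numpy()
    p_die_u = 1 - np.exp(-cfg.death_rate_users * years)
    p_die_n = 1 - np.exp(-cfg.death_rate_nonusers * years)
    dies = rng.random(n) < np.where(is_user, p_die_u, p_die_n)
    for i in np.flatnonzero(dies):
        lo_d = first_claim_day[i] + 30 if first_claim_day[i] > 0 else start_day
        lo_d = min(lo_d, end_day - 1)
        death_day[i] = rng.integers(lo_d, end_day + 1)

    keep = day_i <= death_day[bid_i]
    bid_i, day_i, drug_i = bid_i[keep], day_i[keep], drug_i[keep]

    deaths = pd.DataFrame({
        "beneficiary_id": ids[dies],
        "death_date": pd.to_datetime(death_day[dies], unit="D"),
        "cause_code": rng.choice(
            np.array(["X60", "I63", "E10", "X42", "V89", "R99"]), size=int(dies.sum())),
    }).sort_values("beneficiary_id").reset_index(drop=True)

    # truncate eligibility at death
    death_map = dict(zip(deaths["beneficiary_id"], deaths["death_date"]))
    if death_map:
        dd = eligibility["beneficiary_id"].map(death_map)
        eligibility = eligibility[~(eligibility["start_date"] > dd)].copy()
        dd = eligibility["beneficiary_id"].map(death_map)
        clip = dd.notna() & (eligibility["end_date"] > dd)
        eligibility.loc[clip, "end_date"] = dd[clip]
        eligibility = eligibility.reset_index(drop=True)

    # ---- claim attributes ------------------------------------------------
    drug_names = np.array(drugs)[drug_i] if len(drug_i) else np.array([], dtype=str)
    strength = np.empty(len(drug_i))
    dose = np.empty(len(drug_i))
    price_day = np.empty(len(drug_i))
    for di, drug in enumerate(drugs):
        m = drug_i == di
        st, typ, spread, price = DRUG_PROFILES.get(drug, _DEFAULT_PROFILE)
        strength[m] = st
        dose[m] = typ * np.exp(rng.normal(-spread ** 2 / 2, spread, size=int(m.sum())))
        price_day[m] = price
    days_supply = rng.choice(np.array([30, 60, 90, 100]), size=len(drug_i),
                             p=[0.50, 0.20, 0.20, 0.10])
    quantity = np.maximum(np.round(dose * days_supply / np.maximum(strength, 1e-9)), 1.0)
    amount = np.round(price_day * days_supply * rng.uniform(0.8, 1.2, len(drug_i)), 2)
    copay = np.round(np.minimum(rng.uniform(0, 5, len(drug_i)), amount), 2)

    lai_ok = np.array([catalog.has_long_acting(name_to_atc[d]) for d in drugs])
    user_lai = np.zeros(n, dtype=bool)
    if n_users:
        user_lai[user_idx] = rng.random(n_users) < cfg.lai_fraction
    claim_lai = user_lai[bid_i] & lai_ok[drug_i]
    atcs = np.array([name_to_atc[d] for d in drugs])[drug_i] if len(drug_i) else np.array([], dtype=str)
    din = np.array([f"{a}-{'LAI' if l else 'ORAL'}" for a, l in zip(atcs, claim_lai)])

    spec_pool = np.array(["general_practice", "psychiatry", "pediatrics",
                          "emergency", "internal_medicine", "neurology", "other"])
    spec_p = np.array([0.72, 0.16, 0.035, 0.03, 0.02, 0.02, 0.015])
    known = rng.random(len(drug_i)) < 0.52
    specialty = np.where(known,
                         rng.choice(spec_pool, size=len(drug_i), p=spec_p / spec_p.sum()),
                         "unknown")

    # ---- psychotropic co-prescriptions ----------------------------------
    co_bid, co_day, co_atc = [], [], []
    if n_users:
        anchor = first_claim_day[user_idx]
        has_anchor = anchor > 0
        for cls, codes in _COPRESCRIPTION_ATCS.items():
            p = cfg.coprescribe_probs.get(cls, 0.0)
            hit = (rng.random(n_users) < p) & has_anchor
            rows = np.flatnonzero(hit)
            if not len(rows):
                continue
            lo_w = anchor[rows] - 90
            hi_w = np.minimum(anchor[rows] + 180, end_day)
            days = np.array([
                _sample_dates_in_overlap(rng, u_starts[r][None, :], u_ends[r][None, :],
                                         l, h)[0]
                for r, l, h in zip(rows, lo_w, hi_w)])
            keep = days >= 0
            co_bid.append(user_idx[rows[keep]])
            co_day.append(days[keep])
            co_atc.append(rng.choice(np.array(codes), size=int(keep.sum())))

    def _claims_frame(bids, days_arr, atc_arr, name_arr, strength_arr, qty_arr,
                      ds_arr, amt_arr, cop_arr, din_arr, spec_arr):
        return pd.DataFrame({
            "beneficiary_id": ids[bids],
            "dispense_date": pd.to_datetime(days_arr, unit="D"),
            "atc": atc_arr, "din": din_arr, "drug_name": name_arr,
            "strength_mg_per_unit": strength_arr, "quantity": qty_arr,
            "days_supply": ds_arr, "amount_paid": amt_arr, "copay": cop_arr,
            "prescriber_specialty": spec_arr,
        })

    ap_claims = _claims_frame(bid_i, day_i, atcs, drug_names, strength, quantity,
                              days_supply, amount, copay, din, specialty)
    frames = [ap_claims]
    if co_bid:
        cb = np.concatenate(co_bid)
        cd = np.concatenate(co_day)
        ca = np.concatenate(co_atc)
        keep = cd <= death_day[cb]
        cb, cd, ca = cb[keep], cd[keep], ca[keep]
        nco = len(cb)
        co_ds = rng.choice(np.array([30, 90]), size=nco, p=[0.6, 0.4])
        co_amt = np.round(rng.uniform(10, 80, nco), 2)
        frames.append(_claims_frame(
            cb, cd, ca, np.array(["co_med"] * nco), np.full(nco, 10.0),
            co_ds.astype(float), co_ds, co_amt,
            np.round(np.minimum(rng.uniform(0, 5, nco), co_amt), 2),
            np.array([f"{a}-ORAL" for a in ca]),
            np.array(["general_practice"] * nco)))
    drug_claims = pd.concat(frames, ignore_index=True)
    drug_claims = drug_claims.sort_values(
        ["beneficiary_id", "dispense_date", "atc"]).reset_index(drop=True)

    # ---- diagnoses -------------------------------------------------------
    prefix_pool: dict[tuple[int, int], list[str]] = {}
    for version, prefix, level in hierarchy.iter_prefixes():
        prefix_pool.setdefault((version, level), []).append(prefix)
    for key in prefix_pool:
        prefix_pool[key].sort()

    dx_rows = {"beneficiary_id": [], "service_date": [], "code": [],
               "icd_version": [], "source_db": [], "provider": []}
    levels_arr = np.asarray(cfg.dx_level_weights, dtype=float)
    levels_arr = levels_arr / levels_arr.sum()
    src_p = np.asarray(cfg.dx_source_mix)
    if n_users:
        anchor = first_claim_day[user_idx]
        for ui, i in enumerate(user_idx):
            if anchor[ui] <= 0 or rng.random() < cfg.no_dx_fraction:
                continue
            n_dx = 1 if rng.random() >= cfg.multi_dx_fraction else 2 + rng.poisson(1.0)
            for _ in range(n_dx):
                if rng.random() < cfg.dx_outside_window_fraction:
                    off = int(rng.integers(91, 271)) * (1 if rng.random() < 0.5 else -1)
                else:
                    off = int(rng.integers(-90, 91))
                day = int(np.clip(anchor[ui] + off, start_day - 270, end_day))
                if day > death_day[i]:
                    continue
                src = rng.choice(3, p=src_p)
                level = int(rng.choice(10, p=levels_arr)) + 1
                if src == 0:
                    version, source_db, provider = 10, "DAD", "not_applicable"
                elif src == 1:
                    version, source_db, provider = 9, "MSI", "psychiatrist"
                else:
                    version, source_db, provider = 9, "MSI", "other_physician"
                code = _sample_code(rng, hierarchy, level, version, prefix_pool)
                dx_rows["beneficiary_id"].append(ids[i])
                dx_rows["service_date"].append(day)
                dx_rows["code"].append(code)
                dx_rows["icd_version"].append(version)
                dx_rows["source_db"].append(source_db)
                dx_rows["provider"].append(provider)
        # non-psychiatric comorbidity targets after the incident fill
        from .catalogs import ComorbidityTargets
        targets = ComorbidityTargets.load()
        conds = targets.conditions
        hit = rng.random(n_users) < cfg.comorbidity_rate
        for ui in np.flatnonzero(hit):
            i = user_idx[ui]
            if anchor[ui] <= 0:
                continue
            cond = conds[rng.integers(len(conds))]
            version = 9 if rng.random() < 0.7 else 10
            prefixes = targets.prefixes[cond].get(version) or \
                targets.prefixes[cond][19 - version]
            version = version if targets.prefixes[cond].get(version) else 19 - version
            code = prefixes[rng.integers(len(prefixes))]
            day = int(min(anchor[ui] + rng.integers(1, 731), end_day))
            if day > death_day[i]:
                continue
            source_db = "MSI" if version == 9 else "DAD"
            provider = "other_physician" if version == 9 else "not_applicable"
            dx_rows["beneficiary_id"].append(ids[i])
            dx_rows["service_date"].append(day)
            dx_rows["code"].append(code)
            dx_rows["icd_version"].append(version)
            dx_rows["source_db"].append(source_db)
            dx_rows["provider"].append(provider)

    diagnoses = pd.DataFrame(dx_rows)
    if len(diagnoses):
        diagnoses["service_date"] = pd.to_datetime(diagnoses["service_date"], unit="D")
        diagnoses = diagnoses.sort_values(
            ["beneficiary_id", "service_date", "code"]).reset_index(drop=True)

    return LinkedData(
        beneficiaries=beneficiaries, eligibility=eligibility,
        drug_claims=drug_claims, diagnoses=diagnoses, deaths=deaths,
        catalog=catalog, hierarchy=hierarchy)
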