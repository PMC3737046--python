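"""Statistical structure and determinism of the synthetic linkage generator."""
import numpy as np
import pandas as pd
import pytest

from claimscope.io import write_linked_data
from claimscope.simulate import DrugTrend, SimConfig, generate, reference_config


def _expected_user_fraction(cfg: SimConfig) -> float:
    w = np.asarray(cfg.age_group_weights)
    mf = np.asarray(cfg.male_fraction_by_age)
    pm = np.asarray(cfg.ap_user_fraction_by_age_sex["M"])
    pf = np.asarray(cfg.ap_user_fraction_by_age_sex["F"])
    return float((w * (mf * pm + (1 - mf) * pf)).sum())


def test_reference_config_matches_study_conditions():
    cfg = reference_config()
    cfg.validate()
    assert cfg.study_start == "2000-10-01" and cfg.study_end == "2007-09-30"
    assert cfg.n_beneficiaries == 43888
    assert cfg.multi_dx_fraction == 0.66
    assert cfg.formulary_step[0] == "2003-12-01"
    # the per-stratum user fractions imply the documented male:female OR
    pm = _p = None
    w = np.asarray(cfg.age_group_weights)
    mf = np.asarray(cfg.male_fraction_by_age)
    p_m = float((w * mf * np.asarray(cfg.ap_user_fraction_by_age_sex["M"])).sum()
                / (w * mf).sum())
    p_f = float((w * (1 - mf) * np.asarray(cfg.ap_user_fraction_by_age_sex["F"])).sum()
                / (w * (1 - mf)).sum())
    implied_or = (p_m / (1 - p_m)) / (p_f / (1 - p_f))
    assert implied_or == pytest.approx(cfg.male_female_or_target, rel=0.05)


def test_invalid_configs_name_the_field():
    with pytest.raises(ValueError, match="age_group_weights"):
        SimConfig(age_group_weights=(1.0, 0.2, 0, 0, 0)).validate()
    with pytest.raises(ValueError, match="ar1_k"):
        SimConfig(trend={"risperidone": DrugTrend(1, 0, ar1_k=1.2)},
                  drug_mix={"risperidone": 1.0}).validate()
    with pytest.raises(ValueError, match="study_end"):
        SimConfig(study_end="1999-01-01").validate()


def test_same_seed_is_byte_identical(tmp_path):
    cfg = reference_config().replace(n_beneficiaries=2000)
    p1 = write_linked_data(generate(cfg, seed=5), tmp_path / "a")
    p2 = write_linked_data(generate(cfg, seed=5), tmp_path / "b")
    for name in p1:
        assert p1[name].read_bytes() == p2[name].read_bytes(), name
    p3 = write_linked_data(generate(cfg, seed=6), tmp_path / "c")
    assert any(p1[n].read_bytes() != p3[n].read_bytes() for n in p1)


def test_zero_user_fractions_give_zero_claims():
    cfg = reference_config().replace(
        n_beneficiaries=1000,
        ap_user_fraction_by_age_sex={"M": (0,) * 5, "F": (0,) * 5})
    data = generate(cfg, seed=1)
    assert data.drug_claims.empty
    assert data.diagnoses.empty


def test_marginals_calibrated_to_reference_fractions(small_data):
    cfg = reference_config().replace(n_beneficiaries=6000)
    users = set(small_data.drug_claims[
        small_data.drug_claims["atc"].isin(small_data.catalog.codes)]["beneficiary_id"])
    p = _expected_user_fraction(cfg)
    se = np.sqrt(p * (1 - p) / cfg.n_beneficiaries)
    assert len(users) / cfg.n_beneficiaries == pytest.approx(p, abs=4 * se)


def test_no_claim_outside_an_eligibility_spell(small_data):
    spells = {bid: list(zip(grp["start_date"], grp["end_date"]))
              for bid, grp in small_data.eligibility.groupby("beneficiary_id")}
    claims = small_data.drug_claims
    dates = pd.to_datetime(claims["dispense_date"])
    for bid, d in zip(claims["beneficiary_id"], dates):
        assert any(s <= d <= e for s, e in spells[bid]), (bid, d)


def test_days_supply_capped_at_100(small_data):
    assert small_data.drug_claims["days_supply"].between(1, 100).all()


def test_death_truncates_activity(small_data):
    deaths = dict(zip(small_data.deaths["beneficiary_id"],
                      pd.to_datetime(small_data.deaths["death_date"])))
    claims = small_data.drug_claims
    for bid, d in zip(claims["beneficiary_id"],
                      pd.to_datetime(claims["dispense_date"])):
        if bid in deaths:
            assert d <= deaths[bid]


def test_mean_quarterly_counts_recover_configured_slope():
    """Averaged over seeds, per-quarter claim counts follow the linear trend."""
    cfg = SimConfig(
        n_beneficiaries=20000,
        ap_user_fraction_by_age_sex={"M": (0.08,) * 5, "F": (0.08,) * 5},
        drug_mix={"risperidone": 1.0},
        trend={"risperidone": DrugTrend(10.0, 0.50, ar1_k=0.3, noise_sd=0.05)},
        formulary_step=None, eligibility_gap_rate=0.0,
        death_rate_users=0.0, death_rate_nonusers=0.0,
        prior_user_fraction=0.0, coprescribe_probs={}, no_dx_fraction=1.0,
        comorbidity_rate=0.0)
    counts = []
    for seed in range(6):
        data = generate(cfg, seed=100 + seed)
        rsp = data.drug_claims[data.drug_claims["atc"] == "N05AX08"]
        q = pd.to_datetime(rsp["dispense_date"]).dt.to_period("Q")
        counts.append(q.value_counts().sort_index().to_numpy(dtype=float))
    mean_counts = np.mean(counts, axis=0)
    t = np.arange(1, len(mean_counts) + 1)
    slope = np.polyfit(t, mean_counts, 1)[0]
    expected = 0.50 / 1000 * cfg.n_beneficiaries  # claims per quarter per unit t
    assert slope == pytest.approx(expected, rel=0.25)


def test_detrended_log_counts_recover_ar1_coefficient():
    """Lag-1 autocorrelation of the detrended log series approaches k."""
    cfg = SimConfig(
        n_beneficiaries=40000, study_end="2030-09-30",
        ap_user_fraction_by_age_sex={"M": (0.6,) * 5, "F": (0.6,) * 5},
        drug_mix={"risperidone": 1.0},
        trend={"risperidone": DrugTrend(25.0, 0.0, ar1_k=0.5, noise_sd=0.10)},
        formulary_step=None, eligibility_gap_rate=0.0,
        death_rate_users=0.0, death_rate_nonusers=0.0,
        prior_user_fraction=0.0, coprescribe_probs={},
        no_dx_fraction=1.0, comorbidity_rate=0.0)
    data = generate(cfg, seed=9)
    q = pd.to_datetime(data.drug_claims["dispense_date"]).dt.to_period("Q")
    y = np.log(q.value_counts().sort_index().to_numpy(dtype=float))
    resid = y - y.mean()
    r1 = float(np.corrcoef(resid[:-1], resid[1:])[0, 1])
    # 120 quarters, k = 0.5: sampling sd of r1 is ~0.08; Poisson noise
    # attenuates slightly, so accept a wide but centred band
    assert 0.25 < r1 < 0.75


def test_multi_dx_fraction_realised(small_data):
    from claimscope.cohort import identify_incident
    ap = small_data.drug_claims[
        small_data.drug_claims["atc"].isin(small_data.catalog.codes)]
    inc = identify_incident(ap, "2000-10-01", "2007-09-30")
    dx_counts = small_data.diagnoses.groupby("beneficiary_id").size()
    with_dx = dx_counts[dx_counts.index.isin(inc["beneficiary_id"])]
    share_multi = (with_dx >= 2).mean()
    assert share_multi == pytest.approx(0.66, abs=0.08)
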