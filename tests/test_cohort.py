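"""Cohort construction: incidence, prevalence, long-term rule, duration."""
import itertools

import numpy as np
import pandas as pd
import pytest

from claimscope import cohort
from claimscope.quarters import quarter_label, quarter_range

from conftest import make_claims

START, END = "2000-10-01", "2007-09-30"


class TestIncident:
    def test_washout_claim_excludes_beneficiary(self):
        claims = make_claims([("B1", "2000-08-15", "N05AX08", 30),
                              ("B1", "2001-02-01", "N05AX08", 30)])
        out = cohort.identify_incident(claims, START, END)
        assert out.empty

    def test_single_claim_is_incident(self):
        claims = make_claims([("B1", "2003-05-01", "N05AX08", 30)])
        out = cohort.identify_incident(claims, START, END)
        assert out["incident_date"].iloc[0] == pd.Timestamp("2003-05-01")

    def test_earliest_claim_wins(self):
        claims = make_claims([("B1", "2002-03-01", "N05AH03", 30),
                              ("B1", "2002-01-10", "N05AX08", 30)])
        out = cohort.identify_incident(claims, START, END)
        assert out["incident_date"].iloc[0] == pd.Timestamp("2002-01-10")
        assert out["atc"].iloc[0] == "N05AX08"

    def test_rejects_degenerate_window(self):
        with pytest.raises(ValueError):
            cohort.identify_incident(make_claims([]), END, START)

    def test_washout_is_182_days_by_default(self):
        # a fill just before the washout boundary does not exclude
        claims = make_claims([("B1", "2000-03-31", "N05AX08", 30),
                              ("B1", "2001-02-01", "N05AX08", 30)])
        out = cohort.identify_incident(claims, START, END)
        assert len(out) == 1


class TestPrevalence:
    def test_october_fill_lands_in_q3(self):
        claims = make_claims([("B1", "2000-11-15", "N05AX08", 100)])
        prev = cohort.prevalent_by_quarter(claims, START, END)
        assert "B1" in prev["2000Q3"]
        # dispensing-based: a 100-day supply does not roll into 2000Q4
        assert "B1" not in prev["2000Q4"]

    def test_quarter_labels_span_study(self):
        labels = quarter_range(START, END)
        assert labels[0] == "2000Q3" and labels[-1] == "2007Q2"
        assert len(labels) == 28

    def test_fiscal_vs_calendar_labels(self):
        assert quarter_label("2001-01-15") == "2000Q4"
        assert quarter_label("2001-01-15", "calendar") == "2001Q1"

    def test_rate_arithmetic_and_undefined_flag(self):
        benef = pd.DataFrame({"id": [f"B{i}" for i in range(8000)]})
        elig = pd.DataFrame({"beneficiary_id": benef["id"],
                             "start_date": pd.Timestamp("2000-10-01"),
                             "end_date": pd.Timestamp("2000-12-31")})
        users = {"2000Q3": {f"B{i}" for i in range(40)},
                 "2000Q4": set()}
        out = cohort.rate_series(users, elig, benef)
        q3 = out[out["quarter"] == "2000Q3"].iloc[0]
        assert q3["rate"] == pytest.approx(5.0) and q3["denominator"] == 8000
        q4 = out[out["quarter"] == "2000Q4"].iloc[0]
        assert q4["undefined"] and np.isnan(q4["rate"])


def _oracle_long_term(dates, supplies, window=180, min_supply=90):
    """Brute force: any >=2-claim subset spanning <= window totalling >= min."""
    idx = range(len(dates))
    for r in range(2, len(dates) + 1):
        for combo in itertools.combinations(idx, r):
            ds = [dates[i] for i in combo]
            if (max(ds) - min(ds)).days <= window and \
                    sum(supplies[i] for i in combo) >= min_supply:
                return True
    return False


class TestLongTerm:
    @pytest.mark.parametrize("rows, expected", [
        ([(0, 50), (60, 45)], True),
        ([(0, 100)], False),            # a single fill never qualifies
        ([(0, 60), (200, 60)], False),  # span exceeds 180 days
        ([(0, 30), (90, 30), (180, 30)], True),
        ([(0, 30), (179, 30)], False),  # only 60 days supply in-window
    ])
    def test_examples(self, rows, expected):
        base = pd.Timestamp("2002-01-01")
        claims = make_claims([("B1", base + pd.Timedelta(days=d), "N05AX08", ds)
                              for d, ds in rows])
        assert cohort.classify_long_term(claims).is_long_term is expected

    def test_matches_brute_force_oracle_on_random_claim_sets(self):
        rng = np.random.default_rng(42)
        base = pd.Timestamp("2003-01-01")
        for _ in range(1000):
            n = int(rng.integers(1, 7))
            days = sorted(rng.integers(0, 500, size=n).tolist())
            supplies = rng.integers(1, 101, size=n).tolist()
            claims = make_claims([("B1", base + pd.Timedelta(days=d), "N05AX08", s)
                                  for d, s in zip(days, supplies)])
            got = cohort.classify_long_term(claims).is_long_term
            want = _oracle_long_term([base + pd.Timedelta(days=d) for d in days],
                                     supplies)
            assert got == want, (days, supplies)

    def test_reports_earliest_qualifying_window(self):
        base = pd.Timestamp("2002-01-01")
        claims = make_claims([("B1", base, "N05AX08", 50),
                              ("B1", base + pd.Timedelta(days=30), "N05AX08", 50),
                              ("B1", base + pd.Timedelta(days=300), "N05AX08", 90),
                              ("B1", base + pd.Timedelta(days=330), "N05AX08", 90)])
        flag = cohort.classify_long_term(claims)
        assert flag.qualifying_window[0] == base


class TestDuration:
    def test_short_membership_not_evaluable(self):
        claims = make_claims([("B1", "2002-01-01", "N05AX08", 30)])
        assert cohort.duration_of_use(claims, membership_days=200) is None

    def test_single_claim(self):
        claims = make_claims([("B1", "2002-01-01", "N05AX08", 30)])
        assert cohort.duration_of_use(claims, membership_days=400) == 30

    def test_first_to_last_plus_supply(self):
        claims = make_claims([("B1", "2002-01-01", "N05AX08", 30),
                              ("B1", "2002-09-28", "N05AX08", 30)])
        # 270 days apart + closing 30-day supply
        assert cohort.duration_of_use(claims, membership_days=400) == 300


class TestDistinctAndShares:
    @pytest.mark.parametrize("atcs, expected", [
        (["N05AX08", "N05AX08"], 1),
        (["N05AX08", "N05AH04"], 2),
        ([], 0),
    ])
    def test_count_distinct(self, atcs, expected, catalog):
        claims = make_claims([("B1", "2002-01-01", a, 30) for a in atcs])
        if claims.empty:
            claims = make_claims([]).reindex(columns=["beneficiary_id", "atc"])
        assert cohort.count_distinct_aps(claims, catalog) == expected

    def test_prescriber_shares_over_known_only(self):
        rows = (["general_practice"] * 646 + ["psychiatry"] * 144 +
                ["pediatrics"] * 31 + ["other"] * 77 + ["unknown"] * 829)
        incident = pd.DataFrame({"beneficiary_id": [f"B{i}" for i in range(len(rows))],
                                 "prescriber_specialty": rows})
        table, availability = cohort.prescriber_shares(incident)
        gp = table.set_index("specialty").loc["general_practice"]
        psych = table.set_index("specialty").loc["psychiatry"]
        assert gp["share_pct"] == pytest.approx(71.9, abs=0.05)
        assert round(gp["share_pct"]) == 72 and round(psych["share_pct"]) == 16
        assert availability == pytest.approx(898 / 1727)

    def test_all_unknown(self):
        incident = pd.DataFrame({"beneficiary_id": ["B1"],
                                 "prescriber_specialty": ["unknown"]})
        table, availability = cohort.prescriber_shares(incident)
        assert table.empty and availability == 0.0


def test_incident_users_subset_of_prevalent_union(small_data):
    ap = small_data.drug_claims[
        small_data.drug_claims["atc"].isin(small_data.catalog.codes)]
    inc = cohort.identify_incident(ap, START, END)
    prev = cohort.prevalent_by_quarter(ap, START, END)
    union = set().union(*prev.values())
    assert set(inc["beneficiary_id"]) <= union
    lt = cohort.classify_long_term_all(ap)
    multi = ap.groupby("beneficiary_id").size()
    lt_ids = set(lt.loc[lt["is_long_term"], "beneficiary_id"])
    assert lt_ids <= set(multi[multi >= 2].index)
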