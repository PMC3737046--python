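import logging

import pandas as pd
import pytest

from claimscope.catalogs import AtcCatalog, DiagnosisHierarchy
from claimscope.simulate import generate, reference_config

logging.getLogger("claimscope").setLevel(logging.ERROR)


@pytest.fixture(scope="session")
def catalog():
    return AtcCatalog.load()


@pytest.fixture(scope="session")
def hierarchy():
    return DiagnosisHierarchy.load()


@pytest.fixture(scope="session")
def small_data():
    """Scaled-down simulated linkage shared by read-only tests."""
    return generate(reference_config().replace(n_beneficiaries=6000), seed=11)


def make_claims(rows, **defaults):
    """Drug-claims frame from (beneficiary_id, date, atc, days_supply) tuples."""
    base = dict(din="X-ORAL", drug_name="drug", strength_mg_per_unit=1.0,
                quantity=30.0, amount_paid=10.0, copay=0.0,
                prescriber_specialty="unknown")
    base.update(defaults)
    recs = []
    for bid, date, atc, ds in rows:
        recs.append({"beneficiary_id": bid, "dispense_date": pd.Timestamp(date),
                     "atc": atc, "days_supply": ds, **base})
    return pd.DataFrame(recs)


def make_diagnoses(rows):
    """Diagnosis frame from (bid, date, code, version, source_db, provider)."""
    cols = ["beneficiary_id", "service_date", "code", "icd_version",
            "source_db", "provider"]
    recs = [{"beneficiary_id": b, "service_date": pd.Timestamp(d), "code": c,
             "icd_version": v, "source_db": s, "provider": p}
            for b, d, c, v, s, p in rows]
    return pd.DataFrame(recs, columns=cols)
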