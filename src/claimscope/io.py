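"""Readers, writers and validation for the five linked administrative tables.

The tables emulate a provincial drug-benefit linkage: a beneficiary
registry with eligibility spells, pharmacy claims, fee-for-service
physician billings carrying ICD-9 diagnoses, hospital discharge abstracts
carrying ICD-10 diagnoses, and vital-statistics death records.  All five
ship as UTF-8 CSV with ISO-8601 dates.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from .catalogs import AtcCatalog, DiagnosisHierarchy

logger = logging.getLogger(__name__)

SEXES = {"M", "F"}
SPECIALTIES = {
    "general_practice", "psychiatry", "pediatrics", "emergency",
    "internal_medicine", "neurology", "pediatric_neurology", "other", "unknown",
}
PROVIDERS = {"psychiatrist", "other_physician", "not_applicable"}
SOURCE_DBS = {"DAD", "MSI"}
MAX_DAYS_SUPPLY = 100  # program reimburses at most 100 days per fill

TABLE_COLUMNS = {
    "beneficiaries": ["id", "sex", "birth_date", "region"],
    "eligibility": ["beneficiary_id", "start_date", "end_date"],
    "drug_claims": [
        "beneficiary_id", "dispense_date", "atc", "din", "drug_name",
        "strength_mg_per_unit", "quantity", "days_supply", "amount_paid",
        "copay", "prescriber_specialty",
    ],
    "diagnoses": ["beneficiary_id", "service_date", "code", "icd_version",
                  "source_db", "provider"],
    "deaths": ["beneficiary_id", "death_date", "cause_code"],
}

_DATE_COLUMNS = {
    "beneficiaries": ["birth_date"],
    "eligibility": ["start_date", "end_date"],
    "drug_claims": ["dispense_date"],
    "diagnoses": ["service_date"],
    "deaths": ["death_date"],
}


class SchemaError(ValueError):
    """A table violates its column schema or a field invariant."""

    def __init__(self, table: str, column: str, message: str, rows=None):
        self.table, self.column, self.rows = table, column, rows
        detail = f" (rows {rows[:5]}{'...' if rows and len(rows) > 5 else ''})" if rows else ""
        super().__init__(f"{table}.{column}: {message}{detail}")


class IntegrityError(ValueError):
    """Cross-table referential integrity failure."""


@dataclass
class LinkedData:
    """In-memory bundle of the five linked tables plus reference catalogs."""

    beneficiaries: pd.DataFrame
    eligibility: pd.DataFrame
    drug_claims: pd.DataFrame
    diagnoses: pd.DataFrame
    deaths: pd.DataFrame
    catalog: AtcCatalog = field(default_factory=AtcCatalog.load)
    hierarchy: DiagnosisHierarchy = field(default_factory=DiagnosisHierarchy.load)

    def tables(self):
        return {
            "beneficiaries": self.beneficiaries,
            "eligibility": self.eligibility,
            "drug_claims": self.drug_claims,
            "diagnoses": self.diagnoses,
            "deaths": self.deaths,
        }

    @property
    def n_records(self) -> int:
        return sum(len(t) for t in self.tables().values())


def _bad_rows(mask: pd.Series) -> list[int]:
    return mask[mask].index.tolist()


def _validate_table(name: str, df: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in TABLE_COLUMNS[name] if c not in df.columns]
    if missing:
        raise SchemaError(name, missing[0], "missing column")
    df = df[TABLE_COLUMNS[name]].copy()
    for col in _DATE_COLUMNS[name]:
        parsed = pd.to_datetime(df[col], format="%Y-%m-%d", errors="coerce")
        bad = parsed.isna() & df[col].notna()
        if bad.any():
            raise SchemaError(name, col, "unparseable ISO date", _bad_rows(bad))
        df[col] = parsed
    return df


def validate_beneficiaries(df: pd.DataFrame, study_end=None) -> pd.DataFrame:
    df = _validate_table("beneficiaries", df)
    if df["id"].duplicated().any():
        raise SchemaError("beneficiaries", "id", "duplicate ids",
                          _bad_rows(df["id"].duplicated()))
    bad_sex = ~df["sex"].isin(SEXES)
    if bad_sex.any():
        raise SchemaError("beneficiaries", "sex", "must be M or F", _bad_rows(bad_sex))
    if study_end is not None:
        late = df["birth_date"] > pd.Timestamp(study_end)
        if late.any():
            raise SchemaError("beneficiaries", "birth_date", "after study end",
                              _bad_rows(late))
    return df


def validate_eligibility(df: pd.DataFrame) -> pd.DataFrame:
    df = _validate_table("eligibility", df)
    bad = df["start_date"] > df["end_date"]
    if bad.any():
        raise SchemaError("eligibility", "start_date", "start after end", _bad_rows(bad))
    srt = df.sort_values(["beneficiary_id", "start_date"])
    prev_end = srt.groupby("beneficiary_id")["end_date"].shift()
    overlap = srt["start_date"] <= prev_end
    if overlap.any():
        raise SchemaError("eligibility", "start_date", "overlapping spells",
                          _bad_rows(overlap))
    return df


def validate_drug_claims(df: pd.DataFrame) -> pd.DataFrame:
    df = _validate_table("drug_claims", df)
    for col in ("strength_mg_per_unit", "quantity", "days_supply",
                "amount_paid", "copay"):
        df[col] = pd.to_numeric(df[col], errors="coerce")
        if df[col].isna().any():
            raise SchemaError("drug_claims", col, "non-numeric", _bad_rows(df[col].isna()))
    bad = (df["days_supply"] < 1) | (df["days_supply"] > MAX_DAYS_SUPPLY)
    if bad.any():
        raise SchemaError("drug_claims", "days_supply",
                          f"must be in [1, {MAX_DAYS_SUPPLY}]", _bad_rows(bad))
    df["days_supply"] = df["days_supply"].astype(int)
    for col, msg in (("strength_mg_per_unit", "must be positive"),
                     ("quantity", "must be positive")):
        bad = df[col] <= 0
        if bad.any():
            raise SchemaError("drug_claims", col, msg, _bad_rows(bad))
    bad = (df["amount_paid"] < 0) | (df["copay"] < 0)
    if bad.any():
        raise SchemaError("drug_claims", "amount_paid", "negative currency", _bad_rows(bad))
    bad = df["copay"] > df["amount_paid"] + 1e-9
    if bad.any():
        raise SchemaError("drug_claims", "copay", "copay exceeds amount paid", _bad_rows(bad))
    bad = ~df["prescriber_specialty"].isin(SPECIALTIES)
    if bad.any():
        raise SchemaError("drug_claims", "prescriber_specialty",
                          f"must be one of {sorted(SPECIALTIES)}", _bad_rows(bad))
    return df


def validate_diagnoses(df: pd.DataFrame, strict_source_versions: bool = True) -> pd.DataFrame:
    df = _validate_table("diagnoses", df)
    df["icd_version"] = pd.to_numeric(df["icd_version"], errors="coerce")
    bad = ~df["icd_version"].isin([9, 10])
    if bad.any():
        raise SchemaError("diagnoses", "icd_version", "must be 9 or 10", _bad_rows(bad))
    df["icd_version"] = df["icd_version"].astype(int)
    bad = ~df["source_db"].isin(SOURCE_DBS)
    if bad.any():
        raise SchemaError("diagnoses", "source_db", "must be DAD or MSI", _bad_rows(bad))
    bad = ~df["provider"].isin(PROVIDERS)
    if bad.any():
        raise SchemaError("diagnoses", "provider",
                          f"must be one of {sorted(PROVIDERS)}", _bad_rows(bad))
    if strict_source_versions:
        bad = (df["source_db"] == "DAD") & (
            (df["icd_version"] != 10) | (df["provider"] != "not_applicable"))
        if bad.any():
            raise SchemaError("diagnoses", "source_db",
                              "DAD records must be ICD-10 with provider not_applicable",
                              _bad_rows(bad))
        bad = (df["source_db"] == "MSI") & (df["icd_version"] != 9)
        if bad.any():
            raise SchemaError("diagnoses", "source_db", "MSI records must be ICD-9",
                              _bad_rows(bad))
    return df


def validate_deaths(df: pd.DataFrame) -> pd.DataFrame:
    df = _validate_table("deaths", df)
    dup = df["beneficiary_id"].duplicated()
    if dup.any():
        raise SchemaError("deaths", "beneficiary_id", "more than one death record",
                          _bad_rows(dup))
    return df


def load_linked_data(paths: dict, catalog: AtcCatalog | None = None,
                     hierarchy: DiagnosisHierarchy | None = None,
                     strict_source_versions: bool = True,
                     study_end=None) -> LinkedData:
    """Read, validate and cross-link the five CSV tables.

    ``paths`` maps table name (beneficiaries, eligibility, drug_claims,
    diagnoses, deaths) to a file location.  Referential integrity is
    enforced: every beneficiary_id in a satellite table must exist in the
    registry.
    """
    raw = {}
    for name in TABLE_COLUMNS:
        p = Path(paths[name])
        if not p.exists():
            raise FileNotFoundError(f"{name} table not found: {p}")
        raw[name] = pd.read_csv(p, dtype=str)

    benef = validate_beneficiaries(raw["beneficiaries"], study_end=study_end)
    elig = validate_eligibility(raw["eligibility"])
    claims = validate_drug_claims(raw["drug_claims"])
    dx = validate_diagnoses(raw["diagnoses"], strict_source_versions=strict_source_versions)
    deaths = validate_deaths(raw["deaths"])

    known = set(benef["id"])
    for name, df in (("eligibility", elig), ("drug_claims", claims),
                     ("diagnoses", dx), ("deaths", deaths)):
        orphans = set(df["beneficiary_id"]) - known
        if orphans:
            raise IntegrityError(
                f"{name}: beneficiary_id not in registry: {sorted(orphans)[:5]}")

    data = LinkedData(
        beneficiaries=benef, eligibility=elig, drug_claims=claims,
        diagnoses=dx, deaths=deaths,
        catalog=catalog or AtcCatalog.load(),
        hierarchy=hierarchy or DiagnosisHierarchy.load(),
    )
    logger.info("loaded linked data: %s",
                {k: len(v) for k, v in data.tables().items()})
    return data


def write_linked_data(data: LinkedData, out_dir) -> dict:
    """Write the five tables as CSV; returns the path map (load-compatible)."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {}
    for name, df in data.tables().items():
        df = df.copy()
        for col in _DATE_COLUMNS[name]:
            df[col] = pd.to_datetime(df[col]).dt.strftime("%Y-%m-%d")
        if name == "drug_claims":
            for col in ("amount_paid", "copay"):
                df[col] = df[col].map(lambda v: f"{v:.2f}")
        p = out / f"{name}.csv"
        df.to_csv(p, index=False, lineterminator="\n")
        paths[name] = p
    return paths
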