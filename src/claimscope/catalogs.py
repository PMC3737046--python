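"""Reference catalogs: antipsychotic ATC codes, the attributable-diagnosis
hierarchy, psychotropic class map, comorbidity targets and dose equivalences.

The packaged files mirror the study's drug table (17 antipsychotics, three
of them second-generation) and its ten-level diagnostic hierarchy running
from psychotic disorders (level 1, highest priority) down to a residual
"other" category (level 10).  All catalogs can be replaced by user files
with the same columns.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field
from importlib import resources

import pandas as pd

logger = logging.getLogger(__name__)

SGA_CODES = frozenset({"N05AH03", "N05AH04", "N05AX08"})

#: Multiplicative ratios converting a daily dose to olanzapine milligrams.
OLANZAPINE_EQUIVALENCE = {
    "haloperidol": 2.0,
    "loxapine": 0.33,
    "quetiapine": 0.027,
    "risperidone": 3.33,
    "olanzapine": 1.0,
}


def _packaged(name: str) -> pd.DataFrame:
    with resources.files("claimscope.data").joinpath(name).open("rb") as fh:
        return pd.read_csv(fh, dtype=str)


@dataclass(frozen=True)
class AtcCatalog:
    """Antipsychotic drug catalog keyed by 7-level ATC code."""

    entries: dict  # atc -> (drug_name, generation, frozenset of formulations)

    @classmethod
    def load(cls, path=None) -> "AtcCatalog":
        df = _packaged("atc_antipsychotics.csv") if path is None else pd.read_csv(path, dtype=str)
        entries = {
            r.atc: (r.drug_name, r.generation, frozenset(r.formulations.split("|")))
            for r in df.itertuples()
        }
        return cls(entries=entries)

    @property
    def codes(self) -> frozenset:
        return frozenset(self.entries)

    def drug_name(self, atc: str) -> str:
        return self.entries[atc][0]

    def generation(self, atc: str) -> str:
        return self.entries[atc][1]

    def has_long_acting(self, atc: str) -> bool:
        return "lai" in self.entries[atc][2]


def classify_atc(atc: str, catalog: AtcCatalog) -> tuple[str, str] | None:
    """Exact-match lookup of an ATC code; None for non-antipsychotics."""
    entry = catalog.entries.get(atc)
    if entry is None:
        return None
    return entry[0], entry[1]


def _strip(code: str) -> str:
    return str(code).replace(".", "").strip().upper()


@dataclass(frozen=True)
class DiagnosisHierarchy:
    """Ten-level most-attributable-diagnosis hierarchy.

    Level 1 (non-affective psychotic disorders) outranks level 2 (bipolar)
    and so on down to level 10 (substance use, learning disability, other).
    Codes are matched by longest prefix with dots stripped, so "296.2" and
    "2962" are equivalent; a prefix listed under two levels resolves to the
    lower level number (higher priority) with a logged warning.
    """

    names: dict = field(default_factory=dict)          # level -> category name
    prefixes: dict = field(default_factory=dict)       # (version, stripped prefix) -> level

    @classmethod
    def load(cls, path=None) -> "DiagnosisHierarchy":
        df = _packaged("diagnosis_hierarchy.csv") if path is None else pd.read_csv(path, dtype=str)
        names: dict[int, str] = {}
        prefixes: dict[tuple[int, str], int] = {}
        for r in df.itertuples():
            level = int(r.level)
            names.setdefault(level, r.category)
            key = (int(r.icd_version), _strip(r.prefix))
            if key in prefixes and prefixes[key] != level:
                keep = min(prefixes[key], level)
                logger.warning(
                    "ICD-%s prefix %s listed at levels %d and %d; keeping %d",
                    key[0], r.prefix, prefixes[key], level, keep,
                )
                prefixes[key] = keep
            else:
                prefixes.setdefault(key, level)
        return cls(names=names, prefixes=prefixes)

    @property
    def levels(self) -> list[int]:
        return sorted(self.names)

    def iter_prefixes(self):
        """(version, prefix, level) triples after duplicate resolution."""
        for (version, prefix), level in self.prefixes.items():
            yield version, prefix, level


def classify_icd(code: str, version: int, hierarchy: DiagnosisHierarchy) -> int | None:
    """Resolve an ICD code to its hierarchy level by longest-prefix match."""
    if version not in (9, 10):
        raise ValueError(f"icd_version must be 9 or 10, got {version!r}")
    stripped = _strip(code)
    if not stripped:
        raise ValueError("empty ICD code")
    for cut in range(len(stripped), 0, -1):
        level = hierarchy.prefixes.get((version, stripped[:cut]))
        if level is not None:
            return level
    return None


@dataclass(frozen=True)
class PsychotropicClassMap:
    """Psychotropic co-medication classes as ATC prefix sets."""

    prefixes: dict  # class -> tuple of ATC prefixes

    @classmethod
    def load(cls, path=None) -> "PsychotropicClassMap":
        df = _packaged("psychotropic_classes.csv") if path is None else pd.read_csv(path, dtype=str)
        out: dict[str, list[str]] = {}
        for cls_name, prefix in zip(df["class"], df["atc_prefix"]):
            out.setdefault(cls_name, []).append(prefix)
        return cls(prefixes={k: tuple(v) for k, v in out.items()})

    @property
    def classes(self) -> list[str]:
        return sorted(self.prefixes)

    def classify(self, atc: str, exclude: frozenset = frozenset()) -> str | None:
        if atc in exclude:
            return None
        for cls_name, prefs in self.prefixes.items():
            if any(atc.startswith(p) for p in prefs):
                return cls_name
        return None


@dataclass(frozen=True)
class ComorbidityTargets:
    """Non-psychiatric comorbidity conditions as ICD prefix sets."""

    prefixes: dict  # condition -> {version: tuple of stripped prefixes}

    @classmethod
    def load(cls, path=None) -> "ComorbidityTargets":
        df = _packaged("comorbidity_targets.csv") if path is None else pd.read_csv(path, dtype=str)
        out: dict[str, dict[int, list[str]]] = {}
        for r in df.itertuples():
            out.setdefault(r.condition, {9: [], 10: []})[int(r.icd_version)].append(_strip(r.prefix))
        return cls(prefixes={c: {v: tuple(p) for v, p in d.items()} for c, d in out.items()})

    @property
    def conditions(self) -> list[str]:
        return sorted(self.prefixes)

    def matches(self, code: str, version: int, condition: str) -> bool:
        stripped = _strip(code)
        return any(stripped.startswith(p) for p in self.prefixes[condition].get(version, ()))
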