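"""Curation of symptom-coded inpatient admission records.

Raw admission records carry free-text-derived term lists (symptoms, tongue
and pulse findings, diagnoses, herbs). Curation maps every raw term to a
canonical vocabulary through a term dictionary, de-duplicates, rolls up
ICD codes to their category plus one post-decimal character, and applies
the cohort inclusion/exclusion rules:

1. records lacking a patient id, diagnostic information, or discharge
   information are removed;
2. when a patient has several admissions, only the most complete one is
   kept (completeness = count of populated fields; ties broken by latest
   admission date, then admission id).
"""

from __future__ import annotations

import datetime as _dt
from collections import Counter
from dataclasses import dataclass, field, replace
from enum import Enum
from typing import Iterable, Mapping, Sequence

from .errors import ClassificationError, NormalizationError

__all__ = [
    "FeatureClass",
    "RawRecord",
    "PatientRecord",
    "TermDictionary",
    "CurationReport",
    "normalize_terms",
    "rollup_icd",
    "completeness_score",
    "apply_inclusion_exclusion",
    "curate",
    "FIELD_CLASSES",
    "COMPLETENESS_FIELDS",
]


class FeatureClass(str, Enum):
    SYMPTOM = "symptom"
    TONGUE = "tongue"
    PULSE = "pulse"
    DIAGNOSIS = "diagnosis"
    HERB = "herb"


#: term-list fields of a record -> feature class their terms must belong to
FIELD_CLASSES: dict[str, FeatureClass] = {
    "main_symptoms": FeatureClass.SYMPTOM,
    "general_symptoms": FeatureClass.SYMPTOM,
    "tongue_features": FeatureClass.TONGUE,
    "pulse_features": FeatureClass.PULSE,
    "tcm_diagnoses": FeatureClass.DIAGNOSIS,
    "herbs": FeatureClass.HERB,
    "discharge_symptoms": FeatureClass.SYMPTOM,
}

#: the ten fields counted by completeness_score
COMPLETENESS_FIELDS = (
    "main_symptoms",
    "general_symptoms",
    "tongue_features",
    "pulse_features",
    "tcm_diagnoses",
    "herbs",
    "discharge_symptoms",
    "outcome",
    "age",
    "sex",
)

OUTCOMES = ("improvement", "discharge", "death", "other")


@dataclass
class RawRecord:
    """One hospitalization as parsed from the input file, terms un-normalized."""

    patient_id: str
    admission_id: str
    admission_date: _dt.date | None = None
    age: int | None = None
    sex: str = ""
    main_symptoms: list[str] = field(default_factory=list)
    general_symptoms: list[str] = field(default_factory=list)
    tongue_features: list[str] = field(default_factory=list)
    pulse_features: list[str] = field(default_factory=list)
    tcm_diagnoses: list[str] = field(default_factory=list)
    icd_codes: list[str] = field(default_factory=list)
    herbs: list[str] = field(default_factory=list)
    discharge_symptoms: list[str] = field(default_factory=list)
    outcome: str = ""


@dataclass
class PatientRecord:
    """A curated hospitalization: every term list replaced by a canonical set."""

    patient_id: str
    admission_id: str
    admission_date: _dt.date | None = None
    age: int | None = None
    sex: str = ""
    main_symptoms: frozenset[str] = frozenset()
    general_symptoms: frozenset[str] = frozenset()
    tongue_features: frozenset[str] = frozenset()
    pulse_features: frozenset[str] = frozenset()
    tcm_diagnoses: frozenset[str] = frozenset()
    icd_rollup: frozenset[str] = frozenset()
    herbs: frozenset[str] = frozenset()
    discharge_symptoms: frozenset[str] = frozenset()
    outcome: str = ""

    @property
    def admission_symptoms(self) -> frozenset[str]:
        """Symptoms at admission: chief complaint plus present-illness history."""
        return self.main_symptoms | self.general_symptoms


class TermDictionary:
    """Raw-term -> (canonical term, feature class) mapping.

    Canonical terms themselves are always accepted (normalization is
    idempotent); a raw term has exactly one canonical target.
    """

    def __init__(self, entries: Mapping[str, tuple[str, FeatureClass]]):
        self.entries: dict[str, tuple[str, FeatureClass]] = {}
        for raw, (canon, cls) in entries.items():
            cls = FeatureClass(cls)
            if not canon:
                raise ValueError(f"empty canonical term for raw term {raw!r}")
            self.entries[raw] = (canon, cls)
        # canonical vocabulary per class; canonical terms map to themselves
        self.canonical: dict[FeatureClass, set[str]] = {c: set() for c in FeatureClass}
        for canon, cls in self.entries.values():
            self.canonical[cls].add(canon)
            self.entries.setdefault(canon, (canon, cls))

    def lookup(self, raw: str) -> tuple[str, FeatureClass] | None:
        return self.entries.get(raw)

    def __len__(self) -> int:
        return len(self.entries)


@dataclass
class CurationReport:
    """Audit of the inclusion/exclusion filters and term normalization."""

    n_input: int = 0
    n_excluded_missing: int = 0
    n_excluded_duplicate_admissions: int = 0
    n_included: int = 0
    unmapped_terms: list[tuple[str, int]] = field(default_factory=list)

    def validate(self) -> None:
        total = (
            self.n_included
            + self.n_excluded_missing
            + self.n_excluded_duplicate_admissions
        )
        if total != self.n_input:
            raise ValueError(
                f"report counts do not conserve: {total} != n_input {self.n_input}"
            )

    def to_dict(self) -> dict:
        return {
            "n_input": self.n_input,
            "n_excluded_missing": self.n_excluded_missing,
            "n_excluded_duplicate_admissions": self.n_excluded_duplicate_admissions,
            "n_included": self.n_included,
            "unmapped_terms": [list(t) for t in self.unmapped_terms],
        }


def rollup_icd(codes: Iterable[str]) -> frozenset[str]:
    """Truncate each ICD code to its category plus at most one character
    after the decimal point; codes without a decimal pass through.

    ``{"I50.903", "I50.905"} -> {"I50.9"}``
    """
    rolled = set()
    for code in codes:
        if "." in code:
            head, _, tail = code.partition(".")
            rolled.add(f"{head}.{tail[:1]}" if tail else head)
        else:
            rolled.add(code)
    return frozenset(rolled)


def _normalize_field(
    terms: Sequence[str],
    expected: FeatureClass,
    dictionary: TermDictionary,
    policy: str,
    unmapped: Counter,
    field_name: str,
) -> frozenset[str]:
    out: set[str] = set()
    for raw in terms:
        hit = dictionary.lookup(raw)
        if hit is None:
            if policy == "strict":
                raise NormalizationError(
                    f"unmapped term {raw!r} in field {field_name!r}"
                )
            unmapped[raw] += 1
            continue
        canon, cls = hit
        if cls is not expected:
            raise ClassificationError(
                f"term {raw!r} maps to class {cls.value!r}, "
                f"but field {field_name!r} expects {expected.value!r}"
            )
        out.add(canon)
    return frozenset(out)


def normalize_terms(
    record: RawRecord,
    dictionary: TermDictionary,
    policy: str = "drop_unknown",
    unmapped: Counter | None = None,
) -> PatientRecord:
    """Map every raw term of a record to its canonical form and de-duplicate.

    Under ``strict`` an unmapped term raises :class:`NormalizationError`;
    under ``drop_unknown`` it is dropped and tallied into *unmapped*.
    """
    if policy not in ("strict", "drop_unknown"):
        raise ValueError(f"unknown policy {policy!r}")
    counter = unmapped if unmapped is not None else Counter()
    kwargs = {
        name: _normalize_field(
            getattr(record, name), cls, dictionary, policy, counter, name
        )
        for name, cls in FIELD_CLASSES.items()
    }
    return PatientRecord(
        patient_id=record.patient_id,
        admission_id=record.admission_id,
        admission_date=record.admission_date,
        age=record.age,
        sex=record.sex,
        icd_rollup=rollup_icd(record.icd_codes),
        outcome=record.outcome,
        **kwargs,
    )


def _is_empty(value) -> bool:
    if value is None:
        return True
    if isinstance(value, (list, set, frozenset, tuple, str)):
        return len(value) == 0
    return False


def completeness_score(record: RawRecord | PatientRecord) -> int:
    """Count of populated fields among the ten completeness-relevant ones."""
    return sum(0 if _is_empty(getattr(record, f)) else 1 for f in COMPLETENESS_FIELDS)


def _has_required_information(record: RawRecord) -> bool:
    if _is_empty(record.patient_id):
        return False
    # diagnostic information: a TCM diagnosis or an ICD code
    if _is_empty(record.tcm_diagnoses) and _is_empty(record.icd_codes):
        return False
    # discharge information: discharge symptoms or an outcome
    if _is_empty(record.discharge_symptoms) and _is_empty(record.outcome):
        return False
    return True


def _dedup_key(record: RawRecord) -> tuple:
    date = record.admission_date or _dt.date.min
    return (completeness_score(record), date, record.admission_id)


def apply_inclusion_exclusion(
    records: Sequence[RawRecord],
) -> tuple[list[RawRecord], CurationReport]:
    """Drop incomplete records, then keep one admission per patient.

    Deterministic in input order: the per-patient winner maximizes
    (completeness, admission date, admission id), a total order.
    """
    report = CurationReport(n_input=len(records))
    complete = [r for r in records if _has_required_information(r)]
    report.n_excluded_missing = len(records) - len(complete)

    best: dict[str, RawRecord] = {}
    for rec in complete:
        cur = best.get(rec.patient_id)
        if cur is None or _dedup_key(rec) > _dedup_key(cur):
            best[rec.patient_id] = rec
    report.n_excluded_duplicate_admissions = len(complete) - len(best)

    kept = sorted(best.values(), key=lambda r: (r.patient_id, r.admission_id))
    report.n_included = len(kept)
    report.validate()
    return kept, report


def curate(
    records: Sequence[RawRecord],
    dictionary: TermDictionary,
    policy: str = "drop_unknown",
) -> tuple[list[PatientRecord], CurationReport]:
    """Inclusion/exclusion followed by term normalization, with one report."""
    kept, report = apply_inclusion_exclusion(records)
    unmapped: Counter = Counter()
    curated = [normalize_terms(r, dictionary, policy, unmapped) for r in kept]
    report.unmapped_terms = sorted(unmapped.items(), key=lambda kv: (-kv[1], kv[0]))
    return curated, report


def already_canonical(record: PatientRecord, dictionary: TermDictionary) -> bool:
    """True if every term of *record* is in the canonical vocabulary."""
    for name, cls in FIELD_CLASSES.items():
        if not set(getattr(record, name)) <= dictionary.canonical[cls]:
            return False
    return True


def record_to_raw(record: PatientRecord) -> RawRecord:
    """View a curated record as a raw one (used for idempotence checks)."""
    return RawRecord(
        patient_id=record.patient_id,
        admission_id=record.admission_id,
        admission_date=record.admission_date,
        age=record.age,
        sex=record.sex,
        main_symptoms=sorted(record.main_symptoms),
        general_symptoms=sorted(record.general_symptoms),
        tongue_features=sorted(record.tongue_features),
        pulse_features=sorted(record.pulse_features),
        tcm_diagnoses=sorted(record.tcm_diagnoses),
        icd_codes=sorted(record.icd_rollup),
        herbs=sorted(record.herbs),
        discharge_symptoms=sorted(record.discharge_symptoms),
        outcome=record.outcome,
    )


def replace_record(record: PatientRecord, **changes) -> PatientRecord:
    return replace(record, **changes)
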