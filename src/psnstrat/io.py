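"""Readers and writers for the plain-text interchange formats.

Admission records travel as CSV (list fields joined by ``|``) or JSON
lines (list fields as arrays); the term dictionary is a 3-column TSV
``raw_term<TAB>canonical_term<TAB>feature_class``; reports and profiles
are JSON.
"""

from __future__ import annotations

import csv
import datetime as _dt
import json
from pathlib import Path
from typing import Iterable, Sequence

from ._utils import dump_json
from .curation import CurationReport, FeatureClass, RawRecord, TermDictionary
from .errors import InputError

RECORD_COLUMNS = [
    "patient_id",
    "admission_id",
    "admission_date",
    "age",
    "sex",
    "main_symptoms",
    "general_symptoms",
    "tongue_features",
    "pulse_features",
    "tcm_diagnoses",
    "icd_codes",
    "herbs",
    "discharge_symptoms",
    "outcome",
]

_LIST_FIELDS = [c for c in RECORD_COLUMNS if c.endswith("s") and c != "age"]
_LIST_FIELDS = [
    "main_symptoms",
    "general_symptoms",
    "tongue_features",
    "pulse_features",
    "tcm_diagnoses",
    "icd_codes",
    "herbs",
    "discharge_symptoms",
]


def _parse_date(text: str | None) -> _dt.date | None:
    if not text:
        return None
    try:
        return _dt.date.fromisoformat(text)
    except ValueError as exc:
        raise InputError(f"unparseable admission_date {text!r}") from exc


def _record_from_row(row: dict) -> RawRecord:
    lists = {}
    for name in _LIST_FIELDS:
        value = row.get(name) or []
        if isinstance(value, str):
            value = [t for t in value.split("|") if t]
        lists[name] = list(value)
    age = row.get("age")
    if age in (None, ""):
        age_val = None
    else:
        age_val = int(age)
    return RawRecord(
        patient_id=str(row.get("patient_id") or ""),
        admission_id=str(row.get("admission_id") or ""),
        admission_date=_parse_date(row.get("admission_date") or None),
        age=age_val,
        sex=str(row.get("sex") or ""),
        outcome=str(row.get("outcome") or ""),
        **lists,
    )


def read_records(path: str | Path) -> list[RawRecord]:
    """Dispatch on extension: ``.csv`` or ``.jsonl``/``.ndjson``."""
    path = Path(path)
    if not path.exists():
        raise InputError(f"records file not found: {path}")
    if path.suffix.lower() == ".csv":
        return read_records_csv(path)
    return read_records_jsonl(path)


def read_records_csv(path: str | Path) -> list[RawRecord]:
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        return [_record_from_row(row) for row in reader]


def read_records_jsonl(path: str | Path) -> list[RawRecord]:
    records = []
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            line = line.strip()
            if line:
                records.append(_record_from_row(json.loads(line)))
    return records


def _row_from_record(record: RawRecord) -> dict:
    return {
        "patient_id": record.patient_id,
        "admission_id": record.admission_id,
        "admission_date": record.admission_date.isoformat()
        if record.admission_date
        else "",
        "age": "" if record.age is None else record.age,
        "sex": record.sex,
        "outcome": record.outcome,
        **{name: "|".join(getattr(record, name)) for name in _LIST_FIELDS},
    }


def write_records_csv(records: Sequence[RawRecord], path: str | Path) -> None:
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.DictWriter(fh, fieldnames=RECORD_COLUMNS)
        writer.writeheader()
        for record in records:
            writer.writerow(_row_from_record(record))


def write_records_jsonl(records: Sequence[RawRecord], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for record in records:
            row = _row_from_record(record)
            for name in _LIST_FIELDS:
                row[name] = list(getattr(record, name))
            fh.write(json.dumps(row, ensure_ascii=False, sort_keys=True) + "\n")


def read_term_dictionary(path: str | Path) -> TermDictionary:
    path = Path(path)
    if not path.exists():
        raise InputError(f"term dictionary not found: {path}")
    entries: dict[str, tuple[str, FeatureClass]] = {}
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 3:
                raise InputError(
                    f"{path}:{lineno}: expected 3 tab-separated columns"
                )
            raw, canon, cls = parts
            try:
                entries[raw] = (canon, FeatureClass(cls))
            except ValueError as exc:
                raise InputError(
                    f"{path}:{lineno}: unknown feature class {cls!r}"
                ) from exc
    return TermDictionary(entries)


def write_term_dictionary(dictionary: TermDictionary, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for raw in sorted(dictionary.entries):
            canon, cls = dictionary.entries[raw]
            fh.write(f"{raw}\t{canon}\t{cls.value}\n")


def write_curation_report(report: CurationReport, path: str | Path) -> None:
    dump_json(report.to_dict(), path)


def write_labels_tsv(labels: dict[str, int], path: str | Path) -> None:
    """Two-column TSV of id -> integer label (truth labels, partitions)."""
    with open(path, "w", encoding="utf-8") as fh:
        for key in sorted(labels):
            fh.write(f"{key}\t{labels[key]}\n")


def read_labels_tsv(path: str | Path) -> dict[str, int]:
    path = Path(path)
    if not path.exists():
        raise InputError(f"labels file not found: {path}")
    labels: dict[str, int] = {}
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            line = line.rstrip("\n")
            if line:
                key, value = line.split("\t")
                labels[key] = int(value)
    return labels


def iter_nonempty(values: Iterable[str]) -> Iterable[str]:
    return (v for v in values if v)
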