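"""Admission-vs-discharge symptom comparison per module.

A symptom is *resolved* for a patient when it is present in the
admission symptom universe (chief complaint plus present-illness
history) and absent from the discharge record of the same
hospitalization. Resolution rates are reported per (module, symptom)
with a minimum support to suppress unstable rates, and each module can
be profiled jointly with its significant enrichment features.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

from .communities import Partition
from .curation import FeatureClass, PatientRecord
from .enrichment import EnrichmentResult, enrich

__all__ = [
    "ResolutionResult",
    "symptom_resolution",
    "module_profile",
    "write_resolution_csv",
    "plot_resolution",
]

logger = logging.getLogger(__name__)


@dataclass
class ResolutionResult:
    module: int
    symptom: str
    n_admission: int
    n_resolved: int

    @property
    def resolution_rate(self) -> float:
        return self.n_resolved / self.n_admission


def _has_discharge_data(record: PatientRecord) -> bool:
    # an empty discharge symptom set is data (everything resolved) as long
    # as the discharge record itself exists, signalled by a recorded outcome
    return bool(record.outcome) or bool(record.discharge_symptoms)


def symptom_resolution(
    records: Sequence[PatientRecord],
    partition: Partition,
    min_support: int = 5,
) -> list[ResolutionResult]:
    """Per-(module, symptom) resolution counts over patients with
    discharge data, sorted within module by descending resolved count
    then descending rate."""
    by_id = {r.patient_id: r for r in records}
    counts: dict[tuple[int, str], list[int]] = {}
    n_skipped = 0
    for pid, mod in partition.assignment.items():
        record = by_id.get(pid)
        if record is None:
            continue
        if not _has_discharge_data(record):
            n_skipped += 1
            continue
        for symptom in record.admission_symptoms:
            cell = counts.setdefault((mod, symptom), [0, 0])
            cell[0] += 1
            if symptom not in record.discharge_symptoms:
                cell[1] += 1
    if n_skipped:
        logger.info("skipped %d records without discharge data", n_skipped)

    results = [
        ResolutionResult(module=mod, symptom=sym, n_admission=na, n_resolved=nr)
        for (mod, sym), (na, nr) in counts.items()
        if na >= min_support
    ]
    results.sort(
        key=lambda r: (r.module, -r.n_resolved, -r.resolution_rate, r.symptom)
    )
    return results


def module_profile(
    records: Sequence[PatientRecord],
    partition: Partition,
    module_id: int,
    alpha: float = 0.05,
    top_k: int = 10,
    min_support: int = 5,
) -> dict:
    """Bundle one module's top significant features of every class with
    its symptom-resolution ranking into a single JSON-ready document."""
    if module_id not in set(partition.assignment.values()):
        raise KeyError(f"unknown module id {module_id}")

    sections: dict[str, list[dict]] = {}
    for cls in FeatureClass:
        rows = [
            r
            for r in enrich(records, partition, cls, alpha=alpha)
            if r.module == module_id and r.significant
        ]
        sections[cls.value] = [
            {
                "feature": r.feature,
                "rr": r.rr,
                "chi2": r.chi2,
                "p_value": r.p_value,
                "C_ij": r.counts.c_ij,
            }
            for r in rows[:top_k]
        ]

    resolution = [
        {
            "symptom": r.symptom,
            "n_admission": r.n_admission,
            "n_resolved": r.n_resolved,
            "resolution_rate": r.resolution_rate,
        }
        for r in symptom_resolution(records, partition, min_support)
        if r.module == module_id
    ]

    size = sum(1 for m in partition.assignment.values() if m == module_id)
    return {
        "module": module_id,
        "n_patients": size,
        "significant_features": sections,
        "symptom_resolution": resolution,
    }


def write_resolution_csv(
    results: Sequence[ResolutionResult], path: str | Path
) -> None:
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(
            ["module", "symptom", "n_admission", "n_resolved", "resolution_rate"]
        )
        for r in results:
            writer.writerow(
                [r.module, r.symptom, r.n_admission, r.n_resolved,
                 repr(r.resolution_rate)]
            )


def plot_resolution(
    results: Sequence[ResolutionResult],
    module_id: int,
    path: str | Path,
    top_k: int = 10,
) -> None:
    """Horizontal bar chart of the module's most-resolved symptoms."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    rows = [r for r in results if r.module == module_id][:top_k]
    fig, ax = plt.subplots(figsize=(6, 0.4 * max(len(rows), 1) + 1))
    ax.barh(
        [r.symptom for r in rows][::-1],
        [r.n_resolved for r in rows][::-1],
        color="#4878a8",
    )
    ax.set_xlabel("patients with symptom resolved")
    ax.set_title(f"Module {module_id}: symptom resolution")
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)
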