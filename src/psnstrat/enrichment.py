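"""Relative-risk enrichment of module features with chi-square screening.

For module i and feature j the contingency counts are: C_ij patients in
the module carrying the feature, C_i patients in the module, C_j
carriers in the whole networked cohort, N networked patients. Relative
risk compares the in-module prevalence against the out-of-module one:

    RR = (C_ij / C_i) / ((C_j - C_ij) / (N - C_i))

A feature is flagged significant when RR > 1 and the Pearson chi-square
p-value (1 df, no continuity correction) is below alpha.
"""

from __future__ import annotations

import csv
import logging
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy import stats

from .communities import Partition
from .curation import FeatureClass, PatientRecord
from .errors import DegenerateTableError, UndefinedRelativeRiskError

__all__ = [
    "ContingencyCounts",
    "EnrichmentResult",
    "relative_risk",
    "chi_square",
    "enrich",
    "write_enrichment_csv",
]

logger = logging.getLogger(__name__)

#: record attribute(s) supplying the features of each class
CLASS_FIELDS: dict[FeatureClass, tuple[str, ...]] = {
    FeatureClass.SYMPTOM: ("main_symptoms", "general_symptoms"),
    FeatureClass.TONGUE: ("tongue_features",),
    FeatureClass.PULSE: ("pulse_features",),
    FeatureClass.DIAGNOSIS: ("tcm_diagnoses",),
    FeatureClass.HERB: ("herbs",),
}


@dataclass(frozen=True)
class ContingencyCounts:
    """Module-by-feature 2x2 table in marginal form."""

    c_ij: int
    c_i: int
    c_j: int
    n: int

    def __post_init__(self) -> None:
        if not (0 <= self.c_ij <= min(self.c_i, self.c_j)):
            raise ValueError("require 0 <= C_ij <= min(C_i, C_j)")
        if self.c_i > self.n or self.c_j > self.n:
            raise ValueError("marginals cannot exceed N")
        if self.c_j - self.c_ij > self.n - self.c_i:
            raise ValueError("out-of-module carriers exceed out-of-module size")

    def as_table(self) -> np.ndarray:
        """[[in-module carriers, in-module non-carriers],
        [out-module carriers, out-module non-carriers]]"""
        return np.array(
            [
                [self.c_ij, self.c_i - self.c_ij],
                [self.c_j - self.c_ij, self.n - self.c_i - (self.c_j - self.c_ij)],
            ],
            dtype=float,
        )


@dataclass
class EnrichmentResult:
    module: int
    feature: str
    feature_class: FeatureClass
    counts: ContingencyCounts
    rr: float
    chi2: float
    p_value: float
    significant: bool


def relative_risk(counts: ContingencyCounts) -> float:
    """Exposed/unexposed risk ratio; +inf when the feature occurs only
    inside the module, 0 when it occurs only outside."""
    if counts.c_i == 0 or counts.n <= counts.c_i:
        raise UndefinedRelativeRiskError(
            "RR requires 0 < C_i < N (a module that is neither empty "
            "nor the whole cohort)"
        )
    risk_in = counts.c_ij / counts.c_i
    out_carriers = counts.c_j - counts.c_ij
    if out_carriers == 0:
        return math.inf if counts.c_ij > 0 else 0.0
    risk_out = out_carriers / (counts.n - counts.c_i)
    return risk_in / risk_out


def chi_square(counts: ContingencyCounts) -> tuple[float, float]:
    """Pearson chi-square (1 df, no continuity correction) of the 2x2
    module-by-feature table. Raises on a zero marginal."""
    table = counts.as_table()
    if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
        raise DegenerateTableError(
            f"zero marginal in table {table.astype(int).tolist()}"
        )
    chi2, p, _, _ = stats.chi2_contingency(table, correction=False)
    return float(chi2), float(p)


def _feature_sets(
    records: Sequence[PatientRecord], feature_class: FeatureClass
) -> dict[str, frozenset[str]]:
    fields = CLASS_FIELDS[FeatureClass(feature_class)]
    return {
        r.patient_id: frozenset().union(*(getattr(r, f) for f in fields))
        for r in records
    }


def enrich(
    records: Sequence[PatientRecord],
    partition: Partition,
    feature_class: FeatureClass,
    alpha: float = 0.05,
    bh_correction: bool = False,
) -> list[EnrichmentResult]:
    """One result per (module, feature) pair with C_ij > 0, sorted by
    module then descending RR.

    A feature carried by the whole cohort yields a degenerate table; its
    rows are kept with chi2 = 0, p = 1 (observed equals expected exactly)
    and can never be significant. With *bh_correction* the p-values are
    Benjamini–Hochberg adjusted before flagging (off by default).
    """
    by_id = {r.patient_id: r for r in records}
    missing = [n for n in partition.assignment if n not in by_id]
    if missing:
        raise ValueError(f"{len(missing)} partition nodes have no record")
    cohort = [by_id[n] for n in sorted(partition.assignment)]
    n_total = len(cohort)

    sets = _feature_sets(cohort, feature_class)
    all_features = sorted(set().union(*sets.values())) if sets else []
    if not all_features:
        logger.warning("no %s features present in cohort", feature_class)
        return []

    c_j = {f: 0 for f in all_features}
    for terms in sets.values():
        for f in terms:
            c_j[f] += 1

    module_members: dict[int, list[str]] = {}
    for pid, mod in partition.assignment.items():
        module_members.setdefault(mod, []).append(pid)

    results: list[EnrichmentResult] = []
    for mod in sorted(module_members):
        members = module_members[mod]
        c_i = len(members)
        c_ij: dict[str, int] = {}
        for pid in members:
            for f in sets[pid]:
                c_ij[f] = c_ij.get(f, 0) + 1
        for feature in sorted(c_ij):
            counts = ContingencyCounts(c_ij[feature], c_i, c_j[feature], n_total)
            if c_i == n_total:
                # module covers the whole cohort: no out-group, no signal
                rr = 1.0
            else:
                rr = relative_risk(counts)
            try:
                chi2, p = chi_square(counts)
            except DegenerateTableError:
                # feature carried by everyone (or no one outside the margin):
                # observed == expected, no signal
                chi2, p = 0.0, 1.0
                logger.debug(
                    "degenerate table for %s in module %d", feature, mod
                )
            results.append(
                EnrichmentResult(
                    module=mod,
                    feature=feature,
                    feature_class=FeatureClass(feature_class),
                    counts=counts,
                    rr=rr,
                    chi2=chi2,
                    p_value=p,
                    significant=False,
                )
            )

    p_for_flag = [r.p_value for r in results]
    if bh_correction and results:
        p_for_flag = list(_benjamini_hochberg(np.array(p_for_flag)))
    for res, p_adj in zip(results, p_for_flag):
        res.significant = bool(res.rr > 1.0 and p_adj < alpha)

    results.sort(key=lambda r: (r.module, _rr_sort_key(r.rr), r.feature))
    _check_conservation(results, n_total, c_j)
    return results


def _rr_sort_key(rr: float) -> float:
    return -rr


def _benjamini_hochberg(p: np.ndarray) -> np.ndarray:
    order = np.argsort(p)
    ranked = p[order] * len(p) / (np.arange(len(p)) + 1)
    adjusted = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty_like(p)
    out[order] = np.clip(adjusted, 0, 1)
    return out


def _check_conservation(
    results: list[EnrichmentResult], n_total: int, c_j: dict[str, int]
) -> None:
    """Per-feature sum of module counts must reproduce the cohort count."""
    per_feature: dict[str, int] = {}
    for r in results:
        per_feature[r.feature] = per_feature.get(r.feature, 0) + r.counts.c_ij
    for feature, total in per_feature.items():
        assert total == c_j[feature], (
            f"count conservation violated for {feature}: {total} != {c_j[feature]}"
        )


CSV_COLUMNS = [
    "module",
    "feature",
    "feature_class",
    "C_ij",
    "C_i",
    "C_j",
    "N",
    "rr",
    "chi2",
    "p_value",
    "significant",
]


def write_enrichment_csv(
    results: Sequence[EnrichmentResult], path: str | Path
) -> None:
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(CSV_COLUMNS)
        for r in results:
            writer.writerow(
                [
                    r.module,
                    r.feature,
                    r.feature_class.value,
                    r.counts.c_ij,
                    r.counts.c_i,
                    r.counts.c_j,
                    r.counts.n,
                    "inf" if math.isinf(r.rr) else repr(r.rr),
                    repr(r.chi2),
                    repr(r.p_value),
                    str(r.significant).lower(),
                ]
            )
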