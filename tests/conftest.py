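from __future__ import annotations

import datetime as dt

import pytest

from psnstrat.curation import (
    FeatureClass,
    PatientRecord,
    RawRecord,
    TermDictionary,
)
from psnstrat.synthetic import GeneratorConfig, recovery_experiment


def make_raw(pid="P1", aid="A1", **kwargs) -> RawRecord:
    defaults = dict(
        patient_id=pid,
        admission_id=aid,
        admission_date=dt.date(2020, 1, 1),
        age=60,
        sex="male",
        main_symptoms=["gastric distension"],
        general_symptoms=["insomnia"],
        tongue_features=["red tongue"],
        pulse_features=["thin pulse"],
        tcm_diagnoses=["gastric abscess"],
        icd_codes=["K29.400"],
        herbs=["poria"],
        discharge_symptoms=["insomnia"],
        outcome="improvement",
    )
    defaults.update(kwargs)
    return RawRecord(**defaults)


def make_patient(pid="P1", **kwargs) -> PatientRecord:
    defaults = dict(
        patient_id=pid,
        admission_id=f"{pid}-a",
        admission_date=dt.date(2020, 1, 1),
        age=60,
        sex="male",
        outcome="improvement",
    )
    defaults.update(kwargs)
    for name in (
        "main_symptoms",
        "general_symptoms",
        "tongue_features",
        "pulse_features",
        "tcm_diagnoses",
        "icd_rollup",
        "herbs",
        "discharge_symptoms",
    ):
        if name in defaults:
            defaults[name] = frozenset(defaults[name])
    return PatientRecord(**defaults)


@pytest.fixture
def toy_dictionary() -> TermDictionary:
    entries = {
        "stomach-bloat-a": ("gastric distension", FeatureClass.SYMPTOM),
        "stomach-bloat-b": ("gastric distension", FeatureClass.SYMPTOM),
        "gastric distension": ("gastric distension", FeatureClass.SYMPTOM),
        "no-sleep": ("insomnia", FeatureClass.SYMPTOM),
        "insomnia": ("insomnia", FeatureClass.SYMPTOM),
        "stomach pain": ("stomach pain", FeatureClass.SYMPTOM),
        "poor appetite": ("poor appetite", FeatureClass.SYMPTOM),
        "red tongue": ("red tongue", FeatureClass.TONGUE),
        "thin pulse": ("thin pulse", FeatureClass.PULSE),
        "gastric abscess": ("gastric abscess", FeatureClass.DIAGNOSIS),
        "poria": ("poria", FeatureClass.HERB),
        "fu-ling": ("poria", FeatureClass.HERB),
    }
    return TermDictionary(entries)


@pytest.fixture(scope="session")
def recovery_default() -> dict:
    """The default planted-subgroup recovery run (n=1000, K=3, seed 7);
    computed once per session, shared by synthetic and acceptance tests."""
    return recovery_experiment(GeneratorConfig(n_patients=1000, seed=7))
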