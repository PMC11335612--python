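from __future__ import annotations

import datetime as dt
from collections import Counter

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from conftest import make_raw
from psnstrat.curation import (
    FeatureClass,
    TermDictionary,
    already_canonical,
    apply_inclusion_exclusion,
    completeness_score,
    curate,
    normalize_terms,
    record_to_raw,
    rollup_icd,
)
from psnstrat.errors import ClassificationError, NormalizationError
from psnstrat.io import (
    read_records_csv,
    read_records_jsonl,
    read_term_dictionary,
    write_records_csv,
    write_records_jsonl,
    write_term_dictionary,
)


class TestNormalizeTerms:
    def test_synonyms_collapse_to_one_canonical_term(self, toy_dictionary):
        record = make_raw(main_symptoms=["stomach-bloat-a", "stomach-bloat-b"])
        out = normalize_terms(record, toy_dictionary)
        assert out.main_symptoms == frozenset({"gastric distension"})

    def test_drop_unknown_removes_and_logs(self, toy_dictionary):
        unmapped = Counter()
        record = make_raw(main_symptoms=["xyzzy", "no-sleep"])
        out = normalize_terms(record, toy_dictionary, "drop_unknown", unmapped)
        assert out.main_symptoms == frozenset({"insomnia"})
        assert unmapped["xyzzy"] == 1

    def test_strict_raises_naming_the_term(self, toy_dictionary):
        record = make_raw(main_symptoms=["xyzzy"])
        with pytest.raises(NormalizationError, match="xyzzy"):
            normalize_terms(record, toy_dictionary, "strict")

    def test_wrong_feature_class_raises(self, toy_dictionary):
        record = make_raw(main_symptoms=["poria"])  # an herb in a symptom field
        with pytest.raises(ClassificationError):
            normalize_terms(record, toy_dictionary)

    def test_idempotent_on_canonical_record(self, toy_dictionary):
        record = make_raw(
            main_symptoms=["gastric distension"],
            general_symptoms=["insomnia"],
            herbs=["poria"],
        )
        once = normalize_terms(record, toy_dictionary, "strict")
        assert already_canonical(once, toy_dictionary)
        twice = normalize_terms(record_to_raw(once), toy_dictionary, "strict")
        assert twice == once

    def test_unknown_policy_rejected(self, toy_dictionary):
        with pytest.raises(ValueError):
            normalize_terms(make_raw(), toy_dictionary, "whatever")


class TestRollupIcd:
    def test_sibling_codes_combine(self):
        assert rollup_icd({"I50.903", "I50.905"}) == {"I50.9"}

    def test_truncation_after_one_decimal_char(self):
        assert rollup_icd({"K29.400"}) == {"K29.4"}

    def test_no_decimal_passes_through(self):
        assert rollup_icd({"K29"}) == {"K29"}

    def test_trailing_dot(self):
        assert rollup_icd({"K29."}) == {"K29"}


class TestCompletenessScore:
    def test_fully_populated_scores_ten(self):
        assert completeness_score(make_raw()) == 10

    def test_bare_identifiers_score_zero(self):
        from psnstrat.curation import RawRecord

        assert completeness_score(RawRecord("P1", "A1")) == 0

    def test_two_missing_fields_score_eight(self):
        record = make_raw(herbs=[], discharge_symptoms=[])
        assert completeness_score(record) == 8


class TestInclusionExclusion:
    def test_most_complete_admission_wins(self):
        full = make_raw(pid="P1", aid="A2")
        partial = make_raw(pid="P1", aid="A1", herbs=[], tongue_features=[],
                           pulse_features=[])
        kept, report = apply_inclusion_exclusion([partial, full])
        assert kept == [full]
        assert report.n_excluded_duplicate_admissions == 1

    def test_missing_discharge_information_excluded(self):
        record = make_raw(discharge_symptoms=[], outcome="")
        kept, report = apply_inclusion_exclusion([record])
        assert kept == []
        assert report.n_excluded_missing == 1

    def test_missing_diagnosis_excluded(self):
        record = make_raw(tcm_diagnoses=[], icd_codes=[])
        kept, _ = apply_inclusion_exclusion([record])
        assert kept == []

    def test_missing_patient_id_excluded(self):
        kept, _ = apply_inclusion_exclusion([make_raw(pid="")])
        assert kept == []

    def test_six_records_report_sums(self):
        records = [
            make_raw(pid="P1", aid="A1"),
            make_raw(pid="P1", aid="A2", herbs=[]),  # duplicate, less complete
            make_raw(pid="P2", aid="A3"),
            make_raw(pid="P2", aid="A4", herbs=[], tongue_features=[]),
            make_raw(pid="P3", aid="A5"),
            make_raw(pid="P4", aid="A6", discharge_symptoms=[], outcome=""),
        ]
        kept, report = apply_inclusion_exclusion(records)
        assert report.n_included == len(kept) == 3
        assert report.n_excluded_missing == 1
        assert report.n_excluded_duplicate_admissions == 2
        report.validate()

    def test_tie_breaks_on_latest_date_then_admission_id(self):
        older = make_raw(pid="P1", aid="A1",
                         admission_date=dt.date(2019, 1, 1))
        newer = make_raw(pid="P1", aid="A2",
                         admission_date=dt.date(2021, 1, 1))
        kept, _ = apply_inclusion_exclusion([older, newer])
        assert kept == [newer]
        twin_a = make_raw(pid="P2", aid="B1")
        twin_b = make_raw(pid="P2", aid="B2")
        kept, _ = apply_inclusion_exclusion([twin_a, twin_b])
        assert kept[0].admission_id == "B2"

    def test_empty_input(self):
        kept, report = apply_inclusion_exclusion([])
        assert kept == []
        assert report.n_input == report.n_included == 0


@st.composite
def raw_records(draw):
    pid = draw(st.integers(0, 5))
    aid = draw(st.integers(0, 1000))
    present = draw(st.lists(st.booleans(), min_size=6, max_size=6))
    return make_raw(
        pid=f"P{pid}",
        aid=f"A{aid}",
        admission_date=dt.date(2015, 1, 1)
        + dt.timedelta(days=draw(st.integers(0, 2000))),
        herbs=["poria"] if present[0] else [],
        tongue_features=["red tongue"] if present[1] else [],
        pulse_features=["thin pulse"] if present[2] else [],
        tcm_diagnoses=["gastric abscess"] if present[3] else [],
        discharge_symptoms=["insomnia"] if present[4] else [],
        outcome="improvement" if present[5] else "",
    )


class TestProperties:
    @given(st.lists(raw_records(), max_size=25, unique_by=lambda r: r.admission_id))
    @settings(max_examples=60, deadline=None)
    def test_report_counts_conserve(self, records):
        _, report = apply_inclusion_exclusion(records)
        report.validate()

    @given(
        st.lists(raw_records(), max_size=15, unique_by=lambda r: r.admission_id),
        st.randoms(use_true_random=False),
    )
    @settings(max_examples=40, deadline=None)
    def test_output_invariant_to_input_order(self, records, rnd):
        kept_a, report_a = apply_inclusion_exclusion(records)
        shuffled = list(records)
        rnd.shuffle(shuffled)
        kept_b, report_b = apply_inclusion_exclusion(shuffled)
        assert kept_a == kept_b
        assert report_a.to_dict() == report_b.to_dict()


class TestCurate:
    def test_curate_combines_filters_and_normalization(self, toy_dictionary):
        records = [
            make_raw(pid="P1", main_symptoms=["stomach-bloat-a", "xyzzy"]),
            make_raw(pid="P2", discharge_symptoms=[], outcome=""),
        ]
        curated, report = curate(records, toy_dictionary)
        assert len(curated) == 1
        assert curated[0].main_symptoms == frozenset({"gastric distension"})
        assert ("xyzzy", 1) in report.unmapped_terms
        report.validate()


class TestRoundTrips:
    def test_csv_round_trip(self, tmp_path):
        records = [make_raw(pid="P1"), make_raw(pid="P2", aid="A2", age=None,
                                                herbs=[])]
        path = tmp_path / "records.csv"
        write_records_csv(records, path)
        assert read_records_csv(path) == records

    def test_jsonl_round_trip(self, tmp_path):
        records = [make_raw(pid="P1"), make_raw(pid="P2", aid="A2")]
        path = tmp_path / "records.jsonl"
        write_records_jsonl(records, path)
        assert read_records_jsonl(path) == records

    def test_dictionary_round_trip(self, tmp_path, toy_dictionary):
        path = tmp_path / "dict.tsv"
        write_term_dictionary(toy_dictionary, path)
        loaded = read_term_dictionary(path)
        assert loaded.entries == toy_dictionary.entries

    def test_dictionary_rejects_bad_class(self, tmp_path):
        path = tmp_path / "dict.tsv"
        path.write_text("a\tb\tnot-a-class\n")
        from psnstrat.errors import InputError

        with pytest.raises(InputError):
            read_term_dictionary(path)


def test_dictionary_rejects_empty_canonical():
    with pytest.raises(ValueError):
        TermDictionary({"raw": ("", FeatureClass.SYMPTOM)})
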