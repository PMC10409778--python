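"""Patient-status aggregation, yearly trends, and diagnosis cross-checks."""

import datetime as dt

import numpy as np
import pandas as pd
import pytest

from cannascreen.classify import UseLabel
from cannascreen.cohort import (
    CohortError,
    DiagnosisRecord,
    Patient,
    aggregate_patient_status,
    crosscheck_fraction,
    match_diagnosis_codes,
    procedure_group_distribution,
    trend_table,
)
from cannascreen.screening import Note, ScreenDecision


def _patient(pid, birth=dt.date(2000, 1, 1), sex="male", race="white", svi=0.3):
    return Patient(pid, sex, race, birth, svi)


def _note(nid, pid, date, osm=False):
    return Note(nid, pid, date, osm, "text")


def _dec(nid, status="screened_in"):
    return ScreenDecision(nid, status)


def _lab(nid, label, idx=0):
    return UseLabel(nid, idx, label, 0.9 if label == "positive" else 0.1)


class TestAggregation:
    def test_any_positive_sentence_makes_patient_positive(self):
        notes = [
            _note("n1", "p1", dt.date(2015, 3, 1)),
            _note("n2", "p1", dt.date(2016, 5, 1)),
        ]
        decisions = [_dec("n1"), _dec("n2")]
        labels = [_lab("n1", "negative"), _lab("n2", "positive")]
        out = aggregate_patient_status(notes, decisions, labels, [_patient("p1")])
        assert out[0].status == "positive"
        assert out[0].first_positive_date == dt.date(2016, 5, 1)
        assert out[0].age_at_first_positive == pytest.approx(16.33, abs=0.05)

    def test_excluded_only_patient_is_undocumented(self):
        notes = [_note("n1", "p1", dt.date(2015, 1, 1))]
        out = aggregate_patient_status(
            notes, [_dec("n1", "excluded_bile_duct")], [], [_patient("p1")]
        )
        assert out[0].status == "undocumented"

    def test_statuses_partition_patients(self):
        notes = [
            _note("n1", "p1", dt.date(2015, 1, 1)),
            _note("n2", "p2", dt.date(2015, 1, 1)),
            _note("n3", "p3", dt.date(2015, 1, 1)),
        ]
        decisions = [_dec("n1"), _dec("n2"), _dec("n3", "no_mention")]
        labels = [_lab("n1", "positive"), _lab("n2", "negative")]
        patients = [_patient("p1"), _patient("p2"), _patient("p3")]
        out = aggregate_patient_status(notes, decisions, labels, patients)
        assert sorted(s.status for s in out) == [
            "negative_documented", "positive", "undocumented",
        ]

    def test_label_for_unknown_note_rejected(self):
        with pytest.raises(CohortError):
            aggregate_patient_status(
                [], [], [_lab("ghost", "positive")], [_patient("p1")]
            )

    def test_first_positive_date_is_earliest(self):
        notes = [
            _note("n1", "p1", dt.date(2018, 1, 1)),
            _note("n2", "p1", dt.date(2015, 1, 1)),
        ]
        labels = [_lab("n1", "positive"), _lab("n2", "positive")]
        out = aggregate_patient_status(notes, [_dec("n1"), _dec("n2")], labels, [_patient("p1")])
        assert out[0].first_positive_date == dt.date(2015, 1, 1)


class TestTrendTable:
    def test_forced_single_year_percentages(self):
        notes = [_note(f"n{i}", "p1", dt.date(2015, 1, 1 + i)) for i in range(10)]
        decisions = [_dec("n0"), _dec("n1")] + [_dec(f"n{i}", "no_mention") for i in range(2, 10)]
        labels = [_lab("n0", "positive"), _lab("n1", "negative")]
        patients = [_patient("p1")]
        statuses = aggregate_patient_status(notes, decisions, labels, patients)
        tt = trend_table(notes, decisions, labels, patients, statuses)
        row = tt.iloc[0]
        assert row["pct_documented_all_notes"] == 20.0
        assert row["pct_positive_all_notes"] == 10.0

    def test_new_positive_counted_once_in_first_year(self):
        notes = [
            _note("n1", "p1", dt.date(2015, 6, 1)),
            _note("n2", "p1", dt.date(2018, 6, 1)),
        ]
        decisions = [_dec("n1"), _dec("n2")]
        labels = [_lab("n1", "positive"), _lab("n2", "positive")]
        patients = [_patient("p1")]
        statuses = aggregate_patient_status(notes, decisions, labels, patients)
        tt = trend_table(notes, decisions, labels, patients, statuses).set_index("year")
        assert tt.loc[2015, "n_new_positive_patients"] == 1
        assert tt.loc[2018, "n_new_positive_patients"] == 0

    def test_new_positive_sums_to_total_positive(self):
        rng = np.random.default_rng(0)
        notes, decisions, labels, patients = [], [], [], []
        for i in range(40):
            pid = f"p{i}"
            patients.append(_patient(pid))
            for j in range(3):
                nid = f"n{i}_{j}"
                year = int(rng.integers(2010, 2020))
                notes.append(_note(nid, pid, dt.date(year, 6, 1)))
                if rng.random() < 0.4:
                    decisions.append(_dec(nid))
                    labels.append(_lab(nid, "positive" if rng.random() < 0.5 else "negative"))
                else:
                    decisions.append(_dec(nid, "no_mention"))
        statuses = aggregate_patient_status(notes, decisions, labels, patients)
        tt = trend_table(notes, decisions, labels, patients, statuses)
        n_pos = sum(s.status == "positive" for s in statuses)
        assert tt["n_new_positive_patients"].sum() == n_pos

    def test_osm_percentages_use_osm_denominator(self):
        notes = [
            _note("n1", "p1", dt.date(2015, 1, 1), osm=True),
            _note("n2", "p1", dt.date(2015, 2, 1), osm=True),
            _note("n3", "p1", dt.date(2015, 3, 1), osm=False),
        ]
        decisions = [_dec("n1"), _dec("n2", "no_mention"), _dec("n3")]
        labels = [_lab("n1", "positive")]
        patients = [_patient("p1")]
        statuses = aggregate_patient_status(notes, decisions, labels, patients)
        tt = trend_table(notes, decisions, labels, patients, statuses)
        row = tt.iloc[0]
        assert row["pct_documented_osm"] == 50.0  # 1 of 2 OSM notes
        assert row["pct_documented_all_notes"] == pytest.approx(200 / 3, rel=1e-9)


def oracle_icd_match(code: str, prefix: str) -> bool:
    """Independent normalization oracle: character-by-character prefix walk."""
    c = [ch for ch in code.upper().strip() if ch != "."]
    p = [ch for ch in prefix.upper().strip() if ch != "."]
    if len(c) < len(p):
        return False
    return all(a == b for a, b in zip(c, p))


class TestDiagnosisMatching:
    def test_child_codes_match_parent_prefix(self):
        recs = [
            DiagnosisRecord("p1", "F12.20", "ICD-10-CM", dt.date(2018, 1, 1)),
            DiagnosisRecord("p2", "F12.10", "ICD-10-CM", dt.date(2018, 1, 1)),
            DiagnosisRecord("p3", "F12.90", "ICD-10-CM", dt.date(2018, 1, 1)),
        ]
        assert match_diagnosis_codes(recs) == {"p1", "p2", "p3"}

    def test_icd9_prefix_rule(self):
        recs = [
            DiagnosisRecord("p1", "305.2", "ICD-9-CM", dt.date(2010, 1, 1)),
            DiagnosisRecord("p2", "305.1", "ICD-9-CM", dt.date(2010, 1, 1)),
        ]
        assert match_diagnosis_codes(recs) == {"p1"}

    def test_snomed_exact_match_only(self):
        recs = [
            DiagnosisRecord("p1", "7344009", "SNOMED-CT", dt.date(2018, 1, 1)),
            DiagnosisRecord("p2", "73440090", "SNOMED-CT", dt.date(2018, 1, 1)),
        ]
        assert match_diagnosis_codes(recs) == {"p1"}

    def test_unknown_vocabulary_rejected(self):
        with pytest.raises(CohortError):
            match_diagnosis_codes(
                [DiagnosisRecord("p1", "X", "READ2", dt.date(2018, 1, 1))]
            )

    def test_matches_string_normalization_oracle_on_fuzz_codes(self):
        rng = np.random.default_rng(42)
        letters = "FTMSK"
        codes = []
        for _ in range(100):
            head = str(rng.choice(list(letters))) + "".join(
                str(rng.integers(0, 10)) for _ in range(2)
            )
            tail = "." + "".join(str(rng.integers(0, 10)) for _ in range(int(rng.integers(0, 3)))) \
                if rng.random() < 0.7 else ""
            codes.append((head + tail).rstrip("."))
        # force some true positives into the fuzz set
        codes[:4] = ["F12.20", "T40.7X1A", "F12", "T40.71"]
        prefixes = ["F12", "T40.7"]
        for i, code in enumerate(codes):
            rec = DiagnosisRecord(f"p{i}", code, "ICD-10-CM", dt.date(2018, 1, 1))
            got = match_diagnosis_codes([rec], {"ICD-10-CM": prefixes})
            expected = any(oracle_icd_match(code, p) for p in prefixes)
            assert (f"p{i}" in got) == expected, code


class TestCrosscheck:
    def test_printed_counts_reproduce_percentage(self):
        nlp_pos = {f"p{i}" for i in range(13556)}
        dx_pos = {f"p{i}" for i in range(1971)}
        out = crosscheck_fraction(nlp_pos, dx_pos)
        assert out == {"overlap": 1971, "percent_of_nlp_positive": 14.5}

    def test_identical_sets_full_overlap(self):
        s = {"a", "b"}
        assert crosscheck_fraction(s, set(s))["percent_of_nlp_positive"] == 100.0

    def test_disjoint_sets_zero(self):
        assert crosscheck_fraction({"a"}, {"b"})["percent_of_nlp_positive"] == 0.0

    def test_empty_nlp_positive_rejected(self):
        with pytest.raises(CohortError):
            crosscheck_fraction(set(), {"a"})


class TestProcedureDistribution:
    def test_single_group_is_100_percent(self):
        from cannascreen.cohort import PatientStatus

        procedures = pd.DataFrame({"patient_id": ["p1", "p2"], "group": ["cast", "cast"]})
        statuses = [PatientStatus("p1", "positive"), PatientStatus("p2", "undocumented")]
        out = procedure_group_distribution(procedures, statuses)
        assert (out["percent"] == 100.0).all()

    def test_percentages_sum_to_100_per_cohort(self):
        from cannascreen.cohort import PatientStatus

        rng = np.random.default_rng(1)
        procedures = pd.DataFrame(
            {
                "patient_id": [f"p{i}" for i in range(200)],
                "group": rng.choice(["cast", "splint", "fixation"], size=200),
            }
        )
        statuses = [
            PatientStatus(f"p{i}", "positive" if i % 3 == 0 else "negative_documented")
            for i in range(200)
        ]
        out = procedure_group_distribution(procedures, statuses)
        sums = out.groupby("cohort")["percent"].sum()
        assert np.allclose(sums, 100.0)
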