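"""Patient-level aggregation, yearly trends, and diagnostic-code cross-checks.

A patient is *positive* when any sentence in any of their notes is labeled
positive use; *negative_documented* when they have at least one screened-in
note but no positive sentence; otherwise *undocumented*. Trends report
documentation and positivity as percentages of all notes per calendar year
(overall and within orthopedic/sports-medicine notes), plus newly positive
patients per year with demographic breakdowns.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .classify import POSITIVE, UseLabel
from .screening import DAYS_PER_YEAR, Note, ScreenDecision

__all__ = [
    "Patient",
    "PatientStatus",
    "DiagnosisRecord",
    "DEFAULT_CODEBOOK",
    "aggregate_patient_status",
    "trend_table",
    "match_diagnosis_codes",
    "crosscheck_fraction",
    "procedure_group_distribution",
]

SEXES = ("female", "male", "unknown")
RACES = ("asian", "black", "hispanic", "other", "white", "unavailable")


class CohortError(ValueError):
    pass


@dataclass(frozen=True)
class Patient:
    patient_id: str
    sex: str
    race: str
    birth_date: dt.date
    svi: float | None = None

    def __post_init__(self) -> None:
        if self.sex not in SEXES:
            raise CohortError(f"unknown sex {self.sex!r}")
        if self.race not in RACES:
            raise CohortError(f"unknown race {self.race!r}")
        if self.svi is not None and not (0.0 <= self.svi <= 1.0):
            raise CohortError(f"SVI {self.svi} outside [0, 1]")


@dataclass(frozen=True)
class PatientStatus:
    patient_id: str
    status: str  # positive | negative_documented | undocumented
    first_positive_date: dt.date | None = None
    age_at_first_positive: float | None = None


@dataclass(frozen=True)
class DiagnosisRecord:
    patient_id: str
    code: str
    vocabulary: str  # ICD-9-CM | ICD-10-CM | SNOMED-CT
    date: dt.date


#: Cannabis-use diagnostic codes: ICD families matched by dot-hierarchy
#: prefix, SNOMED CT concepts matched exactly.
DEFAULT_CODEBOOK = {
    "ICD-10-CM": ["F12", "T40.7"],
    "ICD-9-CM": ["305.2", "304.3"],
    "SNOMED-CT": ["7344009", "28823006", "85005007", "191837001"],
}


def aggregate_patient_status(
    notes: list[Note],
    decisions: list[ScreenDecision],
    use_labels: list[UseLabel],
    patients: list[object],
) -> list[PatientStatus]:
    """Roll sentence labels up to one status per patient."""
    note_by_id = {n.note_id: n for n in notes}
    for d in decisions:
        if d.note_id not in note_by_id:
            raise CohortError(f"decision for unknown note {d.note_id!r}")
    for lab in use_labels:
        if lab.note_id not in note_by_id:
            raise CohortError(f"use label for unknown note {lab.note_id!r}")
    screened_pat: set[str] = set()
    for d in decisions:
        if d.status == "screened_in":
            screened_pat.add(note_by_id[d.note_id].patient_id)
    first_pos: dict[str, dt.date] = {}
    for lab in use_labels:
        if lab.label != POSITIVE:
            continue
        note = note_by_id[lab.note_id]
        cur = first_pos.get(note.patient_id)
        if cur is None or note.date < cur:
            first_pos[note.patient_id] = note.date
    birth = {p.patient_id: p.birth_date for p in patients}
    out: list[PatientStatus] = []
    for p in patients:
        pid = p.patient_id
        if pid in first_pos:
            d0 = first_pos[pid]
            age = (d0 - birth[pid]).days / DAYS_PER_YEAR if pid in birth else None
            out.append(PatientStatus(pid, "positive", d0, age))
        elif pid in screened_pat:
            out.append(PatientStatus(pid, "negative_documented"))
        else:
            out.append(PatientStatus(pid, "undocumented"))
    return out


def _mean_ci(values: np.ndarray, level: float = 0.95) -> tuple[float, float, float]:
    """Mean with a t-interval; degenerate inputs collapse to the mean."""
    m = float(np.mean(values))
    if len(values) < 2:
        return m, m, m
    se = float(np.std(values, ddof=1)) / np.sqrt(len(values))
    tcrit = stats.t.ppf(0.5 + level / 2, df=len(values) - 1)
    return m, m - tcrit * se, m + tcrit * se


def trend_table(
    notes: list[Note],
    decisions: list[ScreenDecision],
    use_labels: list[UseLabel],
    patients: list[object],
    statuses: list[PatientStatus],
) -> pd.DataFrame:
    """Per-year documentation/positivity rates and new-positive breakdowns.

    Documentation = screened-in notes as a percent of all notes that year;
    positivity = notes with >= 1 positive sentence. Both are also reported
    over the orthopedic/sports-medicine (OSM) subset with OSM denominators.
    A patient counts as newly positive only in the year of their first
    positive note. Years with zero notes are omitted.
    """
    if len(decisions) != len(notes):
        raise CohortError("every note needs exactly one screen decision")
    dec_by_note = {d.note_id: d.status for d in decisions}
    pos_notes = {lab.note_id for lab in use_labels if lab.label == POSITIVE}
    race = {p.patient_id: p.race for p in patients}
    sex = {p.patient_id: p.sex for p in patients}

    rows: dict[int, dict] = {}
    for n in notes:
        y = n.date.year
        r = rows.setdefault(
            y, {"n_notes": 0, "n_doc": 0, "n_pos": 0, "n_osm": 0, "n_doc_osm": 0, "n_pos_osm": 0}
        )
        r["n_notes"] += 1
        doc = dec_by_note[n.note_id] == "screened_in"
        pos = n.note_id in pos_notes
        r["n_doc"] += doc
        r["n_pos"] += pos
        if n.is_osm:
            r["n_osm"] += 1
            r["n_doc_osm"] += doc
            r["n_pos_osm"] += pos

    new_pos: dict[int, list[PatientStatus]] = {}
    for s in statuses:
        if s.status == "positive" and s.first_positive_date is not None:
            new_pos.setdefault(s.first_positive_date.year, []).append(s)

    records = []
    for y in sorted(rows):
        r = rows[y]
        if r["n_notes"] == 0:
            continue
        yearly_new = new_pos.get(y, [])
        by_race = {rc: 0 for rc in RACES}
        n_female = 0
        ages = []
        for s in yearly_new:
            by_race[race.get(s.patient_id, "unavailable")] += 1
            n_female += sex.get(s.patient_id) == "female"
            if s.age_at_first_positive is not None:
                ages.append(s.age_at_first_positive)
        mean_age, lo, hi = (
            _mean_ci(np.asarray(ages)) if ages else (np.nan, np.nan, np.nan)
        )
        rec = {
            "year": y,
            "n_notes": r["n_notes"],
            "pct_documented_all_notes": 100.0 * r["n_doc"] / r["n_notes"],
            "pct_positive_all_notes": 100.0 * r["n_pos"] / r["n_notes"],
            "n_osm_notes": r["n_osm"],
            "pct_documented_osm": (
                100.0 * r["n_doc_osm"] / r["n_osm"] if r["n_osm"] else np.nan
            ),
            "pct_positive_osm": (
                100.0 * r["n_pos_osm"] / r["n_osm"] if r["n_osm"] else np.nan
            ),
            "n_new_positive_patients": len(yearly_new),
            "pct_new_positive_female": (
                100.0 * n_female / len(yearly_new) if yearly_new else np.nan
            ),
            "mean_age_new_positive": mean_age,
            "mean_age_ci_low": lo,
            "mean_age_ci_high": hi,
        }
        for rc in RACES:
            rec[f"n_new_positive_{rc}"] = by_race[rc]
        records.append(rec)
    return pd.DataFrame.from_records(records)


def _strip_dots(code: str) -> str:
    return code.replace(".", "").strip().upper()


def match_diagnosis_codes(
    records: list[DiagnosisRecord],
    codebook: dict[str, list[str]] | None = None,
) -> set[str]:
    """Patients with >= 1 diagnosis matching the cannabis codebook.

    ICD codes match when they equal or extend a codebook prefix through
    the dot hierarchy (F12.20 matches F12); SNOMED CT concepts match
    exactly. Unknown vocabularies raise.
    """
    codebook = codebook if codebook is not None else DEFAULT_CODEBOOK
    icd_prefixes = {
        vocab: [_strip_dots(c) for c in codes]
        for vocab, codes in codebook.items()
        if vocab.upper().startswith("ICD")
    }
    snomed = {
        c.strip()
        for vocab, codes in codebook.items()
        if "SNOMED" in vocab.upper()
        for c in codes
    }
    matched: set[str] = set()
    for rec in records:
        vocab = rec.vocabulary
        if vocab.upper().startswith("ICD"):
            prefixes = icd_prefixes.get(vocab)
            if prefixes is None:
                raise CohortError(f"unknown vocabulary {vocab!r}")
            code = _strip_dots(rec.code)
            if any(code.startswith(p) for p in prefixes):
                matched.add(rec.patient_id)
        elif "SNOMED" in vocab.upper():
            if rec.code.strip() in snomed:
                matched.add(rec.patient_id)
        else:
            raise CohortError(f"unknown vocabulary {vocab!r}")
    return matched


def crosscheck_fraction(
    nlp_positive: set[str], dx_positive: set[str]
) -> dict[str, float]:
    """Overlap of NLP-positive patients with code-diagnosed patients.

    Returns the intersection count and its share of NLP positives as a
    percentage rounded to one decimal place.
    """
    if not nlp_positive:
        raise CohortError("percent undefined: no NLP-positive patients")
    overlap = len(nlp_positive & dx_positive)
    return {
        "overlap": overlap,
        "percent_of_nlp_positive": round(100.0 * overlap / len(nlp_positive), 1),
    }


def procedure_group_distribution(
    procedures: pd.DataFrame,
    statuses: list[PatientStatus],
) -> pd.DataFrame:
    """Percentage of patients per procedure group, split by use status.

    ``procedures`` needs columns patient_id and group. Cohorts are
    positive vs. everyone else; percentages sum to 100 within each cohort
    (over patients with >= 1 procedure).
    """
    if not {"patient_id", "group"} <= set(procedures.columns):
        raise CohortError("procedures table needs patient_id and group columns")
    pos = {s.patient_id for s in statuses if s.status == "positive"}
    df = procedures.copy()
    df["cohort"] = np.where(df["patient_id"].isin(pos), "positive", "negative")
    counts = df.groupby(["cohort", "group"]).size().rename("n").reset_index()
    counts["percent"] = counts.groupby("cohort")["n"].transform(lambda s: 100.0 * s / s.sum())
    return counts
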