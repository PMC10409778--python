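"""File schemas, validated readers/writers, and the end-to-end pipeline.

Notes travel as JSONL (free text with embedded newlines escapes cleanly);
rectangular tables (patients, diagnoses, labeled sentences) as CSV; all
UTF-8. Every reader validates row-by-row and reports offending line
numbers; every pipeline run writes a manifest whose counts reconcile with
its outputs.
"""

from __future__ import annotations

import dataclasses
import datetime as dt
import hashlib
import json
import re
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import classify as _classify
from . import screening as _screening
from .classify import UseLabel, rule_based_label
from .cohort import (
    DiagnosisRecord,
    Patient,
    aggregate_patient_status,
    crosscheck_fraction,
    match_diagnosis_codes,
    trend_table,
)
from .disparity import build_design, fit_disparity_model
from .lexicon import Lexicon, build_lexicon, expand_misspellings
from .screening import Note, ScreenDecision, extract_cannabis_sentences, screen_notes

__all__ = [
    "SchemaError",
    "PipelineStageError",
    "RunManifest",
    "read_notes",
    "write_notes",
    "read_patients",
    "write_patients",
    "read_diagnoses",
    "write_diagnoses",
    "read_labeled_sentences",
    "write_use_labels",
    "read_use_labels",
    "corpus_vocabulary",
    "run_pipeline",
]


class SchemaError(ValueError):
    """Input file violates the expected schema."""


class PipelineStageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


def _parse_date(value: str, line: int, path: str) -> dt.date:
    try:
        return dt.date.fromisoformat(str(value))
    except ValueError as e:
        raise SchemaError(f"{path}:{line}: bad date {value!r}: {e}") from e


def _require_columns(cols: set[str], required: set[str], path: str) -> None:
    missing = required - cols
    if missing:
        raise SchemaError(f"{path}: missing required column(s): {sorted(missing)}")


# -- notes ----------------------------------------------------------------

NOTE_FIELDS = {"note_id", "patient_id", "date", "is_osm", "text"}


def read_notes(path: str | Path) -> list[Note]:
    """Read notes from JSONL (or CSV with identical headers)."""
    path = Path(path)
    records: list[dict] = []
    if path.suffix == ".csv":
        df = pd.read_csv(path, dtype=str)
        _require_columns(set(df.columns), NOTE_FIELDS, str(path))
        records = df.to_dict("records")
    else:
        with path.open() as fh:
            for i, line in enumerate(fh, 1):
                if not line.strip():
                    continue
                try:
                    obj = json.loads(line)
                except json.JSONDecodeError as e:
                    raise SchemaError(f"{path}:{i}: invalid JSON: {e}") from e
                records.append(obj)
        if records:
            _require_columns(set(records[0]), NOTE_FIELDS, str(path))
    notes = []
    seen: set[str] = set()
    for i, r in enumerate(records, 1):
        missing = NOTE_FIELDS - set(r)
        if missing:
            raise SchemaError(f"{path}:{i}: missing field(s) {sorted(missing)}")
        nid = str(r["note_id"])
        if nid in seen:
            raise SchemaError(f"{path}:{i}: duplicated note_id {nid!r}")
        seen.add(nid)
        is_osm = r["is_osm"]
        if isinstance(is_osm, str):
            is_osm = is_osm.strip().lower() in {"1", "true", "yes"}
        notes.append(
            Note(
                note_id=nid,
                patient_id=str(r["patient_id"]),
                date=_parse_date(r["date"], i, str(path)),
                is_osm=bool(is_osm),
                text=str(r["text"]),
            )
        )
    return notes


def write_notes(notes: list[Note], path: str | Path) -> None:
    with Path(path).open("w") as fh:
        for n in notes:
            fh.write(
                json.dumps(
                    {
                        "note_id": n.note_id,
                        "patient_id": n.patient_id,
                        "date": n.date.isoformat(),
                        "is_osm": n.is_osm,
                        "text": n.text,
                    },
                    sort_keys=True,
                )
                + "\n"
            )


# -- patients -------------------------------------------------------------

PATIENT_FIELDS = {"patient_id", "sex", "race", "birth_date", "svi"}


def read_patients(path: str | Path) -> list[Patient]:
    path = Path(path)
    df = pd.read_csv(path, dtype={"patient_id": str})
    _require_columns(set(df.columns), PATIENT_FIELDS, str(path))
    if df["patient_id"].duplicated().any():
        dupes = df.loc[df["patient_id"].duplicated(), "patient_id"].tolist()
        raise SchemaError(f"{path}: duplicated patient_id(s): {dupes[:5]}")
    patients = []
    for i, r in enumerate(df.itertuples(index=False), 2):
        svi = None if pd.isna(r.svi) else float(r.svi)
        if svi is not None and not (0.0 <= svi <= 1.0):
            raise SchemaError(f"{path}:{i}: SVI {svi} outside [0, 1]")
        try:
            patients.append(
                Patient(
                    patient_id=str(r.patient_id),
                    sex=str(r.sex),
                    race=str(r.race),
                    birth_date=_parse_date(r.birth_date, i, str(path)),
                    svi=svi,
                )
            )
        except ValueError as e:
            raise SchemaError(f"{path}:{i}: {e}") from e
    return patients


def write_patients(patients: list[Patient], path: str | Path) -> None:
    pd.DataFrame(
        [
            {
                "patient_id": p.patient_id,
                "sex": p.sex,
                "race": p.race,
                "birth_date": p.birth_date.isoformat(),
                "svi": "" if p.svi is None else p.svi,
            }
            for p in patients
        ]
    ).to_csv(path, index=False)


# -- diagnoses ------------------------------------------------------------

DIAGNOSIS_FIELDS = {"patient_id", "code", "vocabulary", "date"}


def read_diagnoses(path: str | Path) -> list[DiagnosisRecord]:
    path = Path(path)
    df = pd.read_csv(path, dtype=str)
    _require_columns(set(df.columns), DIAGNOSIS_FIELDS, str(path))
    return [
        DiagnosisRecord(
            patient_id=str(r.patient_id),
            code=str(r.code),
            vocabulary=str(r.vocabulary),
            date=_parse_date(r.date, i, str(path)),
        )
        for i, r in enumerate(df.itertuples(index=False), 2)
    ]


def write_diagnoses(records: list[DiagnosisRecord], path: str | Path) -> None:
    pd.DataFrame(
        [
            {
                "patient_id": d.patient_id,
                "code": d.code,
                "vocabulary": d.vocabulary,
                "date": d.date.isoformat(),
            }
            for d in records
        ]
    ).to_csv(path, index=False)


# -- labeled sentences and predictions -------------------------------------

def read_labeled_sentences(path: str | Path) -> list[_classify.LabeledSentence]:
    path = Path(path)
    df = pd.read_csv(path, dtype=str)
    _require_columns(set(df.columns), {"sentence_text", "label", "note_id"}, str(path))
    return [
        _classify.LabeledSentence(
            sentence_text=str(r.sentence_text), label=str(r.label), note_id=str(r.note_id)
        )
        for r in df.itertuples(index=False)
    ]


def write_use_labels(labels: list[UseLabel], path: str | Path) -> None:
    with Path(path).open("w") as fh:
        for u in labels:
            fh.write(json.dumps(dataclasses.asdict(u), sort_keys=True) + "\n")


def read_use_labels(path: str | Path) -> list[UseLabel]:
    out = []
    with Path(path).open() as fh:
        for line in fh:
            if line.strip():
                out.append(UseLabel(**json.loads(line)))
    return out


def write_decisions(decisions: list[ScreenDecision], path: str | Path) -> None:
    with Path(path).open("w") as fh:
        for d in decisions:
            fh.write(
                json.dumps(
                    {
                        "note_id": d.note_id,
                        "status": d.status,
                        "hits": [dataclasses.asdict(h) for h in d.hits],
                    },
                    sort_keys=True,
                )
                + "\n"
            )


# -- pipeline --------------------------------------------------------------

_WORD = re.compile(r"[a-z]+")


def corpus_vocabulary(notes: list[Note]) -> list[str]:
    """Sorted distinct normalized word tokens across a note corpus."""
    vocab: set[str] = set()
    for n in notes:
        vocab.update(_WORD.findall(n.text.lower()))
    return sorted(vocab)


@dataclass
class RunManifest:
    command: str
    config_hash: str
    seed: int
    timestamp: str
    inputs: dict[str, int] = field(default_factory=dict)
    outputs: dict[str, int] = field(default_factory=dict)
    stage_tallies: dict[str, dict] = field(default_factory=dict)

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(dataclasses.asdict(self), indent=2, sort_keys=True) + "\n")


def run_pipeline(
    notes_path: str | Path,
    patients_path: str | Path,
    out_dir: str | Path,
    diagnoses_path: str | Path | None = None,
    lexicon_config: str | Path | dict | None = None,
    seed: int = 0,
    min_age_years: float = 7.0,
) -> RunManifest:
    """Execute lexicon -> screen -> classify -> cohort -> disparity.

    Intermediates are persisted under ``out_dir``. The sentence classifier
    is the deterministic rule-based labeler (the trainable backend is a
    separate train/predict surface). Any stage failure raises
    :class:`PipelineStageError` naming the stage, after writing a partial
    manifest.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    cfg_repr = json.dumps(
        {
            "notes": str(notes_path),
            "patients": str(patients_path),
            "diagnoses": str(diagnoses_path),
            "lexicon": str(lexicon_config),
            "seed": seed,
            "min_age_years": min_age_years,
        },
        sort_keys=True,
    )
    manifest = RunManifest(
        command="run",
        config_hash=hashlib.sha256(cfg_repr.encode()).hexdigest()[:16],
        seed=seed,
        timestamp=dt.datetime.now(dt.timezone.utc).isoformat(timespec="seconds"),
    )

    def _stage(name):
        def deco(fn):
            try:
                return fn()
            except SchemaError:
                raise  # malformed input, not a stage failure
            except Exception as e:  # noqa: BLE001 - report the failing stage
                manifest.save(out_dir / "manifest.partial.json")
                raise PipelineStageError(name, e) from e

        return deco

    notes = _stage("read_inputs")(lambda: read_notes(notes_path))
    patients = _stage("read_inputs")(lambda: read_patients(patients_path))
    manifest.inputs = {"notes": len(notes), "patients": len(patients)}

    def _build_lex():
        lex = build_lexicon(lexicon_config)
        lex.misspellings = expand_misspellings(corpus_vocabulary(notes), lex)
        lex.save(out_dir / "lexicon.json")
        return lex

    lexicon = _stage("build_lexicon")(_build_lex)
    manifest.stage_tallies["build_lexicon"] = {
        "terms": len(lexicon.all_terms()),
        "misspellings": sum(len(v) for v in lexicon.misspellings.values()),
    }

    def _screen():
        birth = {p.patient_id: p.birth_date for p in patients}
        decisions = screen_notes(notes, lexicon, birth, min_age_years)
        write_decisions(decisions, out_dir / "decisions.jsonl")
        return decisions

    decisions = _stage("screen")(_screen)
    tally = {s: 0 for s in _screening.STATUSES}
    for d in decisions:
        tally[d.status] += 1
    manifest.stage_tallies["screen"] = tally
    assert sum(tally.values()) == len(notes)

    def _predict():
        labels: list[UseLabel] = []
        by_id = {n.note_id: n for n in notes}
        for d in decisions:
            if d.status != "screened_in":
                continue
            note = by_id[d.note_id]
            for sh in extract_cannabis_sentences(note, lexicon, d):
                labels.append(
                    rule_based_label(
                        sh.sentence_text, lexicon, note_id=sh.note_id,
                        sentence_index=sh.sentence_index,
                    )
                )
        write_use_labels(labels, out_dir / "use_labels.jsonl")
        return labels

    use_labels = _stage("predict")(_predict)
    manifest.stage_tallies["predict"] = {
        "sentences": len(use_labels),
        "positive": sum(u.label == "positive" for u in use_labels),
    }

    def _cohort():
        statuses = aggregate_patient_status(notes, decisions, use_labels, patients)
        pd.DataFrame(
            [
                {
                    "patient_id": s.patient_id,
                    "status": s.status,
                    "first_positive_date": (
                        s.first_positive_date.isoformat() if s.first_positive_date else ""
                    ),
                    "age_at_first_positive": (
                        "" if s.age_at_first_positive is None else s.age_at_first_positive
                    ),
                }
                for s in statuses
            ]
        ).to_csv(out_dir / "status.csv", index=False)
        trends = trend_table(notes, decisions, use_labels, patients, statuses)
        trends.to_csv(out_dir / "trend_table.csv", index=False)
        if diagnoses_path is not None:
            dx = read_diagnoses(diagnoses_path)
            dx_pos = match_diagnosis_codes(dx)
            nlp_pos = {s.patient_id for s in statuses if s.status == "positive"}
            if nlp_pos:
                cross = crosscheck_fraction(nlp_pos, dx_pos)
                (out_dir / "crosscheck.json").write_text(
                    json.dumps(cross, indent=2, sort_keys=True) + "\n"
                )
        return statuses

    statuses = _stage("cohort")(_cohort)
    manifest.stage_tallies["cohort"] = {
        s: sum(x.status == s for x in statuses)
        for s in ("positive", "negative_documented", "undocumented")
    }

    def _disparity():
        results = []
        for setting in ("documentation", "positive_use"):
            try:
                y, X = build_design(patients, statuses, setting)
                results.extend(fit_disparity_model(y, X, setting=setting))
            except ValueError:
                continue  # degenerate small corpora: one-class outcome
        (out_dir / "disparity.json").write_text(
            json.dumps([dataclasses.asdict(r) for r in results], indent=2, sort_keys=True)
            + "\n"
        )
        return results

    results = _stage("disparity")(_disparity)
    manifest.stage_tallies["disparity"] = {"contrasts": len(results)}
    manifest.outputs = {
        "decisions": len(decisions),
        "use_labels": len(use_labels),
        "statuses": len(statuses),
        "disparity_contrasts": len(results),
    }
    manifest.save(out_dir / "manifest.json")
    return manifest
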