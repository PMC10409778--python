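"""Synthetic EHR corpus generator with planted ground truth.

Emulates a pediatric orthopedic/sports-medicine note stream: patients with
demographic covariates, notes drawn over a care window, cannabis
documentation and positivity drawn from logistic models with planted
odds ratios and legalization step-ups, template sentences covering
affirmations, denials, toxicology reports, prescription cannabinoids,
counseling, household exposure, and the two classic confounders (CBD as
common bile duct, weed as allergen), plus injected misspellings. Every
note carries a gold record so each pipeline stage can be scored exactly.
"""

from __future__ import annotations

import datetime as dt
import math
from dataclasses import dataclass, field

import numpy as np
from scipy.special import expit

from .cohort import DiagnosisRecord, Patient, PatientStatus
from .lexicon import char_ngram_profile, ngram_cosine
from .screening import Note

__all__ = [
    "SimConfig",
    "GoldRecord",
    "SimResult",
    "generate_cohort",
    "inject_misspellings",
    "gold_confusion",
    "plant_patient_outcomes",
]

GOLD_STATUSES = (
    "no_mention",
    "confounder_bile_duct",
    "confounder_allergy",
    "documented_negative",
    "documented_positive",
    "medical_rx_positive",
    "family_use_negative",
)

_POSITIVE_GOLD = {"documented_positive", "medical_rx_positive"}


class SimError(ValueError):
    pass


@dataclass
class SimConfig:
    """Knobs of the synthetic corpus; defaults mirror the study setting."""

    n_patients: int = 500
    years: tuple[int, int] = (2000, 2021)
    notes_per_patient_year: float = 3.0
    care_window_mean_years: float = 4.0
    osm_fraction: float = 0.6
    # demographics (study cohort proportions)
    sex_probs: dict = field(
        default_factory=lambda: {"female": 0.526, "male": 0.473, "unknown": 0.001}
    )
    race_probs: dict = field(
        default_factory=lambda: {
            "asian": 0.022,
            "black": 0.048,
            "hispanic": 0.067,
            "other": 0.048,
            "white": 0.561,
            "unavailable": 0.254,
        }
    )
    svi_beta: tuple[float, float] = (0.628, 1.690)  # mean .271, sd .244
    svi_missing_rate: float = 0.02
    # documentation model: P(note mentions cannabis)
    doc_base_logodds: float = -4.2
    doc_covariate_logor: dict = field(
        default_factory=lambda: {
            "female": math.log(1.074),
            "race_asian": math.log(0.829),
            "race_black": math.log(3.400),
            "race_hispanic": math.log(2.245),
            "race_other": math.log(1.164),
            "svi_per_001": math.log(1.001),
        }
    )
    # step changes at medical/recreational legalization cutovers
    cutover_logodds_steps: dict = field(
        default_factory=lambda: {2012: math.log(2.0), 2016: math.log(2.0)}
    )
    # positivity model: P(positive use | documented); 0.73 labeled-set balance
    pos_base_logodds: float = 0.9946  # logit(0.73)
    pos_covariate_logor: dict = field(
        default_factory=lambda: {
            "female": math.log(0.957),
            "race_asian": math.log(0.651),
            "race_black": math.log(3.222),
            "race_hispanic": math.log(2.131),
            "race_other": math.log(1.007),
            "svi_per_001": math.log(1.002),
        }
    )
    template_weights: dict = field(
        default_factory=lambda: {
            "affirmation": 0.28,
            "denial": 0.13,
            "tox_positive": 0.12,
            "tox_negative": 0.07,
            "rx_medical": 0.08,
            "counseling": 0.10,
            "family_use": 0.07,
            "bile_duct_confounder": 0.08,
            "allergy_confounder": 0.07,
        }
    )
    confounder_rate: float = 0.02  # among non-documented notes
    misspelling_rate: float = 0.05
    label_noise: float = 0.0  # P(rendered cue polarity disagrees with gold)
    dx_given_positive: float = 0.145
    background_dx_rate: float = 0.3  # non-cannabis codes per patient
    seed: int = 0

    def validate(self) -> list[str]:
        problems = []
        if self.n_patients < 1:
            problems.append("n_patients must be >= 1")
        if self.years[0] > self.years[1]:
            problems.append("years start after end")
        for name, probs in (("sex_probs", self.sex_probs), ("race_probs", self.race_probs)):
            if abs(sum(probs.values()) - 1.0) > 1e-6:
                problems.append(f"{name} must sum to 1")
            if any(p < 0 for p in probs.values()):
                problems.append(f"{name} has negative entries")
        if abs(sum(self.template_weights.values()) - 1.0) > 1e-6:
            problems.append("template_weights must sum to 1")
        for name in ("misspelling_rate", "label_noise", "confounder_rate",
                     "dx_given_positive", "osm_fraction", "svi_missing_rate"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                problems.append(f"{name}={v} outside [0, 1]")
        return problems


@dataclass(frozen=True)
class GoldRecord:
    note_id: str
    true_status: str
    injected_terms: tuple[str, ...] = ()
    injected_misspellings: tuple[str, ...] = ()
    gold_sentence_label: str | None = None  # intended polarity of the cue sentence

    def __post_init__(self) -> None:
        if self.true_status not in GOLD_STATUSES:
            raise SimError(f"unknown gold status {self.true_status!r}")


@dataclass
class SimResult:
    patients: list[Patient]
    notes: list[Note]
    diagnoses: list[DiagnosisRecord]
    gold: list[GoldRecord]
    config: SimConfig
    year_expected_doc_rate: dict[int, float] = field(default_factory=dict)


# -- template banks -------------------------------------------------------

FILLER = [
    "Presents for follow-up of distal radius fracture.",
    "Cast removed today; alignment maintained.",
    "Short leg splint applied to the left ankle.",
    "X-ray shows healing callus formation.",
    "Range of motion improving with physical therapy.",
    "Return to clinic in 4 weeks for repeat films.",
    "No acute distress on exam today.",
    "Pain well controlled with ibuprofen as needed.",
    "Wound healing well with no signs of infection.",
    "Cleared to resume non-contact activity.",
]

RECREATIONAL_TERMS = ["marijuana", "cannabis", "thc", "weed", "cbd"]
MEDICAL_TERMS_POOL = ["marinol", "dronabinol", "epidiolex", "cannabidiol"]

TEMPLATES: dict[str, list[str]] = {
    "affirmation": [
        "Pt admits to smoking {term} daily.",
        "Patient reports using {term} on weekends.",
        "He endorses {term} use since last year.",
        "Social history: pt states used {term} last month.",
        "MJ: +",
    ],
    "denial": [
        "Denies any use of {term}, cocaine, or other drugs.",
        "Patient denies {term} use.",
        "No history of {term} or alcohol use.",
        "Has never used {term} per patient.",
    ],
    "tox_positive": [
        "Urine tox screen: positive for amphetamines and {term}.",
        "Tox screen positive for {term}.",
    ],
    "tox_negative": [
        "Urine tox sent, negative for amphetamines, barbiturates, benzos, {term}.",
        "Toxicology negative for {term} and opiates.",
    ],
    "rx_medical": [
        "RX: DRONABINOL (MARINOL(2.5MG/TAB",
        "Started {term} 100 mg twice daily for seizures.",
        "Continue {term} 2.5 mg tab for nausea.",
    ],
    "counseling": [
        "Discussed the interactions of stimulant medications with alcohol and {term}.",
        "I counseled the patient regarding {term} and its effects on bone healing.",
        "Reviewed risks of {term} with the family; no indication of any consumption.",
    ],
    "family_use": [
        "His brother has been smoking {term} in the house.",
        "Mother reports {term} use during pregnancy but has quit.",
        "Exposed to maternal {term} in utero.",
        "He is exposed to cigarette and {term} smoke in the hallways at home.",
    ],
    "bile_duct_confounder": [
        "Ultrasound shows the CBD dilated to 9 mm, gallbladder wall thickened.",
        "Abdominal pain workup: pancreas unremarkable, CBD within normal limits.",
        "Stones visualized in the common bile duct; CBD measures 7 mm.",
    ],
    "allergy_confounder": [
        "Allergy panel positive for ragweed and weed pollen.",
        "Seasonal allergies flaring; weed pollen exposure noted at home.",
        "Allergic rhinitis attributed to weed and grass pollen.",
    ],
}

_POSITIVE_TEMPLATES = ("affirmation", "tox_positive", "rx_medical")
_NEGATIVE_TEMPLATES = ("denial", "tox_negative", "counseling", "family_use")

# canonical seed(s) present in each fixed-term template
_FIXED_TEMPLATE_TERMS = {
    "MJ: +": ("mj",),
    "RX: DRONABINOL (MARINOL(2.5MG/TAB": ("dronabinol", "marinol"),
    "Ultrasound shows the CBD dilated to 9 mm, gallbladder wall thickened.": ("cbd",),
    "Abdominal pain workup: pancreas unremarkable, CBD within normal limits.": ("cbd",),
    "Stones visualized in the common bile duct; CBD measures 7 mm.": ("cbd",),
    "Allergy panel positive for ragweed and weed pollen.": ("weed",),
    "Seasonal allergies flaring; weed pollen exposure noted at home.": ("weed",),
    "Allergic rhinitis attributed to weed and grass pollen.": ("weed",),
}

_VOWELS = "aeiou"


def inject_misspellings(
    term: str,
    rate: float,
    rng: np.random.Generator | int,
    edit: tuple | None = None,
) -> str:
    """With probability ``rate``, apply one random edit to ``term``.

    Edits: interior character duplication, adjacent transposition, or
    insertion of a vowel/'h' digraph (e.g. marijuana -> marijuahana via
    ``edit=("insert", 7, "ha")``). Terms shorter than 4 characters are
    returned unchanged. An explicit ``edit`` bypasses the random draw.
    """
    if isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(int(rng))
    if len(term) < 4:
        return term
    if edit is None:
        if rng.random() >= rate:
            return term
        # short tokens only get conservative edits: any insertion moves a
        # 4-5 character profile too far for the expansion stage to attach
        kinds = ["duplicate", "transpose", "insert"] if len(term) >= 6 else [
            "duplicate", "transpose"
        ]
        kind = rng.choice(kinds)
        if kind == "duplicate":
            i = int(rng.integers(1, len(term) - 1))
            edit = ("duplicate", i, term[i])
        elif kind == "transpose":
            i = int(rng.integers(1, len(term) - 2)) if len(term) > 4 else 1
            edit = ("transpose", i, "")
        else:
            i = int(rng.integers(2, len(term) - 1))
            frag = str(rng.choice([v + "h" for v in _VOWELS] + ["h" + v for v in _VOWELS]))
            edit = ("insert", i, frag)
    kind, i, payload = edit
    if kind == "duplicate":
        return term[:i] + payload + term[i:]
    if kind == "transpose":
        return term[:i] + term[i + 1] + term[i] + term[i + 2 :]
    if kind == "insert":
        return term[:i] + payload + term[i:]
    raise SimError(f"unknown edit kind {kind!r}")


def _covariate_row(sex: str, race: str, svi: float | None) -> dict[str, float]:
    return {
        "female": float(sex == "female"),
        "race_asian": float(race == "asian"),
        "race_black": float(race == "black"),
        "race_hispanic": float(race == "hispanic"),
        "race_other": float(race == "other"),
        "svi_per_001": (svi if svi is not None else 0.271) * 100.0,
    }


def _linear(base: float, effects: dict[str, float], x: dict[str, float],
            center_svi: float = 27.1) -> float:
    lp = base
    for k, beta in effects.items():
        v = x.get(k, 0.0)
        if k == "svi_per_001":
            v -= center_svi  # center so the base log-odds is at the cohort mean
        lp += beta * v
    return lp


def generate_cohort(config: SimConfig) -> SimResult:
    """Generate patients, notes, diagnoses, and gold labels.

    Deterministic for a given config seed: one numpy Generator drives all
    draws in a fixed order.
    """
    problems = config.validate()
    if problems:
        raise SimError("invalid SimConfig: " + "; ".join(problems))
    rng = np.random.default_rng(config.seed)
    y0, y1 = config.years
    pos_base = config.pos_base_logodds

    sexes = list(config.sex_probs)
    sex_p = np.array([config.sex_probs[s] for s in sexes], dtype=float)
    sex_p /= sex_p.sum()
    races = list(config.race_probs)
    race_p = np.array([config.race_probs[r] for r in races], dtype=float)
    race_p /= race_p.sum()

    patients: list[Patient] = []
    notes: list[Note] = []
    gold: list[GoldRecord] = []
    diagnoses: list[DiagnosisRecord] = []
    doc_p_by_year: dict[int, list[float]] = {}

    tmpl_names = list(config.template_weights)
    tmpl_w = np.array([config.template_weights[t] for t in tmpl_names], dtype=float)

    def pick_template(allowed: tuple[str, ...]) -> str:
        idx = [tmpl_names.index(t) for t in allowed]
        w = tmpl_w[idx]
        w = w / w.sum()
        return str(allowed[int(rng.choice(len(allowed), p=w))])

    note_counter = 0
    for pi in range(config.n_patients):
        pid = f"P{pi:06d}"
        sex = str(rng.choice(sexes, p=sex_p))
        race = str(rng.choice(races, p=race_p))
        svi = None
        if rng.random() >= config.svi_missing_rate:
            svi = float(np.clip(rng.beta(*config.svi_beta), 0.0, 1.0))
        entry_year = int(rng.integers(y0, y1 + 1))
        age_at_entry = float(rng.uniform(1.0, 25.0))
        birth_date = dt.date(entry_year, 1, 1) - dt.timedelta(
            days=int(age_at_entry * 365.25)
        )
        patients.append(Patient(pid, sex, race, birth_date, svi))
        x = _covariate_row(sex, race, svi)

        duration = 1 + int(rng.geometric(1.0 / config.care_window_mean_years))
        last_year = min(y1, entry_year + duration - 1)
        patient_positive_dates: list[dt.date] = []

        for year in range(entry_year, last_year + 1):
            step = sum(
                s for cut, s in config.cutover_logodds_steps.items() if year >= cut
            )
            p_doc = float(expit(_linear(config.doc_base_logodds + step,
                                        config.doc_covariate_logor, x)))
            n_notes = int(rng.poisson(config.notes_per_patient_year))
            for _ in range(n_notes):
                day = int(rng.integers(0, 365))
                date = dt.date(year, 1, 1) + dt.timedelta(days=day)
                if date <= birth_date:
                    continue
                note_id = f"N{note_counter:08d}"
                note_counter += 1
                is_osm = bool(rng.random() < config.osm_fraction)
                doc_p_by_year.setdefault(year, []).append(p_doc)
                documented = bool(rng.random() < p_doc)
                age_at_note = (date - birth_date).days / 365.25

                injected_terms: tuple[str, ...] = ()
                injected_missp: tuple[str, ...] = ()
                sentence = None
                gold_label = None
                if documented:
                    if age_at_note < 7.0:
                        # household-exposure mention, never patient use
                        status = "family_use_negative"
                        tname = "family_use"
                        gold_label = "negative"
                        render_positive = False
                    else:
                        p_pos = float(expit(_linear(pos_base,
                                                    config.pos_covariate_logor, x)))
                        positive = bool(rng.random() < p_pos)
                        gold_label = "positive" if positive else "negative"
                        render_positive = positive
                        if rng.random() < config.label_noise:
                            render_positive = not positive
                        tname = pick_template(
                            _POSITIVE_TEMPLATES if render_positive else _NEGATIVE_TEMPLATES
                        )
                        if positive:
                            status = (
                                "medical_rx_positive" if tname == "rx_medical"
                                else "documented_positive"
                            )
                        else:
                            status = (
                                "family_use_negative" if tname == "family_use"
                                else "documented_negative"
                            )
                    template = str(rng.choice(TEMPLATES[tname]))
                    if template in _FIXED_TEMPLATE_TERMS:
                        sentence = template
                        injected_terms = _FIXED_TEMPLATE_TERMS[template]
                    else:
                        pool = (
                            MEDICAL_TERMS_POOL if tname == "rx_medical"
                            else RECREATIONAL_TERMS
                        )
                        term = str(rng.choice(pool))
                        surface = inject_misspellings(term, config.misspelling_rate, rng)
                        if surface != term:
                            injected_missp = (surface,)
                        injected_terms = (term,)
                        sentence = template.format(term=surface)
                    if status in _POSITIVE_GOLD:
                        patient_positive_dates.append(date)
                else:
                    if rng.random() < config.confounder_rate:
                        w_bile = config.template_weights["bile_duct_confounder"]
                        w_all = config.template_weights["allergy_confounder"]
                        p_bile = w_bile / (w_bile + w_all) if (w_bile + w_all) else 0.5
                        if rng.random() < p_bile:
                            tname, status = "bile_duct_confounder", "confounder_bile_duct"
                        else:
                            tname, status = "allergy_confounder", "confounder_allergy"
                        sentence = str(rng.choice(TEMPLATES[tname]))
                        injected_terms = _FIXED_TEMPLATE_TERMS[sentence]
                    else:
                        status = "no_mention"

                n_filler = int(rng.integers(2, 5))
                parts = [str(s) for s in rng.choice(FILLER, size=n_filler, replace=False)]
                if sentence is not None:
                    pos_idx = int(rng.integers(0, len(parts) + 1))
                    parts.insert(pos_idx, sentence)
                text = " ".join(parts)
                notes.append(Note(note_id, pid, date, is_osm, text))
                gold.append(
                    GoldRecord(
                        note_id=note_id,
                        true_status=status,
                        injected_terms=injected_terms,
                        injected_misspellings=injected_missp,
                        gold_sentence_label=gold_label,
                    )
                )

        # diagnoses
        if patient_positive_dates and rng.random() < config.dx_given_positive:
            code, vocab = [
                ("F12.20", "ICD-10-CM"),
                ("F12.10", "ICD-10-CM"),
                ("F12.90", "ICD-10-CM"),
                ("305.20", "ICD-9-CM"),
                ("304.30", "ICD-9-CM"),
                ("T40.7X1A", "ICD-10-CM"),
                ("7344009", "SNOMED-CT"),
                ("28823006", "SNOMED-CT"),
            ][int(rng.integers(0, 8))]
            diagnoses.append(
                DiagnosisRecord(pid, code, vocab, min(patient_positive_dates))
            )
        if rng.random() < config.background_dx_rate:
            code, vocab = [
                ("M25.50", "ICD-10-CM"),
                ("S52.501A", "ICD-10-CM"),
                ("733.82", "ICD-9-CM"),
                ("125605004", "SNOMED-CT"),
            ][int(rng.integers(0, 4))]
            diagnoses.append(
                DiagnosisRecord(pid, code, vocab, dt.date(entry_year, 6, 15))
            )

    year_rate = {y: float(np.mean(ps)) for y, ps in sorted(doc_p_by_year.items())}
    return SimResult(
        patients=patients,
        notes=notes,
        diagnoses=diagnoses,
        gold=gold,
        config=config,
        year_expected_doc_rate=year_rate,
    )


def gold_patient_status(result: SimResult) -> list[PatientStatus]:
    """Patient statuses implied by the gold note records."""
    note_by_id = {n.note_id: n for n in result.notes}
    first_pos: dict[str, dt.date] = {}
    documented: set[str] = set()
    for g in result.gold:
        note = note_by_id[g.note_id]
        if g.true_status in _POSITIVE_GOLD:
            cur = first_pos.get(note.patient_id)
            if cur is None or note.date < cur:
                first_pos[note.patient_id] = note.date
        if g.true_status in _POSITIVE_GOLD or g.true_status in (
            "documented_negative", "family_use_negative"
        ):
            documented.add(note.patient_id)
    birth = {p.patient_id: p.birth_date for p in result.patients}
    out = []
    for p in result.patients:
        pid = p.patient_id
        if pid in first_pos:
            d0 = first_pos[pid]
            out.append(
                PatientStatus(
                    pid, "positive", d0, (d0 - birth[pid]).days / 365.25
                )
            )
        elif pid in documented:
            out.append(PatientStatus(pid, "negative_documented"))
        else:
            out.append(PatientStatus(pid, "undocumented"))
    return out


def gold_confusion(
    pipeline_statuses: dict[str, str],
    gold: list[GoldRecord],
) -> "pd.DataFrame":
    """Screening-stage confusion: gold note status x pipeline decision.

    ``pipeline_statuses`` maps note_id -> ScreenDecision status. Returns a
    contingency table (rows = gold, columns = pipeline).
    """
    import pandas as pd

    rows = []
    for g in gold:
        rows.append((g.true_status, pipeline_statuses.get(g.note_id, "missing")))
    df = pd.DataFrame(rows, columns=["gold", "pipeline"])
    return pd.crosstab(df["gold"], df["pipeline"])


def plant_patient_outcomes(
    n: int,
    effects: dict[str, float],
    base_logodds: float,
    seed: int,
    config: SimConfig | None = None,
) -> tuple[list[Patient], list[PatientStatus]]:
    """Patient-level logistic simulation for disparity parameter recovery.

    Draws demographics from the standard generator distributions, then a
    binary positive-use outcome from ``expit(base + effects . x)`` (SVI
    entered per 0.01 units, centered at the cohort mean). Returns patients
    plus statuses (positive / negative_documented).
    """
    config = config or SimConfig()
    rng = np.random.default_rng(seed)
    sexes = list(config.sex_probs)
    sex_p = np.array([config.sex_probs[s] for s in sexes], dtype=float)
    sex_p /= sex_p.sum()
    races = list(config.race_probs)
    race_p = np.array([config.race_probs[r] for r in races], dtype=float)
    race_p /= race_p.sum()
    patients, statuses = [], []
    d0 = dt.date(2015, 6, 1)
    for i in range(n):
        pid = f"S{i:06d}"
        sex = str(rng.choice(sexes, p=sex_p))
        race = str(rng.choice(races, p=race_p))
        svi = float(np.clip(rng.beta(*config.svi_beta), 0.0, 1.0))
        x = _covariate_row(sex, race, svi)
        p = float(expit(_linear(base_logodds, effects, x)))
        y = rng.random() < p
        patients.append(Patient(pid, sex, race, dt.date(2000, 1, 1), svi))
        statuses.append(
            PatientStatus(pid, "positive" if y else "negative_documented",
                          d0 if y else None, 15.4 if y else None)
        )
    return patients, statuses
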