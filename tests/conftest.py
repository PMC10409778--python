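import datetime as dt

import pytest

from cannascreen.lexicon import Lexicon, build_lexicon, expand_misspellings
from cannascreen.screening import Note

# Curated clinical example sentences covering the documented use patterns:
# self-report, template fields, prescription cannabinoids, toxicology, and
# the classic negatives (denial, negative tox, counseling-only discussion,
# use attributed to a family member).
EXAMPLE_SENTENCES = [
    ("Pt admits to smoking marijuana daily", "positive"),
    ("MJ: +", "positive"),
    (
        "agreed to try marinol with relief, continued scopolamine patch and all "
        "other antiemetics changed to prn. Be aware you may be light-headed or "
        "dizzy while using marinol RX: DRONABINOL (MARINOL(2.5MG/TAB",
        "positive",
    ),
    (
        'Denies drugs or alcohol; states used marijuana "one year ago". '
        "Urine tox screen: positive for amphetamines and cannabis.",
        "positive",
    ),
    (
        "He has not tried any other drugs and denies any use of marijuana, "
        "cocaine, heroine, or other drug abuse.",
        "negative",
    ),
    (
        "Labs—Urine tox sent—negative for amphetamines, barbiturates, benzos, "
        "cannabis, cocaine, opiates, PCP Wrist films and R hand film "
        "done—Negative for fracture",
        "negative",
    ),
    (
        "I discussed the interactions of stimulant medications with alcohol, "
        "which increases the concentration of the stimulant, and marijuana, "
        "which increases the heart rate with the use of stimulant medication.",
        "negative",
    ),
    (
        "CRAFFT score is 1; he has been in the car when his brother has been "
        "smoking marijuana and driving, but his brothers will not allow him to "
        "do this.",
        "negative",
    ),
]

# Household-exposure mentions typical of patients under age 7.
UNDER7_SENTENCES = [
    "Other tobacco history: Mother smoked but has quit, also use of MJ during "
    "pregnancy but has quit as well.",
    "Birth Hx: Exposed to maternal THC in utero.",
    "Pregnancy is complicated by late care, inconsistent prenatal care, "
    "marijuana use, and viral illness 5 days prior to delivery.",
    "He lives with his mother and occasionally with his grandmother in the "
    "housing projects where she says he is exposed to cigarette and marijuana "
    "smoke in the hallways.",
]


@pytest.fixture(scope="session")
def lexicon() -> Lexicon:
    return build_lexicon()


@pytest.fixture(scope="session")
def expanded_lexicon() -> Lexicon:
    lex = build_lexicon()
    lex.misspellings = expand_misspellings(["marijuahana", "cannabiss"], lex)
    return lex


def make_note(text: str, note_id="n1", patient_id="p1", date=dt.date(2018, 6, 1), is_osm=False):
    return Note(note_id=note_id, patient_id=patient_id, date=date, is_osm=is_osm, text=text)
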