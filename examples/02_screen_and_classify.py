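"""Screen clinical notes and label keyword sentences.

Demonstrates the full note-level cascade on hand-written notes: keyword
retrieval, context exclusion for the two ambiguous terms (CBD as common
bile duct, weed as allergen), the age filter, sentence extraction, and
the rule-based polarity labeler.
"""

import datetime as dt

from cannascreen.classify import rule_based_label
from cannascreen.lexicon import build_lexicon
from cannascreen.screening import Note, extract_cannabis_sentences, screen_notes

NOTES = [
    Note("n01", "teen-1", dt.date(2018, 5, 2), True,
         "Presents with knee pain after soccer. Pt admits to smoking "
         "marijuana daily. Plan: physical therapy."),
    Note("n02", "teen-2", dt.date(2017, 9, 9), True,
         "Denies drugs or alcohol. Urine tox screen: positive for "
         "amphetamines and cannabis."),
    Note("n03", "teen-3", dt.date(2019, 1, 15), False,
         "He has not tried any other drugs and denies any use of "
         "marijuana, cocaine, or other drug abuse."),
    Note("n04", "adult-1", dt.date(2016, 3, 3), False,
         "Ultrasound shows the CBD dilated to 9 mm, gallbladder wall "
         "thickened."),
    Note("n05", "teen-4", dt.date(2015, 7, 21), False,
         "Allergy panel positive for ragweed and weed pollen."),
    Note("n06", "infant-1", dt.date(2019, 3, 1), False,
         "Birth Hx: Exposed to maternal THC in utero."),
    Note("n07", "teen-5", dt.date(2020, 11, 30), True,
         "Ankle sprain, RICE protocol advised. Return in two weeks."),
]

BIRTH_DATES = {
    "teen-1": dt.date(2003, 1, 1),
    "teen-2": dt.date(2002, 6, 1),
    "teen-3": dt.date(2004, 2, 1),
    "adult-1": dt.date(1980, 1, 1),
    "teen-4": dt.date(2001, 1, 1),
    "infant-1": dt.date(2018, 10, 1),
    "teen-5": dt.date(2005, 5, 5),
}


def main() -> None:
    lexicon = build_lexicon()
    decisions = screen_notes(NOTES, lexicon, BIRTH_DATES)

    notes_by_id = {n.note_id: n for n in NOTES}
    for decision in decisions:
        note = notes_by_id[decision.note_id]
        print(f"{note.note_id}  {decision.status:<20} {note.text[:58]}...")
        if decision.status != "screened_in":
            continue
        for sh in extract_cannabis_sentences(note, lexicon, decision):
            label = rule_based_label(sh.sentence_text, lexicon,
                                     note_id=sh.note_id,
                                     sentence_index=sh.sentence_index)
            terms = ",".join(sorted({h.canonical_seed for h in sh.hits}))
            print(f"      sentence {sh.sentence_index} [{terms}] -> "
                  f"{label.label.upper()}  \"{sh.sentence_text}\"")


if __name__ == "__main__":
    main()
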