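"""Note screening: keyword retrieval, context exclusions, age filter,
and keyword-anchored sentence extraction.

Pipeline order per note: keyword match -> context exclusion (bile duct /
allergy readings of ambiguous terms) -> minimum-age filter -> sentence
extraction. A note failing an earlier stage never reaches later stages.
"""

from __future__ import annotations

import datetime as dt
import re
from collections import Counter
from dataclasses import dataclass, field

from .lexicon import Lexicon

__all__ = [
    "Note",
    "KeywordHit",
    "SentenceHit",
    "ScreenDecision",
    "find_keyword_hits",
    "apply_context_exclusions",
    "passes_age_filter",
    "split_sentences",
    "extract_cannabis_sentences",
    "keyword_histogram",
    "screen_notes",
    "STATUSES",
]

STATUSES = (
    "no_mention",
    "excluded_bile_duct",
    "excluded_allergy",
    "excluded_underage",
    "screened_in",
)

DAYS_PER_YEAR = 365.25


class ScreeningError(ValueError):
    pass


@dataclass(frozen=True)
class Note:
    note_id: str
    patient_id: str
    date: dt.date
    is_osm: bool
    text: str


@dataclass(frozen=True)
class KeywordHit:
    matched_term: str     # surface form as matched (lowercased)
    canonical_seed: str   # dictionary term the match resolves to
    start: int
    end: int


@dataclass(frozen=True)
class SentenceHit:
    note_id: str
    sentence_index: int
    sentence_text: str
    hits: tuple[KeywordHit, ...]


@dataclass(frozen=True)
class ScreenDecision:
    note_id: str
    status: str
    hits: tuple[KeywordHit, ...] = ()

    def __post_init__(self) -> None:
        if self.status not in STATUSES:
            raise ScreeningError(f"unknown screen status {self.status!r}")


def _term_pattern(lexicon: Lexicon) -> tuple[re.Pattern, dict[str, str]]:
    """One alternation regex over all dictionary terms and variants.

    Longest terms first so overlapping matches keep the longest; word
    boundaries enforce whole-token matching (so 'seaweed' never hits
    'weed').
    """
    canon: dict[str, str] = {}
    for t in lexicon.all_terms():
        canon[t] = t
    canon.update(lexicon.variant_to_term())
    alts = sorted(canon, key=lambda t: (-len(t), t))
    pat = re.compile(
        r"(?<![A-Za-z])(" + "|".join(re.escape(t) for t in alts) + r")(?![A-Za-z])",
        re.IGNORECASE,
    )
    return pat, canon


def find_keyword_hits(text: str, lexicon: Lexicon) -> list[KeywordHit]:
    """Whole-token, case-insensitive matches of all dictionary terms.

    'mj' is only accepted when the surface form is uppercase 'MJ' or is
    immediately followed by ':' — lowercase 'mj' in running prose is
    overwhelmingly noise.
    """
    pat, canon = _term_pattern(lexicon)
    hits: list[KeywordHit] = []
    for m in pat.finditer(text):
        surface = m.group(1)
        matched = surface.lower()
        if matched == "mj":
            follows_colon = text[m.end() : m.end() + 1] == ":"
            if surface != "MJ" and not follows_colon:
                continue
        hits.append(
            KeywordHit(
                matched_term=matched,
                canonical_seed=canon[matched],
                start=m.start(),
                end=m.end(),
            )
        )
    return hits


def _contains_any(text_lower: str, keywords: list[str]) -> bool:
    for kw in keywords:
        if re.search(r"(?<![A-Za-z])" + re.escape(kw.lower()) + r"(?![A-Za-z])", text_lower):
            return True
    return False


def apply_context_exclusions(
    note: Note, hits: list[KeywordHit], lexicon: Lexicon
) -> ScreenDecision:
    """Resolve ambiguous-term notes to an exclusion or screened_in.

    A note whose only dictionary hits are 'cbd' is excluded when a
    bile-duct context keyword co-occurs; likewise 'weed'-only notes with
    allergy context. Any unambiguous term (marijuana, thc, ...) keeps the
    note screened in regardless of context.
    """
    if not hits:
        return ScreenDecision(note.note_id, "no_mention")
    seeds = {h.canonical_seed for h in hits}
    text_lower = note.text.lower()
    if seeds == {"cbd"} and _contains_any(text_lower, lexicon.exclusion_sets["bile_duct"]):
        return ScreenDecision(note.note_id, "excluded_bile_duct", tuple(hits))
    if seeds == {"weed"} and _contains_any(text_lower, lexicon.exclusion_sets["allergy"]):
        return ScreenDecision(note.note_id, "excluded_allergy", tuple(hits))
    return ScreenDecision(note.note_id, "screened_in", tuple(hits))


def passes_age_filter(
    birth_date: dt.date, note_date: dt.date, min_age_years: float = 7.0
) -> bool:
    """True iff the patient is at least ``min_age_years`` old at the note date."""
    if birth_date > note_date:
        raise ScreeningError(
            f"birth date {birth_date} after note date {note_date}"
        )
    age = (note_date - birth_date).days / DAYS_PER_YEAR
    return age >= min_age_years


# -- sentence splitting -------------------------------------------------

# Clinical abbreviations whose trailing period is not a sentence boundary.
_ABBREVIATIONS = {
    "dr", "mr", "mrs", "ms", "prn", "pt", "hx", "dx", "rx", "fx",
    "b.i.d", "t.i.d", "q.d", "q.i.d", "vs", "e.g", "i.e", "etc",
    "approx", "mo", "yr", "wk", "st", "no",
}

_BOUNDARY = re.compile(r"[.!?;\n]")


def split_sentences(text: str) -> list[tuple[int, int]]:
    """Rule-based sentence spans over clinical text.

    Splits at '.', '!', '?', ';' and newlines, except when the period
    sits inside a number or drug string (digit on either side) or closes
    a known clinical abbreviation. Spans are trimmed of surrounding
    whitespace, ordered, non-overlapping, and cover all non-blank text.
    """
    spans: list[tuple[int, int]] = []
    start = 0
    i = 0
    n = len(text)
    while i < n:
        ch = text[i]
        if _BOUNDARY.match(ch):
            if ch == ".":
                prev = text[i - 1] if i > 0 else ""
                nxt = text[i + 1] if i + 1 < n else ""
                if prev.isdigit() and nxt.isdigit():
                    i += 1
                    continue
                word = re.search(r"[A-Za-z.]+$", text[start:i])
                if word and word.group(0).lower().rstrip(".") in _ABBREVIATIONS:
                    i += 1
                    continue
            spans.append((start, i + 1))
            start = i + 1
        i += 1
    if start < n:
        spans.append((start, n))
    trimmed = []
    for s, e in spans:
        seg = text[s:e]
        ls = len(seg) - len(seg.lstrip())
        rs = len(seg) - len(seg.rstrip())
        if s + ls < e - rs:
            trimmed.append((s + ls, e - rs))
    return trimmed


def extract_cannabis_sentences(
    note: Note,
    lexicon: Lexicon,
    decision: ScreenDecision | None = None,
) -> list[SentenceHit]:
    """Exactly the sentences of a screened-in note containing >= 1 hit.

    Hits are re-based to sentence-local character offsets. Raises when
    called on a note whose decision is not screened_in.
    """
    if decision is not None and decision.status != "screened_in":
        raise ScreeningError(
            f"extract_cannabis_sentences called on {decision.status} note {note.note_id}"
        )
    hits = list(decision.hits) if decision is not None else find_keyword_hits(note.text, lexicon)
    out: list[SentenceHit] = []
    for idx, (s, e) in enumerate(split_sentences(note.text)):
        local = [
            KeywordHit(h.matched_term, h.canonical_seed, h.start - s, h.end - s)
            for h in hits
            if s <= h.start and h.end <= e
        ]
        if local:
            out.append(
                SentenceHit(
                    note_id=note.note_id,
                    sentence_index=idx,
                    sentence_text=note.text[s:e],
                    hits=tuple(local),
                )
            )
    return out


def keyword_histogram(decisions: list[ScreenDecision]) -> dict[str, int]:
    """Per-term count of distinct notes with >= 1 hit for that term."""
    counts: Counter[str] = Counter()
    for d in decisions:
        for seed in {h.canonical_seed for h in d.hits}:
            counts[seed] += 1
    return dict(counts)


def screen_notes(
    notes: list[Note],
    lexicon: Lexicon,
    birth_dates: dict[str, dt.date] | None = None,
    min_age_years: float = 7.0,
) -> list[ScreenDecision]:
    """Run the full screening cascade over a note list.

    ``birth_dates`` maps patient_id -> birth date; when provided, notes
    written before the patient's ``min_age_years`` birthday that would
    otherwise screen in are excluded as underage (household-exposure
    mentions, not patient use).
    """
    decisions: list[ScreenDecision] = []
    for note in notes:
        hits = find_keyword_hits(note.text, lexicon)
        decision = apply_context_exclusions(note, hits, lexicon)
        if decision.status == "screened_in" and birth_dates is not None:
            bd = birth_dates.get(note.patient_id)
            if bd is not None and not passes_age_filter(bd, note.date, min_age_years):
                decision = ScreenDecision(note.note_id, "excluded_underage", tuple(hits))
        decisions.append(decision)
    return decisions
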