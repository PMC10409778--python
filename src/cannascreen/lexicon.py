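"""Cannabis-term lexicon with character n-gram misspelling expansion.

The dictionary holds seed keywords (colloquial cannabis terms), medical
terms (prescription cannabinoids), and per-term accepted misspellings.
Misspellings are discovered by comparing the combined character 1–3-gram
count vector of every corpus vocabulary word against each dictionary term
with cosine similarity: a word clearing a term's threshold (default 0.70)
is accepted as a spelling variant of that term.
"""

from __future__ import annotations

import json
import math
import re
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path

import yaml

__all__ = [
    "NGramProfile",
    "Lexicon",
    "char_ngram_profile",
    "ngram_cosine",
    "expand_misspellings",
    "build_lexicon",
    "DEFAULT_SEEDS",
    "DEFAULT_MEDICAL_TERMS",
    "DEFAULT_THRESHOLD",
]

DEFAULT_SEEDS = ["marijuana", "cannabis", "cbd", "weed", "thc", "mj"]
DEFAULT_MEDICAL_TERMS = [
    "tetrahydrocannabinol",
    "epidiolex",
    "cannabidiol",
    "marinol",
    "dronabinol",
    "syndros",
    "cesamet",
]
DEFAULT_THRESHOLD = 0.70

# Per-keyword manual threshold overrides. Short common-word keywords need a
# stricter bar: at 0.70 'weed' absorbs ordinary English ('needed', 'ragweed',
# 'seaweed', similarity 0.72-0.80) while true single-edit variants score
# >= 0.88, so 0.85 separates them cleanly.
DEFAULT_TERM_THRESHOLDS = {"weed": 0.85}

# Context keywords marking notes where an ambiguous term refers to a
# non-cannabis concept: CBD = common bile duct; weed = plant/allergen.
DEFAULT_BILE_DUCT_KEYWORDS = [
    "abdominal",
    "gallbladder",
    "pancreas",
    "common bile duct",
    "bile duct",
    "biliary",
    "cholecystitis",
    "cholangiogram",
]
DEFAULT_ALLERGY_KEYWORDS = [
    "pollen",
    "allergy",
    "allergies",
    "allergic",
    "allergen",
    "ragweed",
    "antihistamine",
]

# Dictionary terms shorter than this are skipped during misspelling
# expansion: character n-gram cosine is promiscuous on 2–3 letter tokens.
DEFAULT_MIN_EXPAND_LENGTH = 4

_NON_LETTER = re.compile(r"[^a-z]+")


class LexiconError(ValueError):
    """Invalid lexicon configuration or input."""


def normalize_token(token: str) -> str:
    """Lowercase and strip non-letter characters."""
    return _NON_LETTER.sub("", token.lower())


@dataclass(frozen=True)
class NGramProfile:
    """Combined character n-gram count vector for one normalized token.

    Counts for every contiguous substring of length n_min..n_max are held
    in a single vector so that one cosine covers all gram sizes at once.
    """

    token: str
    n_min: int
    n_max: int
    counts: dict[str, int] = field(hash=False)

    def norm(self) -> float:
        return math.sqrt(sum(v * v for v in self.counts.values()))


def char_ngram_profile(token: str, n_min: int = 1, n_max: int = 3) -> NGramProfile:
    """Build the combined character n-gram count profile of ``token``.

    The token is normalized (lowercased, non-letters stripped) first.
    Gram sizes run from ``n_min`` to ``min(n_max, len(token))``.

    Raises
    ------
    LexiconError
        If the token is empty after normalization, or the n-range is
        invalid (n_min < 1, n_min > n_max, or n_min > token length).
    """
    norm_tok = normalize_token(token)
    if not norm_tok:
        raise LexiconError(f"token {token!r} is empty after normalization")
    if n_min < 1 or n_min > n_max:
        raise LexiconError(f"invalid n-gram range [{n_min}, {n_max}]")
    if n_min > len(norm_tok):
        raise LexiconError(
            f"n_min={n_min} exceeds normalized token length {len(norm_tok)}"
        )
    counts: Counter[str] = Counter()
    for n in range(n_min, min(n_max, len(norm_tok)) + 1):
        for i in range(len(norm_tok) - n + 1):
            counts[norm_tok[i : i + n]] += 1
    return NGramProfile(token=norm_tok, n_min=n_min, n_max=n_max, counts=dict(counts))


def ngram_cosine(a: NGramProfile, b: NGramProfile) -> float:
    """Cosine similarity A·B / (|A||B|) over the union of n-gram keys.

    Symmetric, bounded in [0, 1]; 0 when supports are disjoint.
    Both profiles must be built with the same declared (n_min, n_max).
    """
    if (a.n_min, a.n_max) != (b.n_min, b.n_max):
        raise LexiconError(
            f"mismatched n-gram ranges: [{a.n_min},{a.n_max}] vs [{b.n_min},{b.n_max}]"
        )
    dot = 0
    small, large = (a.counts, b.counts) if len(a.counts) <= len(b.counts) else (b.counts, a.counts)
    for key, v in small.items():
        w = large.get(key)
        if w:
            dot += v * w
    if dot == 0:
        return 0.0
    return min(1.0, dot / (a.norm() * b.norm()))


@dataclass
class Lexicon:
    """The cannabis-term dictionary used by the screening stage."""

    seed_terms: list[str] = field(default_factory=lambda: list(DEFAULT_SEEDS))
    medical_terms: list[str] = field(default_factory=lambda: list(DEFAULT_MEDICAL_TERMS))
    misspellings: dict[str, list[str]] = field(default_factory=dict)
    thresholds: dict[str, float] = field(default_factory=dict)
    exclusion_sets: dict[str, list[str]] = field(
        default_factory=lambda: {
            "bile_duct": list(DEFAULT_BILE_DUCT_KEYWORDS),
            "allergy": list(DEFAULT_ALLERGY_KEYWORDS),
        }
    )
    min_expand_length: int = DEFAULT_MIN_EXPAND_LENGTH

    def __post_init__(self) -> None:
        self.seed_terms = [normalize_token(t) or t for t in self.seed_terms]
        self.medical_terms = [normalize_token(t) or t for t in self.medical_terms]
        for term in self.all_terms():
            self.thresholds.setdefault(
                term, DEFAULT_TERM_THRESHOLDS.get(term, DEFAULT_THRESHOLD)
            )
        self.validate()

    def all_terms(self) -> list[str]:
        return self.seed_terms + self.medical_terms

    def expandable_terms(self) -> list[str]:
        return [t for t in self.all_terms() if len(t) >= self.min_expand_length]

    def variant_to_term(self) -> dict[str, str]:
        """Map every accepted misspelling to its canonical term."""
        out: dict[str, str] = {}
        for term, variants in self.misspellings.items():
            for v in variants:
                out[v] = term
        return out

    def validate(self) -> None:
        terms = self.all_terms()
        if not self.seed_terms:
            raise LexiconError("lexicon must contain at least one seed term")
        if len(set(terms)) != len(terms):
            dupes = sorted({t for t in terms if terms.count(t) > 1})
            raise LexiconError(f"duplicate lexicon terms: {dupes}")
        for term in terms:
            if not term:
                raise LexiconError("empty lexicon term")
            thr = self.thresholds.get(term)
            if thr is None:
                raise LexiconError(f"missing threshold for term {term!r}")
            if not (0.0 < thr <= 1.0):
                raise LexiconError(f"threshold {thr} for {term!r} outside (0, 1]")
        seen: dict[str, str] = {}
        for term, variants in self.misspellings.items():
            if term not in terms:
                raise LexiconError(f"misspellings attached to unknown term {term!r}")
            for v in variants:
                if v in seen and seen[v] != term:
                    raise LexiconError(f"variant {v!r} maps to multiple terms")
                seen[v] = term

    # -- serialization -------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "seeds": self.seed_terms,
            "medical_terms": self.medical_terms,
            "misspellings": self.misspellings,
            "thresholds": self.thresholds,
            "exclusions": self.exclusion_sets,
            "min_expand_length": self.min_expand_length,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "Lexicon":
        return cls(
            seed_terms=list(d.get("seeds") or DEFAULT_SEEDS),
            medical_terms=list(d.get("medical_terms") or DEFAULT_MEDICAL_TERMS),
            misspellings={k: list(v) for k, v in (d.get("misspellings") or {}).items()},
            thresholds=dict(d.get("thresholds") or {}),
            exclusion_sets={
                "bile_duct": list(
                    (d.get("exclusions") or {}).get("bile_duct", DEFAULT_BILE_DUCT_KEYWORDS)
                ),
                "allergy": list(
                    (d.get("exclusions") or {}).get("allergy", DEFAULT_ALLERGY_KEYWORDS)
                ),
            },
            min_expand_length=int(d.get("min_expand_length", DEFAULT_MIN_EXPAND_LENGTH)),
        )

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2, sort_keys=True) + "\n")

    @classmethod
    def load(cls, path: str | Path) -> "Lexicon":
        path = Path(path)
        text = path.read_text()
        if path.suffix in {".yml", ".yaml"}:
            return cls.from_dict(yaml.safe_load(text) or {})
        return cls.from_dict(json.loads(text))


def build_lexicon(config: str | Path | dict | None = None) -> Lexicon:
    """Build a validated :class:`Lexicon` from a YAML/JSON config.

    ``config`` may be a path, an already-parsed mapping, or ``None``
    (all defaults). Missing keys fall back to the default seed words,
    medical terms, exclusion keyword sets, and a 0.70 threshold per term.
    """
    if config is None:
        return Lexicon()
    if isinstance(config, dict):
        return Lexicon.from_dict(config)
    return Lexicon.load(config)


def expand_misspellings(
    vocabulary: list[str],
    lexicon: Lexicon,
    n_min: int = 1,
    n_max: int = 3,
) -> dict[str, list[str]]:
    """Attach corpus vocabulary words to dictionary terms as misspellings.

    A vocabulary word ``w`` is accepted as a spelling variant of term ``s``
    iff ``ngram_cosine(w, s) >= thresholds[s]``, ``w`` is not itself a
    dictionary term, and ``s`` achieves the highest similarity among terms
    whose threshold ``w`` clears (ties broken by lexicographic term order).
    Terms shorter than ``lexicon.min_expand_length`` are not expanded.

    Returns a map term -> sorted list of accepted variants (terms with no
    variants are omitted).
    """
    terms = lexicon.expandable_terms()
    if not terms:
        return {}
    term_profiles = {t: char_ngram_profile(t, n_min, n_max) for t in terms}
    known = set(lexicon.all_terms())
    out: dict[str, list[str]] = {}
    seen: set[str] = set()
    for raw in vocabulary:
        w = normalize_token(raw)
        if not w or w in known or w in seen:
            continue
        seen.add(w)
        try:
            wp = char_ngram_profile(w, n_min, n_max)
        except LexiconError:
            continue
        best_term = None
        best_sim = -1.0
        for t in sorted(terms):
            sim = ngram_cosine(wp, term_profiles[t])
            if sim >= lexicon.thresholds[t] and sim > best_sim:
                best_term, best_sim = t, sim
        if best_term is not None:
            out.setdefault(best_term, []).append(w)
    return {t: sorted(vs) for t, vs in out.items()}


def expansion_report(
    vocabulary: list[str], lexicon: Lexicon, n_min: int = 1, n_max: int = 3
) -> list[dict]:
    """Per-variant similarity report for an expansion run."""
    expanded = expand_misspellings(vocabulary, lexicon, n_min, n_max)
    rows = []
    for term, variants in sorted(expanded.items()):
        tp = char_ngram_profile(term, n_min, n_max)
        for v in variants:
            sim = ngram_cosine(char_ngram_profile(v, n_min, n_max), tp)
            rows.append(
                {
                    "term": term,
                    "variant": v,
                    "similarity": round(sim, 4),
                    "threshold": lexicon.thresholds[term],
                }
            )
    return rows
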