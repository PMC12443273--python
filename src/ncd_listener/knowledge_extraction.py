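"""Lexicon-based knowledge extraction.

Populates the eight dashboard variables for each comment by keyword
matching against a bilingual category lexicon: mentioned diseases, symptoms,
treatments and behaviours/causes, the patient's gender (explicit cue words
only), the source of the opinion (self / family member / acquaintance /
general), the classifier's comment category (filled elsewhere), and the
corpus-level word-frequency table.

Matching rules (per language):

* English terms are normalized with the same pipeline as comments and
  matched as contiguous subsequences of the comment's normalized token
  stream, so inflectional variants ("diagnosed with diabetes" vs "diabetic")
  reduce to the lexicon's forms.
* Thai terms are matched as substrings of the raw, unsegmented comment text,
  because word segmentation may split a lexicon term across token
  boundaries.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources as _ilr
from pathlib import Path
from typing import Iterable, Sequence

import yaml

from . import nlp_core
from .nlp_core import TokenizedComment

__all__ = [
    "CATEGORIES",
    "LexiconEntry",
    "Lexicon",
    "ExtractedKnowledge",
    "LexiconError",
    "load_lexicon",
    "default_lexicon",
    "match_category",
    "extract_variables",
    "word_frequency",
    "adjust_selection",
]

CATEGORIES = (
    "disease",
    "symptom",
    "treatment",
    "behavior_cause",
    "gender_cue",
    "source_cue",
)


class LexiconError(ValueError):
    """Raised for schema violations in lexicon files."""


@dataclass(frozen=True)
class LexiconEntry:
    """One concept: a canonical label with its English and Thai surface terms."""

    label: str
    en: tuple[str, ...] = ()
    th: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if not self.en and not self.th:
            raise LexiconError(f"entry {self.label!r} has no terms in any language")


@dataclass
class Lexicon:
    """Category-keyed term lists driving keyword extraction."""

    categories: dict[str, list[LexiconEntry]]

    def __post_init__(self) -> None:
        for cat, entries in self.categories.items():
            if cat not in CATEGORIES:
                raise LexiconError(f"unknown lexicon category {cat!r}")
            if not entries:
                raise LexiconError(f"category {cat!r} has an empty entry list")
            labels = [e.label for e in entries]
            dupes = {l for l in labels if labels.count(l) > 1}
            if dupes:
                raise LexiconError(f"duplicate labels in category {cat!r}: {sorted(dupes)}")

    def entries(self, category: str) -> list[LexiconEntry]:
        return self.categories.get(category, [])

    def with_entry(self, category: str, entry: LexiconEntry) -> "Lexicon":
        cats = {c: list(es) for c, es in self.categories.items()}
        cats.setdefault(category, []).append(entry)
        return Lexicon(cats)


@dataclass
class ExtractedKnowledge:
    """Per-comment values of the dashboard variables."""

    seq: int
    gender: str = "unknown"  # male / female / unknown
    source: str = "general"  # self / family_member / acquaintance / general / unknown
    category: str | None = None  # sharing_experience / inquiring / non_informative
    diseases: list[str] = field(default_factory=list)
    symptoms: list[str] = field(default_factory=list)
    treatments: list[str] = field(default_factory=list)
    behaviors: list[str] = field(default_factory=list)

    def labels(self, variable: str) -> list[str]:
        return {
            "disease": self.diseases,
            "symptom": self.symptoms,
            "treatment": self.treatments,
            "behavior_cause": self.behaviors,
        }[variable]


def load_lexicon(path: str | Path) -> Lexicon:
    """Load and validate a YAML lexicon (category -> [{label, en, th}, ...])."""
    with open(path, "r", encoding="utf-8") as fh:
        doc = yaml.safe_load(fh)
    return _lexicon_from_mapping(doc, str(path))


def default_lexicon() -> Lexicon:
    """The starter NCD lexicon shipped with the package."""
    text = _ilr.files("ncd_listener.resources").joinpath("lexicon.yaml").read_text("utf-8")
    return _lexicon_from_mapping(yaml.safe_load(text), "<builtin lexicon>")


def _lexicon_from_mapping(doc: object, origin: str) -> Lexicon:
    if not isinstance(doc, dict):
        raise LexiconError(f"{origin}: top level must be a mapping of categories")
    categories: dict[str, list[LexiconEntry]] = {}
    for cat, raw_entries in doc.items():
        if not isinstance(raw_entries, list):
            raise LexiconError(f"{origin}: category {cat!r} must hold a list of entries")
        entries = []
        for i, raw in enumerate(raw_entries):
            if not isinstance(raw, dict) or "label" not in raw:
                raise LexiconError(f"{origin}: category {cat!r} entry {i} lacks a label")
            entries.append(
                LexiconEntry(
                    label=str(raw["label"]),
                    en=tuple(str(t) for t in raw.get("en", []) or []),
                    th=tuple(str(t) for t in raw.get("th", []) or []),
                )
            )
        categories[cat] = entries
    return Lexicon(categories)


def _normalize_term(term: str) -> tuple[str, ...]:
    """Normalize an English lexicon term with the comment pipeline."""
    tokens = nlp_core.tokenize(term, nlp_core.ENGLISH)
    tokens = nlp_core.remove_stopwords(tokens, nlp_core.ENGLISH)
    return tuple(nlp_core.normalize_tokens(tokens, nlp_core.ENGLISH))


def _contains_subsequence(haystack: Sequence[str], needle: Sequence[str]) -> int | None:
    """First start index of needle as a contiguous run in haystack, else None."""
    n, m = len(haystack), len(needle)
    if m == 0 or m > n:
        return None
    for i in range(n - m + 1):
        if tuple(haystack[i : i + m]) == tuple(needle):
            return i
    return None


def match_category(
    tokenized: TokenizedComment, lexicon: Lexicon, category: str
) -> list[str]:
    """Canonical labels of entries with at least one term in the comment.

    Labels are deduplicated and ordered by first occurrence position in the
    comment (English: token index; Thai: character index of the substring).
    """
    if category not in CATEGORIES:
        raise LexiconError(f"unknown category {category!r}")
    hits: list[tuple[int, str]] = []
    for entry in lexicon.entries(category):
        best: int | None = None
        for term in entry.en:
            pos = _contains_subsequence(tokenized.normalized_tokens, _normalize_term(term))
            if pos is not None and (best is None or pos < best):
                best = pos
        for term in entry.th:
            pos = tokenized.text.find(term)
            if pos >= 0 and (best is None or pos < best):
                # character offsets and token offsets are not comparable, but
                # each entry reports a single first-occurrence position within
                # its own language; mixed-language entries keep the minimum.
                best = pos if best is None else min(best, pos)
        if best is not None:
            hits.append((best, entry.label))
    hits.sort(key=lambda t: (t[0], t[1]))
    out: list[str] = []
    for _, label in hits:
        if label not in out:
            out.append(label)
    return out


def extract_variables(tokenized: TokenizedComment, lexicon: Lexicon) -> ExtractedKnowledge:
    """Fill the per-comment dashboard variables by lexicon matching.

    Gender comes from explicit cue words only; cues for both genders in one
    comment yield ``unknown`` (no guessing). Source defaults to ``general``
    when no cue is present; when several source cues occur, the earliest in
    the comment wins.
    """
    genders = match_category(tokenized, lexicon, "gender_cue")
    if len(genders) == 1:
        gender = genders[0]
    else:
        gender = "unknown"
    sources = match_category(tokenized, lexicon, "source_cue")
    source = sources[0] if sources else "general"
    return ExtractedKnowledge(
        seq=tokenized.seq,
        gender=gender,
        source=source,
        diseases=match_category(tokenized, lexicon, "disease"),
        symptoms=match_category(tokenized, lexicon, "symptom"),
        treatments=match_category(tokenized, lexicon, "treatment"),
        behaviors=match_category(tokenized, lexicon, "behavior_cause"),
    )


def word_frequency(
    corpus: Iterable[TokenizedComment], top_k: int | None = 20
) -> list[tuple[str, int]]:
    """Most frequent normalized, stopword-removed tokens across the corpus.

    Descending by count, ties broken lexicographically; at most ``top_k``
    rows (None = unbounded).
    """
    if top_k is not None and top_k < 1:
        raise ValueError("top_k must be >= 1")
    counts: dict[str, int] = {}
    for com in corpus:
        for tok in com.normalized_tokens:
            counts[tok] = counts.get(tok, 0) + 1
    ranked = sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))
    return ranked if top_k is None else ranked[:top_k]


def adjust_selection(
    knowledge: list[ExtractedKnowledge],
    include: set[str] | None = None,
    exclude: set[str] | None = None,
) -> list[ExtractedKnowledge]:
    """User-driven data adjustment over disease/symptom mentions.

    A comment survives iff (the include set is empty OR it mentions at least
    one included disease/symptom label) AND it mentions no excluded label.
    Surviving records pass through unchanged.
    """
    include = set(include or ())
    exclude = set(exclude or ())
    overlap = include & exclude
    if overlap:
        raise ValueError(f"labels both included and excluded: {sorted(overlap)}")
    out = []
    for k in knowledge:
        mentioned = set(k.diseases) | set(k.symptoms)
        if include and not (mentioned & include):
            continue
        if mentioned & exclude:
            continue
        out.append(k)
    return out
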