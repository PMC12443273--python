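"""Bilingual (Thai/English) text normalization services.

Everything downstream of ingestion — the short-comment filter, lexicon
matching, classification features and word-frequency charts — runs on the
token streams produced here. All operations are pure functions of
``(text, language, resource files)``: no global state, no randomness.

Thai has no inter-word spacing, so tokenization uses longest-match
(maximal-munch) segmentation against a shipped domain dictionary. English
normalization applies a compact rule-based lemmatizer (exception table plus
suffix rules); Thai normalization is orthographic only, since Thai has no
inflectional morphology to lemmatize.
"""

from __future__ import annotations

import re
import unicodedata
from dataclasses import dataclass
from functools import lru_cache
from importlib import resources as _ilr
from pathlib import Path

__all__ = [
    "Language",
    "TokenizedComment",
    "detect_language",
    "tokenize",
    "remove_stopwords",
    "normalize_tokens",
    "tokenize_comment",
]

# Language tags used across the package.
THAI = "thai"
ENGLISH = "english"
UNKNOWN = "unknown"
Language = str  # one of THAI / ENGLISH / UNKNOWN

_THAI_BLOCK = (0x0E00, 0x0E7F)

_URL_RE = re.compile(r"https?://\S+|www\.\S+", re.IGNORECASE)
# English word tokens: letters/digits with optional internal apostrophe.
_EN_TOKEN_RE = re.compile(r"[a-z0-9]+(?:'[a-z]+)?")
# Thai combining marks (vowels above/below, tone marks) that may be typed twice.
_TH_COMBINING_RE = re.compile(r"([ัำ-ฺ็-๎])\1+")
_ZERO_WIDTH_RE = re.compile(r"[​‌‍﻿]")


def _read_resource_lines(name: str) -> list[str]:
    text = _ilr.files("ncd_listener.resources").joinpath(name).read_text("utf-8")
    out = []
    for line in text.splitlines():
        line = line.strip()
        if line and not line.startswith("#"):
            out.append(line)
    return out


@lru_cache(maxsize=None)
def _thai_dictionary() -> frozenset[str]:
    return frozenset(_read_resource_lines("thai_words.txt"))


@lru_cache(maxsize=None)
def _thai_max_word_len() -> int:
    return max((len(w) for w in _thai_dictionary()), default=1)


@lru_cache(maxsize=8)
def _stopwords(language: Language, override_path: str | None = None) -> frozenset[str]:
    if override_path is not None:
        lines = [
            ln.strip()
            for ln in Path(override_path).read_text("utf-8").splitlines()
            if ln.strip() and not ln.strip().startswith("#")
        ]
        return frozenset(lines)
    if language == THAI:
        return frozenset(_read_resource_lines("stopwords_th.txt"))
    if language == ENGLISH:
        return frozenset(_read_resource_lines("stopwords_en.txt"))
    return frozenset()


@dataclass
class TokenizedComment:
    """Token-level view of one comment, linked to its source by ``seq``.

    ``tokens`` is the raw tokenization; ``normalized_tokens`` is the
    stopword-removed, lemmatized/orthographically-normalized stream that
    lexicon matching and word-frequency counting consume. ``text`` keeps the
    original body because Thai lexicon terms are matched as substrings of the
    unsegmented text.
    """

    seq: int
    language: Language
    tokens: list[str]
    normalized_tokens: list[str]
    text: str = ""


def _is_thai_char(ch: str) -> bool:
    return _THAI_BLOCK[0] <= ord(ch) <= _THAI_BLOCK[1]


def detect_language(text: str, thai_threshold: float = 0.5) -> Language:
    """Classify a string as thai / english / unknown by script majority.

    Counts Thai-block vs Latin characters among alphabetic characters; a
    Thai fraction above ``thai_threshold`` wins, otherwise Latin majority
    means English. Strings without alphabetic content are unknown.
    Mixed-script (code-switched) comments get the majority script.
    """
    thai = latin = other = 0
    for ch in text:
        if _is_thai_char(ch) and unicodedata.category(ch).startswith(("L", "M")):
            thai += 1
        elif ch.isalpha():
            if "LATIN" in unicodedata.name(ch, ""):
                latin += 1
            else:
                other += 1
    total = thai + latin + other
    if total == 0:
        return UNKNOWN
    if thai / total > thai_threshold:
        return THAI
    if latin / total > 0.5:
        return ENGLISH
    return UNKNOWN


def _strip_noise(text: str) -> str:
    """Remove URLs, zero-width characters and emoji/symbol codepoints."""
    text = _URL_RE.sub(" ", text)
    text = _ZERO_WIDTH_RE.sub("", text)
    return "".join(
        " " if unicodedata.category(ch) in ("So", "Sk", "Cs", "Co") else ch
        for ch in text
    )


def _segment_thai(text: str) -> list[str]:
    """Longest-match dictionary segmentation; unknown runs become one token."""
    words = _thai_dictionary()
    max_len = _thai_max_word_len()
    tokens: list[str] = []
    unknown_run: list[str] = []
    i, n = 0, len(text)
    while i < n:
        ch = text[i]
        if not _is_thai_char(ch):
            if unknown_run:
                tokens.append("".join(unknown_run))
                unknown_run = []
            i += 1
            continue
        matched = None
        for length in range(min(max_len, n - i), 0, -1):
            cand = text[i : i + length]
            if cand in words:
                matched = cand
                break
        if matched is not None:
            if unknown_run:
                tokens.append("".join(unknown_run))
                unknown_run = []
            tokens.append(matched)
            i += len(matched)
        else:
            unknown_run.append(ch)
            i += 1
    if unknown_run:
        tokens.append("".join(unknown_run))
    return tokens


def tokenize(text: str, language: Language) -> list[str]:
    """Deterministic tokenization.

    Thai: dictionary-based longest-match segmentation over Thai-script runs,
    with embedded Latin words tokenized by the English rule. English and
    unknown: lowercased, punctuation-stripped whitespace tokens.
    """
    text = _strip_noise(text)
    if language == THAI:
        tokens: list[str] = []
        # Split out Latin/digit words first so code-switched text survives.
        for piece in re.split(r"([a-zA-Z0-9']+)", text):
            if not piece:
                continue
            if re.fullmatch(r"[a-zA-Z0-9']+", piece):
                tokens.extend(_EN_TOKEN_RE.findall(piece.lower()))
            else:
                tokens.extend(_segment_thai(piece))
        return tokens
    return _EN_TOKEN_RE.findall(text.lower())


def remove_stopwords(
    tokens: list[str], language: Language, stopword_path: str | None = None
) -> list[str]:
    """Order-preserving removal of the language's stopword set.

    Unknown-language streams pass through unchanged (there is no list to
    apply). Custom one-token-per-line files may be supplied via
    ``stopword_path``.
    """
    stops = _stopwords(language, stopword_path)
    if not stops:
        return list(tokens)
    return [t for t in tokens if t not in stops]


# Irregular lemma table for words likely in health-comment text; the suffix
# rules below handle the regular cases.
_LEMMA_EXCEPTIONS = {
    "was": "be", "were": "be", "is": "be", "are": "be", "been": "be",
    "has": "have", "had": "have", "did": "do", "does": "do",
    "diagnosed": "diagnose", "died": "die", "dying": "die",
    "worse": "bad", "worst": "bad", "better": "good", "best": "good",
    "feet": "foot", "teeth": "tooth", "men": "man", "women": "woman",
    "children": "child", "people": "person", "lives": "life",
    "taken": "take", "took": "take", "given": "give", "gave": "give",
    "felt": "feel", "found": "find", "lost": "lose", "said": "say",
    "told": "tell", "went": "go", "gone": "go", "got": "get",
    "knew": "know", "known": "know", "saw": "see", "seen": "see",
}

_VOWELS = set("aeiou")


def _lemmatize_en(token: str) -> str:
    if token in _LEMMA_EXCEPTIONS:
        return _LEMMA_EXCEPTIONS[token]
    n = len(token)
    if n > 4 and token.endswith("ies"):
        return token[:-3] + "y"
    if n > 4 and token.endswith("sses"):
        return token[:-2]
    if n > 3 and token.endswith("es") and not token.endswith(("ses", "oes")):
        stem = token[:-2]
        # "diseases" -> "disease", "matches" -> "match"
        if stem.endswith(("ch", "sh", "x", "z", "s")):
            return stem
        return token[:-1]
    if n > 3 and token.endswith("s") and not token.endswith(("ss", "us", "is")):
        return token[:-1]
    if n > 5 and token.endswith("ing"):
        stem = token[:-3]
        if len(stem) > 2 and stem[-1] == stem[-2] and stem[-1] not in _VOWELS:
            stem = stem[:-1]  # running -> run
        if not any(c in _VOWELS for c in stem):
            return token
        return stem
    if n > 4 and token.endswith("ed"):
        stem = token[:-2]
        if len(stem) > 2 and stem[-1] == stem[-2] and stem[-1] not in _VOWELS:
            return stem[:-1]  # stopped -> stop
        if stem.endswith(("iz", "ag", "os")):
            return stem + "e"  # realized -> realize, encouraged -> encourage
        if not any(c in _VOWELS for c in stem):
            return token
        return stem
    return token


def _normalize_th(token: str) -> str:
    """Orthographic cleanup: NFC form, de-duplicated combining marks."""
    token = unicodedata.normalize("NFC", token)
    token = _ZERO_WIDTH_RE.sub("", token)
    return _TH_COMBINING_RE.sub(r"\1", token)


def normalize_tokens(tokens: list[str], language: Language) -> list[str]:
    """Lemmatize English tokens; orthographically normalize Thai tokens.

    Idempotent: applying twice equals applying once (enforced by clamping
    each output through the normalizer until it is a fixed point).
    """
    if language == THAI:
        return [_normalize_th(t) for t in tokens]
    out = []
    for t in tokens:
        prev, cur = t, _lemmatize_en(t)
        # iterate to a fixed point so the operation is idempotent
        while cur != prev:
            prev, cur = cur, _lemmatize_en(cur)
        out.append(cur)
    return out


def tokenize_comment(
    seq: int,
    text: str,
    language: Language | None = None,
    stopword_path: str | None = None,
) -> TokenizedComment:
    """Full per-comment pipeline: detect, tokenize, de-stopword, normalize."""
    lang = language if language is not None else detect_language(text)
    tokens = tokenize(text, lang)
    normalized = normalize_tokens(remove_stopwords(tokens, lang, stopword_path), lang)
    return TokenizedComment(
        seq=seq, language=lang, tokens=tokens, normalized_tokens=normalized, text=text
    )
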