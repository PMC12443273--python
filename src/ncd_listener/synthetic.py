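"""Seeded generators for every input the pipeline consumes.

Emulates scraped bilingual comment corpora (with planted class labels,
lexicon mentions, duplicates and short comments), saved comment-section HTML
snapshots, and ordinal survey responses — each with recorded ground truth so
every pipeline stage can be verified offline without hand labeling.

Comments are assembled from class-specific template banks: inquiring
templates carry interrogative cues, sharing templates carry first-person
cues plus lexicon terms, non-informative templates carry neither. This is a
deliberately stylized emulation — real social-media text has slang,
misspellings, code-switching and topic drift that these templates do not —
so results on synthetic corpora bound mechanics, not real-world accuracy.
"""

from __future__ import annotations

import html as _html
import re
from dataclasses import dataclass, field

import numpy as np

from . import nlp_core
from .ingestion import CommentRecord, SelectorConfig, SHORT_COMMENT_MAX_TOKENS
from .knowledge_extraction import Lexicon, default_lexicon

__all__ = [
    "CorpusSpec",
    "GroundTruthEntry",
    "GroundTruth",
    "generate_corpus",
    "generate_fixture_html",
    "generate_likert_responses",
]


@dataclass(frozen=True)
class CorpusSpec:
    """Study conditions for one synthetic comment corpus."""

    n_comments: int = 200
    thai_fraction: float = 0.5
    # sharing_experience, inquiring, non_informative
    class_mixture: tuple[float, float, float] = (0.45, 0.15, 0.40)
    duplicate_rate: float = 0.10
    short_rate: float = 0.10
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_comments < 1:
            raise ValueError("n_comments must be positive")
        if not 0 <= self.thai_fraction <= 1:
            raise ValueError("thai_fraction must be in [0, 1]")
        if abs(sum(self.class_mixture) - 1.0) > 1e-9 or any(
            p < 0 for p in self.class_mixture
        ):
            raise ValueError("class_mixture must be a 3-simplex")
        if sum(self.class_mixture) == 0:
            raise ValueError("degenerate class mixture")
        if not 0 <= self.duplicate_rate < 1 or not 0 <= self.short_rate < 1:
            raise ValueError("rates must be in [0, 1)")
        if self.duplicate_rate + self.short_rate >= 0.9:
            raise ValueError("duplicate_rate + short_rate leaves too few base comments")


@dataclass
class GroundTruthEntry:
    """What was planted in one comment."""

    seq: int
    label: str  # classifier class
    language: str
    diseases: list[str] = field(default_factory=list)
    symptoms: list[str] = field(default_factory=list)
    treatments: list[str] = field(default_factory=list)
    behaviors: list[str] = field(default_factory=list)
    gender: str = "unknown"
    source: str = "general"
    is_duplicate: bool = False
    duplicate_of: int | None = None
    is_short: bool = False


@dataclass
class GroundTruth:
    entries: list[GroundTruthEntry]

    @property
    def n_duplicates(self) -> int:
        return sum(e.is_duplicate for e in self.entries)

    @property
    def n_short(self) -> int:
        return sum(e.is_short for e in self.entries)

    def by_seq(self, seq: int) -> GroundTruthEntry:
        return next(e for e in self.entries if e.seq == seq)


# --------------------------------------------------------------------------
# Template banks. {d}=disease term, {s}=symptom term, {t}=treatment term,
# {b}=behavior term. Gender/source cues are embedded in the template text and
# declared alongside it.

# (template, gender, source)
_SHARING_EN = (
    ("I was diagnosed with {d} two years ago and the {s} never really stopped", "unknown", "self"),
    ("My mother has been fighting {d} and her {s} got worse after starting {t}", "female", "family_member"),
    ("My father lived with {d} for a decade because of his {b} habit", "male", "family_member"),
    ("I am getting {t} every month for my {d} and it leaves me with {s}", "unknown", "self"),
    ("My friend went through {t} for {d} and he said the {s} was the hardest part", "male", "acquaintance"),
    ("I changed my {b} habits completely after the doctor found {d}", "unknown", "self"),
    ("My sister manages her {d} with {t} and she feels much stronger now", "female", "family_member"),
)
_INQUIRING_EN = (
    ("What are the early warning signs of {d} before the {s} starts?", "unknown", "general"),
    ("Does {t} actually help with {d} or are there better options now?", "unknown", "general"),
    ("How long does {s} usually last for someone with {d}?", "unknown", "general"),
    ("Can {b} really cause {d} even in young healthy adults?", "unknown", "general"),
    ("Where can a patient with {d} find affordable {t} around here?", "unknown", "general"),
)
_NONINFORMATIVE_EN = (
    "thanks for sharing this helpful post with all of us today",
    "sending good vibes and strength to everyone reading this thread",
    "this page always posts such interesting content every single week",
    "great community here with lots of supportive people around lately",
    "following this topic closely since it comes up everywhere these days",
)
_SHARING_TH = (
    ("ผมเป็น{d}มาสองปีแล้ว อาการ{s}ยังไม่หายเลย ต้องดูแลตัวเองทุกวัน", "male", "self"),
    ("แม่ของฉันเป็น{d} หลังจากเริ่ม{t}ก็มีอาการ{s}มากขึ้น ทุกคนช่วยกันดูแล", "female", "family_member"),
    ("พ่อผมเป็น{d}เพราะ{b}มานาน ตอนนี้เริ่ม{t}แล้ว กำลังใจสำคัญมาก", "male", "family_member"),
    ("ฉันเป็น{d} ต้องไป{t}ทุกเดือน รู้สึก{s}หลังการรักษาทุกครั้ง", "female", "self"),
    ("เพื่อนผมเป็น{d} เขาเล่าว่า{s}หนักมาก ตอนนี้รักษาด้วย{t}อยู่", "male", "acquaintance"),
)
_INQUIRING_TH = (
    ("อาการ{s}แบบนี้ใช่{d}หรือเปล่า ใครรู้ช่วยบอกหน่อย", "unknown", "general"),
    ("{t}ช่วยรักษา{d}ได้จริงไหม มีใครเคยลองบ้าง", "unknown", "general"),
    ("ทำไม{b}ถึงทำให้เป็น{d}ได้ อยากรู้มาก", "unknown", "general"),
    ("เป็น{d}ควรไปตรวจที่ไหนดี มีหมอแนะนำไหม", "unknown", "general"),
)
_NONINFORMATIVE_TH = (
    "ขอบคุณสำหรับข้อมูลดีๆ ที่แชร์ให้ทุกคนได้อ่านกัน",
    "เพจนี้ลงข้อมูลดีตลอด ติดตามมานานแล้ว ชอบมาก",
    "ขอให้ทุกคนมีสุขภาพแข็งแรงกันถ้วนหน้า โชคดีทุกท่าน",
    "โพสต์นี้มีประโยชน์มาก ส่งต่อให้เพื่อนในบ้านได้อ่านแล้ว",
)
_SHORT_EN = (
    "stay strong friend",
    "so sad",
    "sending love",
    "good luck",
    "take care",
    "wow amazing",
    "very useful post",
    "thanks doc",
    "me too",
    "great news",
)
_SHORT_TH = (
    "สู้ๆนะ",
    "เป็นกำลังใจให้",
    "ขอบคุณค่ะ",
    "ดีมากครับ",
    "เสียใจด้วยนะ",
)

_EN_ALIASES = (
    "somchai", "malee", "john_doe", "healthfan42", "mary.p", "arthit",
    "kwan123", "peterpan", "nok_b", "susan_k",
)


def _term(rng: np.random.Generator, lexicon: Lexicon, category: str, language: str) -> tuple[str, str]:
    """Pick a (surface term, canonical label) for a category and language."""
    entries = [
        e
        for e in lexicon.entries(category)
        if (e.th if language == nlp_core.THAI else e.en)
    ]
    entry = entries[rng.integers(0, len(entries))]
    terms = entry.th if language == nlp_core.THAI else entry.en
    return str(terms[rng.integers(0, len(terms))]), entry.label


def _ensure_long(text: str, language: str) -> str:
    """Pad a base comment until it clears the short-comment filter."""
    pad_en, pad_th = " truly indeed", "ตอนนี้เริ่มดีขึ้น"
    guard = 0
    while len(nlp_core.tokenize(text, language)) <= SHORT_COMMENT_MAX_TOKENS and guard < 10:
        text = text + (pad_th if language == nlp_core.THAI else pad_en)
        guard += 1
    return text


def generate_corpus(
    spec: CorpusSpec, lexicon: Lexicon | None = None
) -> tuple[list[CommentRecord], GroundTruth]:
    """Generate a comment corpus with recorded ground truth.

    The corpus holds ``n_comments`` records in total: a base of distinct
    comments of more than 5 tokens, ``round(duplicate_rate * n)`` exact
    duplicates of earlier base comments, and ``round(short_rate * n)``
    distinct comments of at most 5 tokens. Running the preprocessing
    pipeline on the output therefore yields exactly
    ``n - n_duplicates - n_short`` records. Reproducible from the seed.
    """
    lexicon = lexicon or default_lexicon()
    rng = np.random.default_rng(spec.seed)
    n = spec.n_comments
    n_dup = int(round(spec.duplicate_rate * n))
    n_short = int(round(spec.short_rate * n))
    n_base = n - n_dup - n_short
    if n_base < 1:
        raise ValueError("spec leaves no base comments")

    base: list[tuple[str, GroundTruthEntry]] = []
    seen_texts: set[str] = set()
    class_names = ("sharing_experience", "inquiring", "non_informative")
    for i in range(n_base):
        label = class_names[int(rng.choice(3, p=list(spec.class_mixture)))]
        language = nlp_core.THAI if rng.random() < spec.thai_fraction else nlp_core.ENGLISH
        text, entry = _render_comment(rng, lexicon, label, language)
        text = _ensure_long(text, language)
        filler = " จริงๆ" if language == nlp_core.THAI else " honestly"
        while text in seen_texts:
            text = text + filler
        seen_texts.add(text)
        base.append((text, entry))

    # interleave base comments, duplicates (kept after their source) and shorts
    items: list[tuple[str, GroundTruthEntry]] = list(base)
    dup_sources = rng.integers(0, len(base), size=n_dup)
    for src in dup_sources:
        text, src_entry = base[src]
        dup_entry = GroundTruthEntry(
            seq=0,
            label=src_entry.label,
            language=src_entry.language,
            diseases=list(src_entry.diseases),
            symptoms=list(src_entry.symptoms),
            treatments=list(src_entry.treatments),
            behaviors=list(src_entry.behaviors),
            gender=src_entry.gender,
            source=src_entry.source,
            is_duplicate=True,
            duplicate_of=src,  # resolved to a seq below
        )
        items.append((text, dup_entry))
    shorts_pool = list(_SHORT_EN) + list(_SHORT_TH)
    for j in range(n_short):
        text = shorts_pool[j % len(shorts_pool)]
        if j >= len(shorts_pool):
            # numeric marker keeps texts distinct without crossing 5 tokens
            text = f"{text} {j // len(shorts_pool)}"
        lang = nlp_core.detect_language(text)
        items.append(
            (text, GroundTruthEntry(seq=0, label="non_informative", language=lang, is_short=True))
        )

    # shuffle but keep each duplicate after its source occurrence
    order = list(rng.permutation(len(items)))
    pos = {item_idx: p for p, item_idx in enumerate(order)}
    for item_idx in range(len(base), len(base) + n_dup):
        src = int(dup_sources[item_idx - len(base)])
        if pos[item_idx] < pos[src]:  # swap so the original comes first
            order[pos[item_idx]], order[pos[src]] = order[pos[src]], order[pos[item_idx]]
            pos[item_idx], pos[src] = pos[src], pos[item_idx]

    records: list[CommentRecord] = []
    entries: list[GroundTruthEntry] = []
    base_seq: dict[int, int] = {}
    for seq, item_idx in enumerate(order, start=1):
        text, entry = items[item_idx]
        entry.seq = seq
        if item_idx < len(base):
            base_seq[item_idx] = seq
        records.append(
            CommentRecord(
                seq=seq,
                alias=str(_EN_ALIASES[rng.integers(0, len(_EN_ALIASES))]) + str(seq),
                text=text,
                likes=int(rng.integers(0, 500)),
                replies=int(rng.integers(0, 50)),
                language=nlp_core.detect_language(text),
            )
        )
        entries.append(entry)
    for entry in entries:
        if entry.is_duplicate:
            entry.duplicate_of = base_seq[entry.duplicate_of]
    return records, GroundTruth(entries)


def _render_comment(
    rng: np.random.Generator, lexicon: Lexicon, label: str, language: str
) -> tuple[str, GroundTruthEntry]:
    th = language == nlp_core.THAI
    if label == "non_informative":
        bank = _NONINFORMATIVE_TH if th else _NONINFORMATIVE_EN
        text = str(bank[rng.integers(0, len(bank))])
        return text, GroundTruthEntry(seq=0, label=label, language=language)
    bank = (
        (_SHARING_TH if th else _SHARING_EN)
        if label == "sharing_experience"
        else (_INQUIRING_TH if th else _INQUIRING_EN)
    )
    template, gender, source = bank[rng.integers(0, len(bank))]
    entry = GroundTruthEntry(seq=0, label=label, language=language, gender=gender, source=source)
    fills: dict[str, str] = {}
    for slot, category, sink in (
        ("{d}", "disease", entry.diseases),
        ("{s}", "symptom", entry.symptoms),
        ("{t}", "treatment", entry.treatments),
        ("{b}", "behavior_cause", entry.behaviors),
    ):
        if slot in template:
            term, canonical = _term(rng, lexicon, category, language)
            fills[slot[1]] = term
            sink.append(canonical)
    text = template.format(**fills)
    return text, entry


# --------------------------------------------------------------------------
# Fixture HTML

_SIMPLE_SELECTOR_RE = re.compile(r"^([a-zA-Z][a-zA-Z0-9]*)?(?:\.([\w-]+))?$")


def _selector_to_markup(selector: str) -> tuple[str, str]:
    """Split a 'tag.class' / '.class' / 'tag' selector into (tag, class attr)."""
    m = _SIMPLE_SELECTOR_RE.match(selector.strip())
    if not m or (not m.group(1) and not m.group(2)):
        raise ValueError(
            f"fixture generator only supports tag/.class/tag.class selectors, got {selector!r}"
        )
    tag = m.group(1) or "div"
    cls = f' class="{m.group(2)}"' if m.group(2) else ""
    return tag, cls


def generate_fixture_html(records: list[CommentRecord], config: SelectorConfig) -> str:
    """Render records as an HTML page parseable back with the same config.

    Parsing the output with ``parse_comments_html(html, config)`` reproduces
    alias/text/likes/replies field-for-field. Only the simple selector subset
    (tag, .class, tag.class) is supported.
    """
    ctag, ccls = _selector_to_markup(config.comment_container_selector)
    parts = [
        "<!DOCTYPE html><html><head><meta charset='utf-8'>"
        f"<title>{config.platform} snapshot</title></head><body><main>"
    ]
    for rec in records:
        parts.append(f"<{ctag}{ccls}>")
        for fld, value in (
            ("name", rec.alias),
            ("comment", rec.text),
            ("likes", str(rec.likes)),
            ("replies", str(rec.replies)),
        ):
            ftag, fcls = _selector_to_markup(config.field_selectors[fld])
            parts.append(f"<{ftag}{fcls}>{_html.escape(value)}</{ftag}>")
        parts.append(f"</{ctag}>")
    parts.append("</main></body></html>")
    return "".join(parts)


# --------------------------------------------------------------------------
# Ordinal survey responses


def generate_likert_responses(
    n_per_group: int, shift: float = 0.0, seed: int = 0
) -> tuple[np.ndarray, np.ndarray]:
    """Two seeded 1-5 ordinal samples, group 1 shifted upward by ``shift``.

    Responses are latent-normal draws (sd 1) cut at fixed thresholds into
    the five ordinal levels; group 1's latent mean is ``3 + shift`` and
    group 2's is 3, so at shift 0 the groups are exchangeable and a growing
    shift makes group 1 stochastically dominate group 2.
    """
    if shift < 0:
        raise ValueError("shift must be non-negative")
    rng = np.random.default_rng(seed)
    cuts = np.array([1.5, 2.5, 3.5, 4.5])

    def draw(mu: float) -> np.ndarray:
        latent = rng.normal(mu, 1.0, size=n_per_group)
        return (np.digitize(latent, cuts) + 1).astype(int)

    return draw(3.0 + shift), draw(3.0)
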