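"""Comment ingestion and preprocessing.

Turns saved comment-section HTML snapshots (or previously exported CSV
tables) into a clean, anonymized four-column comment table — the entry point
of the listening pipeline. Cleaning applies three rules in a fixed order:

1. drop duplicate comments (exact text match after whitespace collapsing),
2. drop extremely short comments (token count <= 5 under the language's
   tokenizer), and
3. anonymize authors by replacing every name with ``Name(n)`` where ``n`` is
   the comment's original sequence number.

Sequence numbers are assigned once at parse/read time and never renumbered,
so ``Name(n)`` remains traceable to the n-th scraped comment even after
filtering.
"""

from __future__ import annotations

import csv
import logging
import re
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Callable, Iterable, Mapping

import yaml
from bs4 import BeautifulSoup

from . import nlp_core

__all__ = [
    "SelectorConfig",
    "CommentRecord",
    "IngestionError",
    "load_selector_config",
    "parse_comments_html",
    "parse_count",
    "read_comment_table",
    "write_comment_table",
    "deduplicate",
    "filter_short",
    "anonymize",
    "preprocess_pipeline",
]

logger = logging.getLogger(__name__)

CSV_COLUMNS = ("name", "comments", "likes", "replies")

SHORT_COMMENT_MAX_TOKENS = 5  # "less than or equal to 5 words" removal rule


class IngestionError(ValueError):
    """Raised for malformed HTML/CSV inputs; message names the failing part."""


@dataclass(frozen=True)
class SelectorConfig:
    """CSS selectors locating comment fields on one platform's pages."""

    platform: str
    comment_container_selector: str
    field_selectors: Mapping[str, str]  # keys: name, comment, likes, replies

    REQUIRED_FIELDS = ("name", "comment", "likes", "replies")

    def __post_init__(self) -> None:
        for fld in self.REQUIRED_FIELDS:
            sel = self.field_selectors.get(fld)
            if not sel or not str(sel).strip():
                raise IngestionError(
                    f"selector config for {self.platform!r} missing field selector {fld!r}"
                )
        if not self.comment_container_selector.strip():
            raise IngestionError("comment_container_selector must be non-empty")


@dataclass
class CommentRecord:
    """One scraped comment row (the four-column table plus bookkeeping)."""

    seq: int
    alias: str
    text: str
    likes: int = 0
    replies: int = 0
    language: str = nlp_core.UNKNOWN

    def __post_init__(self) -> None:
        if self.seq < 1:
            raise ValueError("seq must be a positive 1-based integer")
        if self.likes < 0 or self.replies < 0:
            raise ValueError("likes/replies must be non-negative")


def load_selector_config(path: str | Path, platform: str) -> SelectorConfig:
    """Load one platform block from a YAML selector configuration file."""
    with open(path, "r", encoding="utf-8") as fh:
        doc = yaml.safe_load(fh)
    if not isinstance(doc, dict) or platform not in doc:
        raise IngestionError(f"no selector block for platform {platform!r} in {path}")
    block = doc[platform]
    return SelectorConfig(
        platform=platform,
        comment_container_selector=block["comment_container_selector"],
        field_selectors=block["field_selectors"],
    )


_COUNT_SUFFIX = {"k": 1_000, "m": 1_000_000}


def parse_count(text: str | None) -> int:
    """Parse a rendered like/reply count ("3", "1.2K", "2M") to an integer.

    Missing, empty or unparsable strings yield 0 — platforms omit the element
    entirely when the count is zero.
    """
    if text is None:
        return 0
    text = text.strip().replace(",", "")
    if not text:
        return 0
    m = re.fullmatch(r"(\d+(?:\.\d+)?)\s*([kKmM]?)", text)
    if not m:
        # strings like "12 likes": take the leading number if any
        m2 = re.match(r"(\d+(?:\.\d+)?)\s*([kKmM]?)", text)
        if not m2:
            return 0
        m = m2
    value = float(m.group(1)) * _COUNT_SUFFIX.get(m.group(2).lower(), 1)
    return int(round(value))


def parse_comments_html(html: str, config: SelectorConfig) -> list[CommentRecord]:
    """Extract one CommentRecord per comment container in document order.

    Fields are located with the per-platform CSS selectors; a missing likes
    or replies element defaults to 0. Zero matching containers is not an
    error (a warning is logged) — pages legitimately carry no comments.
    """
    try:
        soup = BeautifulSoup(html, "lxml")
    except Exception as exc:  # pragma: no cover - lxml is extremely lenient
        raise IngestionError(f"unparseable document: {exc}") from exc

    try:
        containers = soup.select(config.comment_container_selector)
    except Exception as exc:
        raise IngestionError(
            f"invalid container selector {config.comment_container_selector!r}: {exc}"
        ) from exc
    if not containers:
        logger.warning(
            "no comment containers matched %r on platform %s",
            config.comment_container_selector,
            config.platform,
        )
        return []

    records: list[CommentRecord] = []
    for i, node in enumerate(containers, start=1):
        def pick(fld: str) -> str | None:
            sel = config.field_selectors[fld]
            try:
                hit = node.select_one(sel)
            except Exception as exc:
                raise IngestionError(f"invalid selector for {fld!r}: {sel!r}: {exc}")
            return hit.get_text(strip=True) if hit is not None else None

        text = pick("comment") or ""
        records.append(
            CommentRecord(
                seq=i,
                alias=pick("name") or "",
                text=text,
                likes=parse_count(pick("likes")),
                replies=parse_count(pick("replies")),
                language=nlp_core.detect_language(text),
            )
        )
    return records


def read_comment_table(path: str | Path) -> list[CommentRecord]:
    """Read a name/comments/likes/replies CSV; columns matched by header name."""
    with open(path, "r", encoding="utf-8", newline="") as fh:
        reader = csv.DictReader(fh)
        header = reader.fieldnames or []
        for col in CSV_COLUMNS:
            if col not in header:
                raise IngestionError(f"CSV {path} is missing required column {col!r}")
        records = []
        for rownum, row in enumerate(reader, start=2):
            try:
                likes = int(row["likes"]) if row["likes"] not in (None, "") else 0
                replies = int(row["replies"]) if row["replies"] not in (None, "") else 0
            except ValueError as exc:
                raise IngestionError(
                    f"CSV {path} row {rownum}: malformed integer in likes/replies"
                ) from exc
            text = row["comments"] or ""
            records.append(
                CommentRecord(
                    seq=len(records) + 1,
                    alias=row["name"] or "",
                    text=text,
                    likes=likes,
                    replies=replies,
                    language=nlp_core.detect_language(text),
                )
            )
    return records


def write_comment_table(records: Iterable[CommentRecord], path: str | Path) -> None:
    """Write records as the canonical four-column CSV (UTF-8, quoted)."""
    with open(path, "w", encoding="utf-8", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(CSV_COLUMNS)
        for rec in records:
            writer.writerow([rec.alias, rec.text, rec.likes, rec.replies])


_WS_RE = re.compile(r"\s+")


def _normalized_text(text: str) -> str:
    return _WS_RE.sub(" ", text.strip())


def deduplicate(records: list[CommentRecord]) -> list[CommentRecord]:
    """Keep the first occurrence of each comment text.

    Duplicate = identical text after trimming and collapsing whitespace runs
    (case-sensitive). Order is preserved; the operation is idempotent.
    """
    seen: set[str] = set()
    out = []
    for rec in records:
        key = _normalized_text(rec.text)
        if key in seen:
            continue
        seen.add(key)
        out.append(rec)
    return out


def default_tokenizer(rec: CommentRecord) -> list[str]:
    """Language-aware token counter used by the short-comment filter.

    Thai text is counted in dictionary-segmentation tokens; English and
    unknown-language text in whitespace/punctuation tokens.
    """
    lang = rec.language
    if lang == nlp_core.UNKNOWN:
        detected = nlp_core.detect_language(rec.text)
        if detected == nlp_core.THAI:
            lang = nlp_core.THAI
        else:
            lang = nlp_core.ENGLISH  # whitespace-token fallback, with warning
            logger.warning("record %d: unknown language, counting whitespace tokens", rec.seq)
    return nlp_core.tokenize(rec.text, lang)


def filter_short(
    records: list[CommentRecord],
    tokenizer: Callable[[CommentRecord], list[str]] = default_tokenizer,
) -> list[CommentRecord]:
    """Drop comments of <= 5 tokens; comments of >= 6 tokens are retained."""
    return [r for r in records if len(tokenizer(r)) > SHORT_COMMENT_MAX_TOKENS]


def anonymize(records: list[CommentRecord]) -> list[CommentRecord]:
    """Replace every alias with ``Name(seq)``; idempotent."""
    return [replace(rec, alias=f"Name({rec.seq})") for rec in records]


def preprocess_pipeline(
    records: list[CommentRecord],
    tokenizer: Callable[[CommentRecord], list[str]] = default_tokenizer,
) -> list[CommentRecord]:
    """Deduplicate, then drop short comments, then anonymize.

    Sequence numbers are not reassigned, so anonymized names keep pointing at
    the original comment numbers. Logs the count removed at each stage.
    """
    deduped = deduplicate(records)
    long_enough = filter_short(deduped, tokenizer)
    cleaned = anonymize(long_enough)
    logger.info(
        "preprocess: %d in, %d duplicates removed, %d short removed, %d out",
        len(records),
        len(records) - len(deduped),
        len(deduped) - len(long_enough),
        len(cleaned),
    )
    return cleaned
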