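"""Retrieval-augmented comment summarization.

Retained comments are embedded into a vector index; at summarization time
the approach's predefined question is embedded, the top-k most similar
comments are retrieved, and a prompt (question + retrieved context) is sent
to a pluggable text-generation backend. Two summary approaches exist, each
with a fixed English question:

* ``general`` — "Can you summarize the comments? What are the
  characteristics of the comments?"
* ``medical_focus`` — "Can you summarize the comments? What are the
  diseases? What are the symptoms of the disease? And other interesting
  information?"

The shipped backends are fully offline and deterministic: ``hash_embed``
(feature hashing of normalized tokens into a fixed-dimension unit vector)
and ``MockLLMBackend`` (a digest of the retrieved context). Remote
embedding/generation services plug in through the same two-method contract.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass
from typing import Iterable, Protocol, Sequence

import numpy as np

from . import knowledge_extraction, nlp_core

__all__ = [
    "QUESTIONS",
    "EmbeddingVector",
    "VectorIndex",
    "PromptTemplate",
    "EmbeddingBackend",
    "GenerationBackend",
    "HashEmbedBackend",
    "MockLLMBackend",
    "embed",
    "build_index",
    "retrieve",
    "render_prompt",
    "summarize",
]

GENERAL = "general"
MEDICAL_FOCUS = "medical_focus"

# The two predefined questions, fixed verbatim; summaries are always English.
QUESTIONS = {
    GENERAL: (
        "Can you summarize the comments? "
        "What are the characteristics of the comments?"
    ),
    MEDICAL_FOCUS: (
        "Can you summarize the comments? What are the diseases? "
        "What are the symptoms of the disease? And other interesting information?"
    ),
}

NO_CONTEXT_MARKER = "[no context retrieved]"


@dataclass(frozen=True)
class EmbeddingVector:
    values: tuple[float, ...]
    source_seq: int


@dataclass
class VectorIndex:
    """A flat cosine-similarity index over comment embeddings."""

    vectors: list[EmbeddingVector]

    def __post_init__(self) -> None:
        dims = {len(v.values) for v in self.vectors}
        if len(dims) > 1:
            raise ValueError(f"inconsistent embedding dimensions: {sorted(dims)}")
        seqs = [v.source_seq for v in self.vectors]
        if len(seqs) != len(set(seqs)):
            raise ValueError("source_seq values must be unique within an index")

    @property
    def dimension(self) -> int:
        return len(self.vectors[0].values) if self.vectors else 0

    def matrix(self) -> np.ndarray:
        return np.array([v.values for v in self.vectors], dtype=float)


@dataclass(frozen=True)
class PromptTemplate:
    approach: str
    question_text: str
    framing: str = (
        "You are summarizing public social-media comments about "
        "non-communicable diseases. Answer in English, based only on the "
        "comments below.\n\nQuestion: {question}\n\nComments:\n{context}"
    )

    def render(self, retrieved_texts: Sequence[str]) -> str:
        context = (
            "\n".join(f"- {t}" for t in retrieved_texts)
            if retrieved_texts
            else NO_CONTEXT_MARKER
        )
        return self.framing.format(question=self.question_text, context=context)


class EmbeddingBackend(Protocol):
    def embed(self, texts: Sequence[str]) -> list[list[float]]: ...


class GenerationBackend(Protocol):
    def generate(self, prompt: str) -> str: ...


class HashEmbedBackend:
    """Deterministic offline embedding: seeded feature hashing.

    Each normalized token is hashed (BLAKE2b keyed with the seed) to a
    coordinate and a sign; token counts accumulate and the vector is
    L2-normalized. Identical texts always map to identical vectors.
    """

    def __init__(self, dimension: int = 256, seed: int = 0):
        if dimension < 2:
            raise ValueError("dimension must be >= 2")
        self.dimension = dimension
        self._key = str(seed).encode()

    def _token_slot(self, token: str) -> tuple[int, float]:
        digest = hashlib.blake2b(token.encode("utf-8"), key=self._key, digest_size=8)
        h = int.from_bytes(digest.digest(), "big")
        return h % self.dimension, 1.0 if (h >> 62) & 1 else -1.0

    def embed(self, texts: Sequence[str]) -> list[list[float]]:
        out = []
        for text in texts:
            lang = nlp_core.detect_language(text)
            tokens = nlp_core.normalize_tokens(nlp_core.tokenize(text, lang), lang)
            vec = np.zeros(self.dimension)
            for tok in tokens:
                idx, sign = self._token_slot(tok)
                vec[idx] += sign
            norm = np.linalg.norm(vec)
            if norm > 0:
                vec /= norm
            out.append(vec.tolist())
        return out


class MockLLMBackend:
    """Deterministic stand-in generator for offline pipelines and tests.

    Emits a digest of the prompt's context block: the number of context
    comments and the sorted disease labels matched in them by the lexicon.
    """

    def __init__(self, lexicon: knowledge_extraction.Lexicon | None = None):
        self.lexicon = lexicon or knowledge_extraction.default_lexicon()

    def generate(self, prompt: str) -> str:
        lines = [
            l[2:] for l in prompt.splitlines() if l.startswith("- ")
        ]
        diseases: set[str] = set()
        for i, line in enumerate(lines, start=1):
            tok = nlp_core.tokenize_comment(i, line)
            diseases.update(
                knowledge_extraction.match_category(tok, self.lexicon, "disease")
            )
        disease_str = ", ".join(sorted(diseases)) if diseases else "none identified"
        return (
            f"Summary of {len(lines)} comments. "
            f"Diseases mentioned: {disease_str}."
        )


def embed(
    texts: Sequence[str],
    backend: EmbeddingBackend | None = None,
    seqs: Sequence[int] | None = None,
) -> list[EmbeddingVector]:
    """Embed texts into EmbeddingVectors tagged with their source seq."""
    backend = backend or HashEmbedBackend()
    seqs = list(seqs) if seqs is not None else list(range(1, len(texts) + 1))
    if len(seqs) != len(texts):
        raise ValueError("seqs and texts must have equal length")
    raw = backend.embed(texts)
    return [
        EmbeddingVector(values=tuple(vec), source_seq=seq)
        for vec, seq in zip(raw, seqs)
    ]


def build_index(vectors: Iterable[EmbeddingVector]) -> VectorIndex:
    return VectorIndex(list(vectors))


def retrieve(index: VectorIndex, query_vector: Sequence[float], k: int) -> list[int]:
    """Source seqs of the k items most cosine-similar to the query.

    Descending similarity, ties broken by lower source_seq; asking for more
    items than the index holds returns everything.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if not index.vectors:
        raise ValueError("cannot retrieve from an empty index")
    mat = index.matrix()
    q = np.asarray(query_vector, dtype=float)
    if q.shape[0] != index.dimension:
        raise ValueError("query dimension does not match index dimension")
    norms = np.linalg.norm(mat, axis=1) * (np.linalg.norm(q) or 1.0)
    norms[norms == 0] = 1.0  # zero vectors get similarity 0
    sims = mat @ q / norms
    order = sorted(
        range(len(index.vectors)),
        key=lambda i: (-sims[i], index.vectors[i].source_seq),
    )
    return [index.vectors[i].source_seq for i in order[: min(k, len(order))]]


def render_prompt(approach: str, retrieved_texts: Sequence[str]) -> str:
    """Render the approach's prompt with the retrieved context block."""
    if approach not in QUESTIONS:
        raise ValueError(f"unknown approach {approach!r}; choose from {sorted(QUESTIONS)}")
    template = PromptTemplate(approach=approach, question_text=QUESTIONS[approach])
    return template.render(retrieved_texts)


def summarize(
    comments: Sequence[tuple[int, str]],
    approach: str = MEDICAL_FOCUS,
    k: int = 20,
    llm_backend: GenerationBackend | None = None,
    embed_backend: EmbeddingBackend | None = None,
) -> str:
    """End-to-end RAG summary of (seq, text) comments.

    Embeds the comments, retrieves the top-k most similar to the approach's
    question, renders the prompt and calls the generation backend. Defaults
    are the offline deterministic backends.
    """
    if not comments:
        raise ValueError("cannot summarize an empty comment set")
    if approach not in QUESTIONS:
        raise ValueError(f"unknown approach {approach!r}; choose from {sorted(QUESTIONS)}")
    embed_backend = embed_backend or HashEmbedBackend()
    llm_backend = llm_backend or MockLLMBackend()
    seqs = [s for s, _ in comments]
    texts = [t for _, t in comments]
    index = build_index(embed(texts, embed_backend, seqs))
    query = embed_backend.embed([QUESTIONS[approach]])[0]
    top = retrieve(index, query, k)
    by_seq = dict(comments)
    prompt = render_prompt(approach, [by_seq[s] for s in top])
    return llm_backend.generate(prompt)
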