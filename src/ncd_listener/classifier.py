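"""Three-way comment topic classification.

Every comment is assigned to exactly one of three categories:

* ``sharing_experience`` — first-person accounts of living with a disease,
* ``inquiring`` — questions about symptoms, treatments or impacts,
* ``non_informative`` — everything else (off-topic, bare disease names).

Three interchangeable backends sit behind one ``classify(text) -> label``
contract:

* ``rule_based`` (default, no training): interrogative cues (question marks,
  wh-words, Thai question particles) -> inquiring; else first-person
  experience cues -> sharing_experience; else non_informative.
* ``linear_bow``: bag-of-words + logistic regression, trainable on a desk
  scale in seconds, fully seeded.
* ``transformer``: the fine-tuning recipe (70/30 stratified split, minority
  oversampling, max sequence length 200, learning rate 2e-5, early stopping
  on a validation split) for a pretrained BERT-family encoder. It requires
  the optional ``transformers`` dependency and model weights, so it is never
  exercised in the test suite; the recipe parameters live in ``TrainConfig``.
"""

from __future__ import annotations

import re
from collections import Counter
from dataclasses import dataclass
from typing import Protocol, Sequence

import numpy as np

from . import nlp_core

__all__ = [
    "LABELS",
    "LabeledComment",
    "TrainConfig",
    "ConfusionMatrix",
    "ClassMetrics",
    "ClassifierModel",
    "split_data",
    "oversample",
    "train",
    "classify",
    "evaluate",
    "RuleBasedClassifier",
    "LinearBowClassifier",
]

SHARING = "sharing_experience"
INQUIRING = "inquiring"
NON_INFORMATIVE = "non_informative"
LABELS = (SHARING, INQUIRING, NON_INFORMATIVE)


@dataclass(frozen=True)
class LabeledComment:
    text: str
    label: str
    language: str = nlp_core.UNKNOWN

    def __post_init__(self) -> None:
        if self.label not in LABELS:
            raise ValueError(f"label must be one of {LABELS}, got {self.label!r}")


@dataclass
class TrainConfig:
    """Training recipe parameters (defaults follow the published recipe)."""

    test_fraction: float = 0.30
    max_sequence_length: int = 200
    learning_rate: float = 2e-5
    early_stopping_patience: int = 3
    validation_fraction: float = 0.10
    oversample: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.test_fraction < 1:
            raise ValueError("test_fraction must be in (0, 1)")
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")


# ---------------------------------------------------------------------------
# Data plumbing


def split_data(
    labeled: Sequence[LabeledComment], config: TrainConfig
) -> tuple[list[LabeledComment], list[LabeledComment]]:
    """Stratified-by-label random train/test split, reproducible from seed."""
    if len(labeled) < 10:
        raise ValueError("need at least 10 labeled comments to split")
    counts = Counter(c.label for c in labeled)
    scarce = [l for l, n in counts.items() if n < 2]
    if scarce:
        raise ValueError(f"classes with < 2 instances cannot be stratified: {scarce}")
    from sklearn.model_selection import train_test_split

    train_set, test_set = train_test_split(
        list(labeled),
        test_size=config.test_fraction,
        random_state=config.seed,
        stratify=[c.label for c in labeled],
    )
    return list(train_set), list(test_set)


def oversample(
    train_set: Sequence[LabeledComment], seed: int = 0
) -> list[LabeledComment]:
    """Balance classes by seeded random duplication of minority items.

    Every class is upsampled to the majority class count; the output is the
    input plus duplicates, never touching any held-out data.
    """
    counts = Counter(c.label for c in train_set)
    if not counts:
        raise ValueError("cannot oversample an empty training set")
    for lbl, n in counts.items():
        if n == 0:
            raise ValueError(f"class {lbl!r} has no instances")
    target = max(counts.values())
    rng = np.random.default_rng(seed)
    out = list(train_set)
    for lbl in sorted(counts):
        pool = [c for c in train_set if c.label == lbl]
        deficit = target - len(pool)
        if deficit > 0:
            picks = rng.integers(0, len(pool), size=deficit)
            out.extend(pool[i] for i in picks)
    return out


# ---------------------------------------------------------------------------
# Backends


class ClassifierModel(Protocol):
    def classify(self, text: str) -> str: ...


_WH_WORDS = {
    "what", "why", "how", "when", "where", "who", "whom", "which",
    "can", "could", "should", "is", "are", "does", "do", "did", "anyone",
}
_TH_QUESTION_PARTICLES = (
    "ไหม", "มั้ย", "หรือเปล่า", "ทำไม", "อะไร", "อย่างไร", "ยังไง",
    "ที่ไหน", "เมื่อไหร่", "เหรอ", "หรอ", "กี่", "ใคร",
)
_FIRST_PERSON_EN = {"i", "i've", "i'm", "i'd", "my", "me", "myself", "mine"}
_FIRST_PERSON_TH = ("ผม", "ฉัน", "ดิฉัน", "แม่", "พ่อ", "ครอบครัว", "ตัวเอง", "เคย")
_EXPERIENCE_EN = {
    "diagnose", "diagnosed", "survive", "survived", "suffer", "suffered",
    "treatment", "treated", "recovered", "experience", "living",
}


class RuleBasedClassifier:
    """Cue-based classifier: total, deterministic, needs no training data.

    Precedence: interrogative cues beat experience cues (a question that
    mentions personal context is still a question); comments with neither
    cue family are non-informative.
    """

    def classify(self, text: str) -> str:
        if "?" in text:
            return INQUIRING
        lowered = text.lower()
        if any(p in text for p in _TH_QUESTION_PARTICLES):
            return INQUIRING
        tokens = nlp_core.tokenize(lowered, nlp_core.detect_language(text))
        if tokens and tokens[0] in _WH_WORDS:
            return INQUIRING
        if any(t in _FIRST_PERSON_EN for t in tokens) or any(
            p in text for p in _FIRST_PERSON_TH
        ):
            return SHARING
        if any(t in _EXPERIENCE_EN for t in tokens):
            return SHARING
        return NON_INFORMATIVE


class LinearBowClassifier:
    """Bag-of-words + multinomial logistic regression, seeded."""

    def __init__(self, config: TrainConfig):
        from sklearn.feature_extraction.text import CountVectorizer
        from sklearn.linear_model import LogisticRegression
        from sklearn.pipeline import Pipeline

        self.config = config
        self._pipeline = Pipeline(
            [
                ("bow", CountVectorizer(analyzer=_bow_analyzer, min_df=1)),
                (
                    "logreg",
                    LogisticRegression(max_iter=1000, random_state=config.seed),
                ),
            ]
        )
        self._fitted = False

    def fit(self, train_set: Sequence[LabeledComment]) -> "LinearBowClassifier":
        texts = [c.text for c in train_set]
        labels = [c.label for c in train_set]
        self._pipeline.fit(texts, labels)
        self._fitted = True
        return self

    def classify(self, text: str) -> str:
        if not self._fitted:
            raise RuntimeError("LinearBowClassifier.classify called before fit")
        return str(self._pipeline.predict([text])[0])


def _bow_analyzer(text: str) -> list[str]:
    lang = nlp_core.detect_language(text)
    tokens = nlp_core.tokenize(text, lang)
    return nlp_core.normalize_tokens(tokens, lang)


class TransformerClassifier:  # pragma: no cover - requires optional heavy deps
    """Fine-tuned BERT-family backend; needs the ``transformers`` package.

    Default checkpoints: ``wangchanberta-base-att-spm-uncased`` (Thai) and
    ``bert-large-uncased`` (English). The maximum sequence length from
    ``TrainConfig`` is applied in tokenizer units.
    """

    DEFAULT_CHECKPOINTS = {
        nlp_core.THAI: "airesearch/wangchanberta-base-att-spm-uncased",
        nlp_core.ENGLISH: "bert-large-uncased",
    }

    def __init__(self, config: TrainConfig, checkpoint: str | None = None):
        try:
            import transformers  # noqa: F401
        except ImportError as exc:
            raise ImportError(
                "the transformer backend requires the optional 'transformers' "
                "package and downloadable model weights; use rule_based or "
                "linear_bow for offline work"
            ) from exc
        self.config = config
        self.checkpoint = checkpoint

    def fit(self, train_set: Sequence[LabeledComment]) -> "TransformerClassifier":
        raise NotImplementedError(
            "transformer fine-tuning is intentionally not bundled; the recipe "
            "parameters are carried by TrainConfig for external training scripts"
        )

    def classify(self, text: str) -> str:
        raise NotImplementedError("transformer backend has no bundled weights")


BACKENDS = ("rule_based", "linear_bow", "transformer")


def train(
    labeled: Sequence[LabeledComment] | None,
    config: TrainConfig | None = None,
    backend: str = "rule_based",
) -> ClassifierModel:
    """Build a classifier with the given backend.

    ``rule_based`` needs no data and returns immediately. ``linear_bow``
    splits off nothing itself — callers hold out their own test set — but
    honours ``config.oversample`` before fitting.
    """
    config = config or TrainConfig()
    if backend == "rule_based":
        return RuleBasedClassifier()
    if backend == "linear_bow":
        if not labeled:
            raise ValueError("linear_bow backend requires labeled training data")
        train_set = list(labeled)
        if config.oversample:
            train_set = oversample(train_set, seed=config.seed)
        return LinearBowClassifier(config).fit(train_set)
    if backend == "transformer":
        model = TransformerClassifier(config)
        if labeled:
            model.fit(labeled)
        return model
    raise ValueError(f"unknown backend {backend!r}; choose from {BACKENDS}")


def classify(model: ClassifierModel, text: str) -> str:
    label = model.classify(text)
    if label not in LABELS:
        raise ValueError(f"backend produced an out-of-taxonomy label {label!r}")
    return label


# ---------------------------------------------------------------------------
# Evaluation


@dataclass
class ConfusionMatrix:
    """Rows = true label, columns = predicted label, in ``labels`` order."""

    labels: tuple[str, ...]
    counts: np.ndarray  # shape (k, k), non-negative ints

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def to_lists(self) -> list[list[int]]:
        return [[int(v) for v in row] for row in self.counts]


@dataclass
class ClassMetrics:
    """One-vs-rest precision/recall/F1 per class plus overall accuracy."""

    precision: dict[str, float]
    recall: dict[str, float]
    f1: dict[str, float]
    accuracy: float


def evaluate(
    predictions: Sequence[str], gold: Sequence[str], labels: Sequence[str] = LABELS
) -> tuple[ConfusionMatrix, ClassMetrics]:
    """Confusion matrix and one-vs-rest metrics.

    Per class: P = TP/(TP+FP), R = TP/(TP+FN), F1 = 2PR/(P+R); each defined
    as 0 when its denominator is 0. Accuracy = trace/N.
    """
    if len(predictions) != len(gold):
        raise ValueError("predictions and gold must have equal length")
    if not gold:
        raise ValueError("cannot evaluate an empty set")
    labels = tuple(labels)
    index = {l: i for i, l in enumerate(labels)}
    counts = np.zeros((len(labels), len(labels)), dtype=int)
    for p, g in zip(predictions, gold):
        counts[index[g], index[p]] += 1
    precision, recall, f1 = {}, {}, {}
    for l, i in index.items():
        tp = counts[i, i]
        fp = counts[:, i].sum() - tp
        fn = counts[i, :].sum() - tp
        p = tp / (tp + fp) if tp + fp > 0 else 0.0
        r = tp / (tp + fn) if tp + fn > 0 else 0.0
        precision[l] = float(p)
        recall[l] = float(r)
        f1[l] = float(2 * p * r / (p + r)) if p + r > 0 else 0.0
    accuracy = float(np.trace(counts) / counts.sum())
    return ConfusionMatrix(labels, counts), ClassMetrics(precision, recall, f1, accuracy)
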