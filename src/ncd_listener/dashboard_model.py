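"""Dashboard aggregation data model.

Aggregates per-comment extracted knowledge into the eight chart
specifications of the user-validated dashboard. Default visibility follows
the user study's rule: variables whose mean relevance rating reached at
least 4.21 on the 1-5 Likert scale ("Very Good") are shown by default, the
rest stay hidden but retrievable:

========================  ====  =======  =========
variable                  type  rating   default
========================  ====  =======  =========
gender                    pie   4.67     visible
source of opinion         pie   3.56     hidden
categorized comments      pie   3.56     hidden
mentioned diseases        bar   5.00     visible
mentioned symptoms        bar   4.67     visible
mentioned treatments      bar   4.89     visible
patient behaviors         bar   4.78     visible
most frequent words       bar   3.33     hidden
========================  ====  =======  =========

Each comment contributes at most once per label to a bar chart, regardless
of how many times it repeats the term. The report/export layer emits JSON
and the canonical comment CSV; presentation (web UI, PDF) is out of scope.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from . import ingestion, knowledge_extraction
from .ingestion import CommentRecord
from .knowledge_extraction import ExtractedKnowledge
from .nlp_core import TokenizedComment

__all__ = [
    "VARIABLES",
    "VISIBLE_BY_DEFAULT",
    "ChartSpec",
    "DashboardState",
    "aggregate",
    "build_state",
    "refilter",
    "export_table",
    "build_report",
]

# (variable name, chart type, visible by default per the >= 4.21 rating rule)
VARIABLES: tuple[tuple[str, str, bool], ...] = (
    ("gender", "pie", True),
    ("source", "pie", False),
    ("categorized_comments", "pie", False),
    ("diseases", "bar", True),
    ("symptoms", "bar", True),
    ("treatments", "bar", True),
    ("behaviors", "bar", True),
    ("word_frequency", "bar", False),
)
VISIBLE_BY_DEFAULT = frozenset(name for name, _, vis in VARIABLES if vis)

WORD_FREQUENCY_TOP_K = 20

_LIST_VARIABLE_FIELDS = {
    "diseases": "diseases",
    "symptoms": "symptoms",
    "treatments": "treatments",
    "behaviors": "behaviors",
}


@dataclass
class ChartSpec:
    variable: str
    chart_type: str  # pie | bar
    visible_by_default: bool
    data: list[tuple[str, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.chart_type not in ("pie", "bar"):
            raise ValueError(f"chart_type must be pie or bar, got {self.chart_type!r}")
        if any(count < 0 for _, count in self.data):
            raise ValueError("chart counts must be non-negative")


@dataclass
class DashboardState:
    charts: list[ChartSpec]
    include: set[str] = field(default_factory=set)
    exclude: set[str] = field(default_factory=set)
    summary_text: str = ""
    summary_stale: bool = False
    records: list[CommentRecord] = field(default_factory=list)
    knowledge: list[ExtractedKnowledge] = field(default_factory=list)
    tokenized: list[TokenizedComment] = field(default_factory=list)

    def chart(self, variable: str) -> ChartSpec:
        for c in self.charts:
            if c.variable == variable:
                return c
        raise KeyError(variable)


def _bar_counts(
    knowledge: Sequence[ExtractedKnowledge], fld: str
) -> list[tuple[str, int]]:
    counts: dict[str, int] = {}
    for k in knowledge:
        for label in set(getattr(k, fld)):  # once per comment per label
            counts[label] = counts.get(label, 0) + 1
    return sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))


def _pie_counts(values: Iterable[str], skip: tuple[str, ...] = ()) -> list[tuple[str, int]]:
    counts: dict[str, int] = {}
    for v in values:
        if v in skip or v is None:
            continue
        counts[v] = counts.get(v, 0) + 1
    return sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))


def aggregate(
    knowledge: Sequence[ExtractedKnowledge],
    tokenized: Sequence[TokenizedComment] | None = None,
    top_k_words: int = WORD_FREQUENCY_TOP_K,
) -> list[ChartSpec]:
    """Build the eight chart specs from per-comment knowledge.

    Bar categories are sorted descending by count (ties lexicographic).
    Comments with unknown gender are excluded from the gender pie but remain
    in the underlying table. The word-frequency chart needs the tokenized
    corpus; without it the chart is empty.
    """
    charts = []
    for variable, chart_type, visible in VARIABLES:
        if variable == "gender":
            data = _pie_counts((k.gender for k in knowledge), skip=("unknown",))
        elif variable == "source":
            data = _pie_counts(k.source for k in knowledge)
        elif variable == "categorized_comments":
            data = _pie_counts(k.category for k in knowledge if k.category is not None)
        elif variable == "word_frequency":
            data = (
                list(knowledge_extraction.word_frequency(tokenized, top_k_words))
                if tokenized
                else []
            )
        else:
            data = _bar_counts(knowledge, _LIST_VARIABLE_FIELDS[variable])
        charts.append(ChartSpec(variable, chart_type, visible, data))
    return charts


def build_state(
    records: Sequence[CommentRecord],
    knowledge: Sequence[ExtractedKnowledge],
    tokenized: Sequence[TokenizedComment] | None = None,
    summary_text: str = "",
) -> DashboardState:
    """Assemble a dashboard state from aligned records and knowledge."""
    return DashboardState(
        charts=aggregate(knowledge, tokenized),
        summary_text=summary_text,
        records=list(records),
        knowledge=list(knowledge),
        tokenized=list(tokenized or []),
    )


def refilter(
    state: DashboardState, include: set[str] | None = None, exclude: set[str] | None = None
) -> DashboardState:
    """Apply include/exclude disease/symptom filters and re-aggregate.

    The comment table, knowledge and charts all shrink to the surviving
    comments; the previous summary text is kept but marked stale until a new
    summary is generated over the filtered corpus.
    """
    kept = knowledge_extraction.adjust_selection(state.knowledge, include, exclude)
    kept_seqs = {k.seq for k in kept}
    records = [r for r in state.records if r.seq in kept_seqs]
    tokenized = [t for t in state.tokenized if t.seq in kept_seqs]
    return DashboardState(
        charts=aggregate(kept, tokenized or None),
        include=set(include or ()),
        exclude=set(exclude or ()),
        summary_text=state.summary_text,
        summary_stale=bool(state.summary_text),
        records=records,
        knowledge=kept,
        tokenized=tokenized,
    )


def export_table(state: DashboardState, path: str | Path) -> None:
    """Export the retained comment table as the canonical CSV."""
    ingestion.write_comment_table(state.records, path)


def build_report(state: DashboardState) -> dict:
    """Structured JSON-serializable report of the full dashboard state."""
    report = {
        "charts": [
            {
                "variable": c.variable,
                "chart_type": c.chart_type,
                "visible_by_default": c.visible_by_default,
                "data": [[label, count] for label, count in c.data],
            }
            for c in state.charts
        ],
        "filters": {
            "include": sorted(state.include),
            "exclude": sorted(state.exclude),
        },
        "summary_text": state.summary_text,
        "summary_stale": state.summary_stale,
        "n_comments": len(state.records),
    }
    json.dumps(report)  # guarantee serializability before returning
    return report
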