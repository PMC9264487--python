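"""End-to-end orchestration: question in, slot-filled answer out.

One call runs the whole chain — question-type classification, BIO entity
tagging, span decoding, entity linking, relation routing, template
rendering — and records every intermediate product in a
:class:`PipelineTrace`.  The pipeline is total: any internal failure
degrades to the fallback answer with the cause logged, never an exception.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

from . import answers as answers_mod
from .answers import Answer, QueryPlan, compose_fallback, render_answer, route_question
from .classify import ClassifierModel
from .corpus import AnnotatedQuestion, read_corpus, tokens_of
from .kb import KnowledgeStore, RelationIndex
from .metrics import JudgedResponse, judgment_report, read_judgments
from .ner import bio_to_spans, _decode

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class PipelineConfig:
    """Paths and knobs for a deployed pipeline instance."""

    classifier_path: str
    embeddings_path: str
    embeddings_dim: int
    tagger_path: str
    kb_concepts: str
    kb_relations: str
    kb_attributes: str
    indices_dir: str
    templates_path: str | None = None
    linking_threshold: float = 0.85
    max_entries: int = 3
    seed: int = 0
    log_level: str = "WARNING"

    @classmethod
    def from_file(cls, path) -> "PipelineConfig":
        cfg = cls(**json.loads(Path(path).read_text(encoding="utf-8")))
        for name in (
            "classifier_path", "embeddings_path", "tagger_path",
            "kb_concepts", "kb_relations", "kb_attributes", "indices_dir",
        ):
            p = getattr(cfg, name)
            if not Path(p).exists():
                raise FileNotFoundError(f"{name}: {p} does not exist")
        return cfg


@dataclass
class PipelineTrace:
    """Everything the pipeline did for one question."""

    text: str
    qtype: str | None = None
    entities: list[tuple[str, str]] = field(default_factory=list)
    linked: dict[str, str | None] = field(default_factory=dict)
    relations: list[str] = field(default_factory=list)
    answer: Answer = Answer(answers_mod.FALLBACK_GENERIC, grounded=False)
    error: str | None = None

    def to_dict(self) -> dict:
        return {
            "text": self.text,
            "qtype": self.qtype,
            "entities": [list(e) for e in self.entities],
            "linked": self.linked,
            "relations": self.relations,
            "answer": {
                "text": self.answer.text,
                "grounded": self.answer.grounded,
                "provenance": list(self.answer.provenance),
            },
            "error": self.error,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineTrace":
        return cls(
            text=d["text"],
            qtype=d["qtype"],
            entities=[tuple(e) for e in d["entities"]],
            linked=d["linked"],
            relations=d["relations"],
            answer=Answer(
                d["answer"]["text"],
                d["answer"]["grounded"],
                tuple(d["answer"]["provenance"]),
            ),
            error=d["error"],
        )


def answer_question(
    text: str,
    classifier: ClassifierModel,
    tagger,
    store: KnowledgeStore,
    indices: dict[str, RelationIndex],
    templates: dict[str, str] | None = None,
    linking_threshold: float = 0.85,
) -> PipelineTrace:
    """Run the full pipeline on one question; total on arbitrary input."""
    trace = PipelineTrace(text=text)
    try:
        trace.qtype = classifier.predict(text)
        toks = tokens_of(text)
        if toks:
            tagged = _decode(tagger, toks)
            trace.entities = bio_to_spans(tagged)
        plan = route_question(trace.qtype, trace.entities, store, linking_threshold)
        trace.relations = plan.relations
        trace.linked = {
            "DS": plan.ds.cui if plan.ds else None,
            "second": plan.second.cui if plan.second else None,
        }
        trace.answer = render_answer(plan, store, indices, templates)
    except Exception as exc:  # noqa: BLE001 — totality is the contract
        log.warning("pipeline degraded to fallback for %r: %s", text[:60], exc)
        trace.error = str(exc)
        trace.answer = compose_fallback(
            QueryPlan(qtype=trace.qtype or "Background", relations=[])
        )
    return trace


def batch_evaluate(
    questions_path,
    classifier,
    tagger,
    store,
    indices,
    judgments_path=None,
    templates=None,
    linking_threshold: float = 0.85,
) -> dict:
    """Answer every corpus question; join judgment grades when supplied.

    Returns ``{"traces": [...], "metrics": {...}|None, "grounded_rate": r}``.
    A qid present in the judgments but not the corpus (or vice versa) is an
    error listing the missing ids.
    """
    corpus = read_corpus(questions_path)
    if not corpus:
        raise ValueError("empty question file")
    traces = {
        q.qid: answer_question(
            q.text, classifier, tagger, store, indices, templates, linking_threshold
        )
        for q in corpus
    }
    report = None
    if judgments_path is not None:
        judgments = read_judgments(judgments_path)
        jids = {j.qid for j in judgments}
        qids = set(traces)
        if jids != qids:
            raise ValueError(
                f"qid mismatch: missing grades for {sorted(qids - jids)}, "
                f"grades without questions {sorted(jids - qids)}"
            )
        report = judgment_report(judgments)
    grounded = sum(t.answer.grounded for t in traces.values()) / len(traces)
    return {
        "traces": [traces[q.qid].to_dict() for q in corpus],
        "metrics": report,
        "grounded_rate": grounded,
    }


def write_traces(traces: list[PipelineTrace], path) -> None:
    """Traces as JSON-lines; round-trips through :func:`read_traces`."""
    with open(path, "w", encoding="utf-8") as fh:
        for t in traces:
            fh.write(json.dumps(t.to_dict(), ensure_ascii=False) + "\n")


def read_traces(path) -> list[PipelineTrace]:
    with open(path, encoding="utf-8") as fh:
        return [PipelineTrace.from_dict(json.loads(line)) for line in fh if line.strip()]
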