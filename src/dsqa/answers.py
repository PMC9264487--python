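"""Question routing and slot-filled natural-language answer rendering.

A classified question plus its extracted entities becomes a
:class:`QueryPlan` — which knowledge-base relations to query and which
concepts fill the slots — and the plan is rendered through a fixed sentence
template per question type.  Templates live in a plain-text config file
(``templates.cfg``) so the wording is auditable and overridable; slots are
written as ``{name}`` placeholders.

Routing rules:

* Effectiveness and Indication both query ``is_effective_for`` (their
  templates are identical, so they are aliases end to end).
* Interaction queries ``interacts_with``; a recognized medication entity, if
  present, narrows the verbalized objects to that drug.
* AdverseEffects queries ``has_adverse_reaction`` (sign/symptom level) first,
  then ``has_adverse_effect`` (organ-class level), concatenating results.
* Background and Safety read the concept's free-text attributes.
* Availability and Usage render the concept's first two source links.

Grounded answers embed only strings retrieved from the store; anything that
cannot be grounded falls back to a fixed apology template.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources

from .corpus import QUESTION_TYPES
from .kb import Concept, KnowledgeStore, RelationIndex, link_entity, query_relation

#: Relations queried per question type (empty list = attribute/link lookup).
QTYPE_RELATIONS: dict[str, list[str]] = {
    "Availability": [],
    "AdverseEffects": ["has_adverse_reaction", "has_adverse_effect"],
    "Background": [],
    "Effectiveness": ["is_effective_for"],
    "Indication": ["is_effective_for"],
    "Interaction": ["interacts_with"],
    "Safety": [],
    "Usage": [],
}

FALLBACK_WITH_SUBJECT = "Sorry, I could not find information about {X}."
FALLBACK_GENERIC = "Sorry, I could not find an answer to that question."


def load_templates(path=None) -> dict[str, str]:
    """Read the qtype -> template table (tab-separated, ``#`` comments)."""
    if path is None:
        text = resources.files("dsqa").joinpath("templates.cfg").read_text("utf-8")
    else:
        with open(path, encoding="utf-8") as fh:
            text = fh.read()
    templates: dict[str, str] = {}
    for line in text.splitlines():
        if not line.strip() or line.lstrip().startswith("#"):
            continue
        qtype, _, tmpl = line.partition("\t")
        if qtype not in QUESTION_TYPES:
            raise ValueError(f"template for unknown question type {qtype!r}")
        templates[qtype] = tmpl
    missing = set(QUESTION_TYPES) - set(templates)
    if missing:
        raise ValueError(f"missing templates for {sorted(missing)}")
    return templates


@dataclass
class QueryPlan:
    """Routing output: relations to query plus linked slot concepts."""

    qtype: str
    relations: list[str]
    ds: Concept | None = None
    ds_surface: str | None = None
    second: Concept | None = None
    second_surface: str | None = None

    @property
    def groundable(self) -> bool:
        return self.ds is not None


@dataclass(frozen=True)
class Answer:
    text: str
    grounded: bool
    provenance: tuple[str, ...] = ()


def route_question(
    qtype: str,
    entities: list[tuple[str, str]],
    store: KnowledgeStore,
    threshold: float = 0.85,
) -> QueryPlan:
    """Build the query plan for a classified question.

    The first DS-labelled entity binds the supplement slot; for Interaction
    questions the first MED entity binds the drug slot, otherwise the first
    DIS entity is kept as secondary context.  Entities are linked against the
    store; a missing or unlinkable supplement makes the plan ungroundable.
    """
    if qtype not in QTYPE_RELATIONS:
        raise ValueError(f"unknown question type {qtype!r}")
    plan = QueryPlan(qtype=qtype, relations=list(QTYPE_RELATIONS[qtype]))
    second_label = "MED" if qtype == "Interaction" else "DIS"
    for surface, label in entities:
        if label == "DS" and plan.ds_surface is None:
            plan.ds_surface = surface
        elif label == second_label and plan.second_surface is None:
            plan.second_surface = surface
    if plan.ds_surface is None and entities:
        # no DS mention: keep the first entity so the fallback can name it
        plan.second_surface = plan.second_surface or entities[0][0]
    if plan.ds_surface is not None and store.concepts:
        plan.ds = link_entity(plan.ds_surface, store, threshold)
    if plan.second_surface is not None and store.concepts:
        plan.second = link_entity(plan.second_surface, store, threshold)
    return plan


def compose_fallback(plan: QueryPlan) -> Answer:
    """The no-answer response; names the best available surface form."""
    subject = (
        (plan.ds.preferred_name if plan.ds else None)
        or plan.ds_surface
        or plan.second_surface
    )
    if subject is None:
        return Answer(FALLBACK_GENERIC, grounded=False)
    return Answer(FALLBACK_WITH_SUBJECT.format(X=subject), grounded=False)


def _joined_links(template: str, links: list[str]) -> str:
    if len(links) >= 2:
        return template.format(link1=links[0], link2=links[1])
    # single link: drop the " or {link2}" clause
    return template.replace(" or {link2}", "").format(link1=links[0])


def render_answer(
    plan: QueryPlan,
    store: KnowledgeStore,
    indices: dict[str, RelationIndex],
    templates: dict[str, str] | None = None,
) -> Answer:
    """Fill the question type's template from the store, or fall back.

    The supplement display name is always the linked concept's stored
    preferred name, not the user's surface form.
    """
    templates = templates or load_templates()
    if not plan.groundable:
        return compose_fallback(plan)
    ds = plan.ds
    template = templates[plan.qtype]

    if plan.relations:
        objects: list[tuple[str, tuple[str, ...]]] = []
        for rel in plan.relations:
            objects.extend(query_relation(ds, rel, indices))
        if plan.second is not None:
            narrowed = [
                o for o in objects if o[0] == plan.second.preferred_name
            ]
            if narrowed:
                objects = narrowed
        if not objects:
            return compose_fallback(plan)
        names = ", ".join(name for name, _ in objects)
        provenance = tuple(sorted({s for _, srcs in objects for s in srcs}))
        return Answer(
            template.format(DS=ds.preferred_name, objects=names),
            grounded=True,
            provenance=provenance,
        )

    if plan.qtype == "Background":
        if not ds.background:
            return compose_fallback(plan)
        return Answer(template.format(background=ds.background), grounded=True)
    if plan.qtype == "Safety":
        if not ds.safety:
            return compose_fallback(plan)
        return Answer(
            template.format(DS=ds.preferred_name, safety=ds.safety), grounded=True
        )
    # Availability / Usage: two-link templates
    links = ds.source_links[:2]
    if not links:
        return compose_fallback(plan)
    return Answer(_joined_links(template, links), grounded=True)
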