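"""Supplement knowledge base: concepts, triples, per-relation indices, linking.

The store mirrors the layout of an integrated dietary-supplement knowledge
base: concepts carry one of seven semantic types —

    SDSI  supplement ingredient       DSP   supplement product
    DIS   disease or syndrome         SPD   pharmaceutical drug
    SOC   system organ class          SS    sign or symptom
    TC    therapeutic class

— and edges are subject–relation–object triples over six relations, each
with a fixed (subject type, object type) signature.  Input files follow the
pipe-delimited RRF convention (one concept-name row or relation row per
line, columns configurable); query-time structures are flat per-relation
JSON indices from normalized subject name to object names, rebuilt
deterministically from the store.

Entity linking is two-stage: exact case-insensitive match on preferred names
and synonyms, then fuzzy matching by normalized edit similarity
(1 - distance/max_length) against a threshold.
"""

from __future__ import annotations

import json
import logging
import re
from dataclasses import dataclass, field
from pathlib import Path

import edlib

log = logging.getLogger(__name__)

SEMANTIC_TYPES: tuple[str, ...] = ("SDSI", "DSP", "DIS", "SPD", "SOC", "SS", "TC")

RELATIONS: tuple[str, ...] = (
    "has_adverse_effect",
    "has_adverse_reaction",
    "has_ingredient",
    "has_therapeutic_class",
    "interacts_with",
    "is_effective_for",
)

#: (subject type, object type) signature of each relation.
RELATION_SIGNATURES: dict[str, tuple[str, str]] = {
    "has_adverse_effect": ("SDSI", "SOC"),
    "has_adverse_reaction": ("SDSI", "SS"),
    "has_ingredient": ("DSP", "SDSI"),
    "has_therapeutic_class": ("SDSI", "TC"),
    "interacts_with": ("SDSI", "SPD"),
    "is_effective_for": ("SDSI", "DIS"),
}


class KbError(ValueError):
    pass


def normalize_name(name: str) -> str:
    """Case-fold, trim, and collapse internal whitespace (the match key)."""
    return re.sub(r"\s+", " ", name.strip()).casefold()


def canonical_relation(raw: str) -> str | None:
    """Map a raw relation string ("interacts with", "INTERACTS_WITH") to the enum."""
    key = re.sub(r"[\s_]+", "_", raw.strip().casefold())
    return key if key in RELATIONS else None


@dataclass
class Concept:
    cui: str
    preferred_name: str
    semantic_type: str
    synonyms: list[str] = field(default_factory=list)
    background: str | None = None
    safety: str | None = None
    source_links: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.semantic_type not in SEMANTIC_TYPES:
            raise KbError(f"unknown semantic type {self.semantic_type!r}")

    @property
    def all_names(self) -> list[str]:
        return [self.preferred_name, *self.synonyms]


@dataclass(frozen=True)
class Triple:
    subject_cui: str
    relation: str
    object_cui: str
    sources: tuple[str, ...] = ()


@dataclass
class KnowledgeStore:
    """In-process concept + triple container with name lookup tables."""

    concepts: dict[str, Concept] = field(default_factory=dict)
    triples: list[Triple] = field(default_factory=list)

    def __post_init__(self) -> None:
        self._by_name: dict[str, list[str]] = {}
        for c in self.concepts.values():
            self._index_names(c)

    def _index_names(self, c: Concept) -> None:
        for name in c.all_names:
            self._by_name.setdefault(normalize_name(name), []).append(c.cui)

    def add_concept(self, c: Concept) -> None:
        if c.cui in self.concepts:
            raise KbError(f"duplicate cui {c.cui}")
        self.concepts[c.cui] = c
        self._index_names(c)

    def exact_lookup(self, name: str) -> list[Concept]:
        cuis = self._by_name.get(normalize_name(name), [])
        return [self.concepts[c] for c in sorted(set(cuis))]


# ---------------------------------------------------------------------------
# Pipe-delimited readers (RRF convention)


@dataclass(frozen=True)
class ConceptColumns:
    """Column indices of the concept (MRCONSO-style) file.

    Default layout: CUI|NAME|TTY|STY|SAB — term-type "P" marks the preferred
    name row; all other rows for the same CUI become synonyms.
    """

    cui: int = 0
    name: int = 1
    term_type: int = 2
    semantic_type: int = 3
    source: int = 4


@dataclass(frozen=True)
class RelationColumns:
    """Column indices of the relation (MRREL-style) file: SUBJ|REL|OBJ|SAB."""

    subject: int = 0
    relation: int = 1
    object: int = 2
    source: int = 3


@dataclass(frozen=True)
class AttributeColumns:
    """Column indices of the attribute file: CUI|ATTR|VALUE.

    Recognized attribute names: ``background``, ``safety``, ``source_link``.
    """

    cui: int = 0
    name: int = 1
    value: int = 2


def _split_row(line: str, lineno: int, max_index: int) -> list[str]:
    fields = line.rstrip("\n").split("|")
    if len(fields) <= max_index:
        raise KbError(
            f"line {lineno}: {len(fields)} fields, need index {max_index}"
        )
    return fields


def read_concepts(path, columns: ConceptColumns = ConceptColumns()) -> KnowledgeStore:
    """Read a pipe-delimited concept file, merging rows that share a CUI."""
    store = KnowledgeStore()
    has_preferred: set[str] = set()
    max_idx = max(columns.cui, columns.name, columns.term_type, columns.semantic_type)
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            f = _split_row(line, lineno, max_idx)
            cui = f[columns.cui]
            name = f[columns.name]
            preferred = f[columns.term_type] == "P"
            sty = f[columns.semantic_type]
            existing = store.concepts.get(cui)
            if existing is None:
                # first row stands in as preferred until a P row arrives
                store.add_concept(
                    Concept(cui=cui, preferred_name=name, semantic_type=sty)
                )
                if preferred:
                    has_preferred.add(cui)
            else:
                if existing.semantic_type != sty:
                    raise KbError(
                        f"line {lineno}: cui {cui} has conflicting semantic types"
                    )
                if preferred and cui not in has_preferred:
                    old = existing.preferred_name
                    existing.preferred_name = name
                    if old != name and old not in existing.synonyms:
                        existing.synonyms.append(old)
                    has_preferred.add(cui)
                    store._index_names(existing)
                elif name != existing.preferred_name and name not in existing.synonyms:
                    existing.synonyms.append(name)
                    store._index_names(existing)
    return store


def read_attributes(
    store: KnowledgeStore, path, columns: AttributeColumns = AttributeColumns()
) -> None:
    """Attach background/safety text and source links to loaded concepts."""
    max_idx = max(columns.cui, columns.name, columns.value)
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            f = _split_row(line, lineno, max_idx)
            c = store.concepts.get(f[columns.cui])
            if c is None:
                log.warning("line %d: attribute for unknown cui %s", lineno, f[columns.cui])
                continue
            attr, value = f[columns.name], f[columns.value]
            if attr == "background":
                c.background = value
            elif attr == "safety":
                c.safety = value
            elif attr == "source_link":
                c.source_links.append(value)
            else:
                log.warning("line %d: unknown attribute %r", lineno, attr)


def read_relations(
    path,
    store: KnowledgeStore,
    columns: RelationColumns = RelationColumns(),
    strict: bool = False,
) -> list[Triple]:
    """Read the relation file and join against loaded concepts.

    Rows with unknown relation strings, dangling CUIs, or signature-violating
    type pairs are dropped with a warning (or raise in strict mode).  The
    accepted triples are appended to ``store.triples`` and returned.
    """
    triples: list[Triple] = []
    max_idx = max(columns.subject, columns.relation, columns.object, columns.source)
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            f = _split_row(line, lineno, max_idx)
            rel = canonical_relation(f[columns.relation])
            if rel is None:
                msg = f"line {lineno}: unknown relation {f[columns.relation]!r}"
                if strict:
                    raise KbError(msg)
                log.warning(msg)
                continue
            subj = store.concepts.get(f[columns.subject])
            obj = store.concepts.get(f[columns.object])
            if subj is None or obj is None:
                msg = f"line {lineno}: dangling cui reference"
                if strict:
                    raise KbError(msg)
                log.warning(msg)
                continue
            want = RELATION_SIGNATURES[rel]
            if (subj.semantic_type, obj.semantic_type) != want:
                msg = (
                    f"line {lineno}: {rel} requires {want}, got "
                    f"({subj.semantic_type}, {obj.semantic_type})"
                )
                if strict:
                    raise KbError(msg)
                log.warning(msg)
                continue
            sources = tuple(s for s in f[columns.source].split(";") if s)
            triples.append(Triple(subj.cui, rel, obj.cui, sources))
    store.triples.extend(triples)
    return triples


# ---------------------------------------------------------------------------
# Relation indices


@dataclass
class RelationIndex:
    """relation -> {normalized subject name: [(object name, sources), ...]}."""

    relation: str
    entries: dict[str, list[tuple[str, tuple[str, ...]]]] = field(default_factory=dict)


def build_relation_indices(
    store: KnowledgeStore, max_entries: int = 3
) -> dict[str, RelationIndex]:
    """Group triples per relation, keyed by normalized subject name.

    Deterministic: subjects and objects are sorted by name, per-subject
    object lists truncated at ``max_entries``.
    """
    grouped: dict[str, dict[str, list[tuple[str, tuple[str, ...]]]]] = {}
    for t in store.triples:
        subj = store.concepts[t.subject_cui]
        obj = store.concepts[t.object_cui]
        grouped.setdefault(t.relation, {}).setdefault(
            normalize_name(subj.preferred_name), []
        ).append((obj.preferred_name, t.sources))
    out: dict[str, RelationIndex] = {}
    for rel in sorted(grouped):
        entries = {}
        for subj_name in sorted(grouped[rel]):
            objs = sorted(set(grouped[rel][subj_name]))[:max_entries]
            entries[subj_name] = objs
        out[rel] = RelationIndex(relation=rel, entries=entries)
    return out


def write_indices(indices: dict[str, RelationIndex], out_dir) -> list[Path]:
    """Persist one JSON file per relation (byte-identical on rebuild)."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = []
    for rel in sorted(indices):
        path = out_dir / f"{rel}.json"
        payload = {
            subj: [[name, list(srcs)] for name, srcs in objs]
            for subj, objs in indices[rel].entries.items()
        }
        path.write_text(
            json.dumps({"relation": rel, "entries": payload},
                       indent=2, sort_keys=True, ensure_ascii=False) + "\n",
            encoding="utf-8",
        )
        paths.append(path)
    return paths


def load_indices(in_dir) -> dict[str, RelationIndex]:
    out = {}
    for path in sorted(Path(in_dir).glob("*.json")):
        data = json.loads(path.read_text(encoding="utf-8"))
        entries = {
            subj: [(name, tuple(srcs)) for name, srcs in objs]
            for subj, objs in data["entries"].items()
        }
        out[data["relation"]] = RelationIndex(relation=data["relation"], entries=entries)
    return out


# ---------------------------------------------------------------------------
# Entity linking and queries


def _similarity(a: str, b: str) -> float:
    if not a and not b:
        return 1.0
    dist = edlib.align(a, b)["editDistance"]
    return 1.0 - dist / max(len(a), len(b))


def link_entity(
    surface: str, store: KnowledgeStore, threshold: float = 0.85
) -> Concept | None:
    """Resolve a surface mention to a concept, or ``None`` for no match.

    Stage 1 is exact case-insensitive lookup over preferred names and
    synonyms; stage 2 scores every name by normalized edit similarity and
    keeps the best score at or above ``threshold``.  Ties break on the
    lexicographically smallest CUI.
    """
    if not store.concepts:
        raise KbError("empty store")
    exact = store.exact_lookup(surface)
    if exact:
        return exact[0]
    key = normalize_name(surface)
    best: tuple[float, str] | None = None  # (score, cui); cui breaks ties
    for cui in sorted(store.concepts):
        for name in store.concepts[cui].all_names:
            score = _similarity(key, normalize_name(name))
            if score >= threshold and (best is None or score > best[0]):
                best = (score, cui)
    return store.concepts[best[1]] if best else None


def query_relation(
    subject: Concept, relation: str, indices: dict[str, RelationIndex]
) -> list[tuple[str, tuple[str, ...]]]:
    """Indexed (object name, sources) pairs for a subject, possibly empty."""
    if relation not in RELATIONS:
        raise KbError(f"unknown relation {relation!r}")
    index = indices.get(relation)
    if index is None:
        return []
    return list(index.entries.get(normalize_name(subject.preferred_name), []))
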