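"""Deterministic synthetic fixtures: toy knowledge bases and question corpora.

Real consumer questions and the production supplement knowledge base cannot
ship with the package, so tests and examples run on generated stand-ins that
keep the statistical structure the pipeline assumes:

* a knowledge store with pseudo-named concepts of all seven semantic types,
  signature-valid triples over all six relations, and background/safety/link
  attributes on every supplement ingredient;
* an annotated question corpus drawn from hand-written paraphrase pools
  (>= 5 surface patterns per question type), with class counts proportional
  to the published 8-class distribution of the annotated corpus this package
  models (Availability 147, AdverseEffects 133, Background 125,
  Effectiveness 318, Indication 188, Interaction 237, Safety 108, Usage 253;
  total 1509), gold entity spans with exact character offsets, and a
  configurable fraction of questions prefixed with shuffled filler words.

Pattern pools are constructed to be separable by question type given local
word order: three pairs of types share bag-of-words-identical but
order-swapped patterns, so an order-blind classifier has an intrinsic
handicap against the convolutional one.

A small frozen subset — the worked question/answer examples with Shark
Cartilage, Blessed Thistle and Melatonin, and the example entities of the
annotated-corpus table — is embedded verbatim in every generated store so
worked examples are reproducible byte for byte.  All outputs are pure
functions of the :class:`FixtureSpec`.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping

import numpy as np

from .corpus import AnnotatedQuestion, EntitySpan, QUESTION_TYPES
from .kb import (
    KnowledgeStore,
    read_attributes,
    read_concepts,
    read_relations,
)

#: Published class counts of the annotated corpus (sums to 1509).
TABLE_CLASS_COUNTS: dict[str, int] = {
    "Availability": 147,
    "AdverseEffects": 133,
    "Background": 125,
    "Effectiveness": 318,
    "Indication": 188,
    "Interaction": 237,
    "Safety": 108,
    "Usage": 253,
}


@dataclass(frozen=True)
class FixtureSpec:
    """Everything the generator needs; identical specs give identical bytes."""

    seed: int = 42
    concept_counts: Mapping[str, int] = field(
        default_factory=lambda: {
            "SDSI": 60, "DSP": 10, "DIS": 25, "SPD": 20,
            "SOC": 10, "SS": 20, "TC": 8,
        }
    )
    triples_per_relation: Mapping[str, int] = field(
        default_factory=lambda: {
            "has_adverse_reaction": 90,
            "has_adverse_effect": 70,
            "has_ingredient": 10,
            "has_therapeutic_class": 60,
            "interacts_with": 90,
            "is_effective_for": 100,
        }
    )
    n_questions: int = 2000
    questions_per_qtype: Mapping[str, int] | None = None
    noise_rate: float = 0.1
    max_entries: int = 3


# ---------------------------------------------------------------------------
# Frozen worked-example subset


def _frozen_rows() -> tuple[list[str], list[str], list[str]]:
    """Concept/relation/attribute rows for the embedded worked examples."""
    melatonin_safety = (
        "Melatonin may cause drowsiness. Patients should not drive or operate "
        "heavy machinery until familiar with the effects of melatonin"
    )
    concepts = [
        ("F001", "Shark Cartilage", "SDSI", []),
        ("F002", "Blessed Thistle", "SDSI", []),
        ("F003", "pure crystalline Melatonin", "SDSI", ["Melatonin"]),
        ("F004", "Degenerative Polyarthritis", "DIS", []),
        ("F005", "Eye disorders", "SOC", []),
        ("F006", "Ephedrine", "SDSI", []),
        ("F007", "Levothyroxine", "SPD", []),
        ("F008", "Niacin", "SDSI", []),
        ("F009", "Milk Thistle", "SDSI", []),
        ("F010", "Selenium", "SDSI", []),
        ("F011", "Brewer’s yeast", "SDSI", []),
        ("F012", "L-glutamine", "SDSI", []),
        ("F013", "Barley grass", "SDSI", []),
        ("F014", "Acai berry", "SDSI", []),
        ("F015", "Headache", "SS", []),
        ("F016", "IBS", "DIS", []),
    ]
    concept_rows = []
    for cui, name, sty, syns in concepts:
        concept_rows.append(f"{cui}|{name}|P|{sty}|NMCD")
        for syn in syns:
            concept_rows.append(f"{cui}|{syn}|S|{sty}|NMCD")
    relation_rows = [
        "F001|is_effective_for|F004|NMCD",
        "F002|has_adverse_effect|F005|NMCD",
        "F006|interacts_with|F007|NMCD",
        "F014|has_adverse_reaction|F015|MSKCC",
    ]
    attribute_rows = []
    for cui, name, sty, _ in concepts:
        if sty != "SDSI":
            continue
        safety = (
            melatonin_safety
            if cui == "F003"
            else f"{name} is generally considered safe at recommended doses"
        )
        attribute_rows += [
            f"{cui}|background|{name} is a dietary supplement ingredient used "
            f"in traditional and modern preparations",
            f"{cui}|safety|{safety}",
            f"{cui}|source_link|https://idisk.example/supplement/{cui}",
            f"{cui}|source_link|https://idisk.example/sources/{cui}",
        ]
    return concept_rows, relation_rows, attribute_rows


# ---------------------------------------------------------------------------
# Pseudo-name generation

_SYLLABLES = [
    "bar", "bel", "dor", "dra", "fen", "gal", "gro", "kar", "lim", "lor",
    "mel", "mir", "nar", "nol", "pel", "pli", "quin", "ral", "sar", "tan",
    "thal", "tor", "vel", "ver", "xan", "zel", "zor",
]
_SDSI_SUFFIXES = ["", "", "", " root", " extract", " leaf", " berry", " seed"]
_DIS_SUFFIXES = ["itis", "osis", "algia", "emia", "opathy", "oma"]
_SPD_SUFFIXES = ["zole", "pril", "statin", "mycin", "olol", "oxetine", "azepam"]
_ORGANS = [
    "Skin", "Liver", "Kidney", "Heart", "Nerve", "Muscle",
    "Blood", "Lung", "Bone", "Gut", "Ear", "Thyroid",
]
_SYMPTOM_HEADS = ["stomach", "head", "joint", "muscle", "skin", "chest", "back"]
_SYMPTOM_TAILS = ["cramps", "tingling", "rash", "stiffness", "flutter", "itching", "throbbing"]


def _stem(rng: np.random.RandomState, n_syll: int) -> str:
    return "".join(rng.choice(_SYLLABLES) for _ in range(n_syll)).capitalize()


def _make_name(rng: np.random.RandomState, sty: str, used: set[str]) -> str:
    for _ in range(1000):
        if sty == "SDSI":
            name = _stem(rng, int(rng.randint(2, 4))) + str(rng.choice(_SDSI_SUFFIXES))
        elif sty == "DSP":
            name = _stem(rng, 2) + " " + str(rng.choice(["Complex", "Plus", "Formula"]))
        elif sty == "DIS":
            name = _stem(rng, 2) + str(rng.choice(_DIS_SUFFIXES))
        elif sty == "SPD":
            name = _stem(rng, 2).lower().capitalize() + str(rng.choice(_SPD_SUFFIXES))
        elif sty == "SOC":
            name = str(rng.choice(_ORGANS)) + " disorders"
        elif sty == "SS":
            name = str(rng.choice(_SYMPTOM_HEADS)) + " " + str(rng.choice(_SYMPTOM_TAILS))
        else:  # TC
            name = _stem(rng, 2) + " agents"
        if name.casefold() not in used:
            used.add(name.casefold())
            return name
    raise RuntimeError(f"name pool exhausted for {sty}")


# ---------------------------------------------------------------------------
# Knowledge-base generation

from .kb import RELATION_SIGNATURES  # noqa: E402  (grouped with use below)


def generate_kb(spec: FixtureSpec, out_dir) -> dict[str, Path]:
    """Write pipe-delimited concept/relation/attribute files.

    The frozen worked-example subset is always present; generated triples
    never reuse frozen subjects, so the worked-example answers stay exact.
    Identical specs produce byte-identical files.
    """
    if any(c <= 0 for c in spec.concept_counts.values()):
        raise ValueError("concept counts must be positive")
    rng = np.random.RandomState(spec.seed)
    concept_rows, relation_rows, attribute_rows = _frozen_rows()
    used = {row.split("|")[1].casefold() for row in concept_rows}

    by_type: dict[str, list[tuple[str, str]]] = {sty: [] for sty in spec.concept_counts}
    counter = 0
    for sty in sorted(spec.concept_counts):
        for _ in range(spec.concept_counts[sty]):
            counter += 1
            cui = f"G{counter:04d}"
            name = _make_name(rng, sty, used)
            by_type[sty].append((cui, name))
            concept_rows.append(f"{cui}|{name}|P|{sty}|SYN")

    for rel in sorted(spec.triples_per_relation):
        subj_t, obj_t = RELATION_SIGNATURES[rel]
        subjects = by_type.get(subj_t, [])
        objects = by_type.get(obj_t, [])
        if not subjects or not objects:
            continue
        seen: set[tuple[str, str]] = set()
        count = spec.triples_per_relation[rel]
        for i in range(count):
            subj = subjects[i % len(subjects)]
            obj = objects[int(rng.randint(len(objects)))]
            if (subj[0], obj[0]) in seen:
                continue
            seen.add((subj[0], obj[0]))
            source = str(rng.choice(["NMCD", "MSKCC", "DSLD", "LNHPD"]))
            relation_rows.append(f"{subj[0]}|{rel}|{obj[0]}|{source}")

    for cui, name in by_type.get("SDSI", []):
        attribute_rows += [
            f"{cui}|background|{name} is a dietary supplement ingredient used "
            f"in traditional and modern preparations",
            f"{cui}|safety|{name} is generally considered safe at recommended doses",
            f"{cui}|source_link|https://idisk.example/supplement/{cui}",
            f"{cui}|source_link|https://idisk.example/sources/{cui}",
        ]

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = {
        "concepts": out_dir / "concepts.psv",
        "relations": out_dir / "relations.psv",
        "attributes": out_dir / "attributes.psv",
    }
    paths["concepts"].write_text("\n".join(concept_rows) + "\n", encoding="utf-8")
    paths["relations"].write_text("\n".join(relation_rows) + "\n", encoding="utf-8")
    paths["attributes"].write_text("\n".join(attribute_rows) + "\n", encoding="utf-8")
    return paths


def load_kb(paths: Mapping[str, Path]) -> KnowledgeStore:
    """Read generated fixture files back into a store with triples."""
    store = read_concepts(paths["concepts"])
    read_attributes(store, paths["attributes"])
    read_relations(paths["relations"], store)
    return store


def toy_store(tmp_dir) -> KnowledgeStore:
    """The frozen worked-example store alone (no generated concepts)."""
    tmp_dir = Path(tmp_dir)
    tmp_dir.mkdir(parents=True, exist_ok=True)
    concept_rows, relation_rows, attribute_rows = _frozen_rows()
    (tmp_dir / "concepts.psv").write_text("\n".join(concept_rows) + "\n", "utf-8")
    (tmp_dir / "relations.psv").write_text("\n".join(relation_rows) + "\n", "utf-8")
    (tmp_dir / "attributes.psv").write_text("\n".join(attribute_rows) + "\n", "utf-8")
    return load_kb(
        {
            "concepts": tmp_dir / "concepts.psv",
            "relations": tmp_dir / "relations.psv",
            "attributes": tmp_dir / "attributes.psv",
        }
    )


# ---------------------------------------------------------------------------
# Question generation

# Placeholders: {DS} supplement, {DIS} disease, {MED} drug, {SS} sign/symptom
# (SS surfaces carry the DIS entity label, as in the annotated corpus, where
# symptom mentions such as "headache" are labelled DIS).
#
# Starred comments mark bag-of-words-identical, order-swapped pattern pairs
# across type pairs (Effectiveness/Indication, Safety/Background,
# Usage/Availability): an order-blind model cannot tell the pair apart.
PATTERN_POOLS: dict[str, list[str]] = {
    "Effectiveness": [
        "Does {DS} really work?",
        "Are there any proven benefits to taking {DS}?",
        "Is {DS} effective for {DIS}?",
        "Has anyone had success treating {DIS} with {DS}?",
        "Does {DS} really help with {DIS}?",   # * pair with Indication
        "Can {DS} do anything for {DIS}?",     # * pair with Indication
    ],
    "Indication": [
        "What is {DS} good for?",
        "What are the health benefits of {DS}?",
        "Which conditions is {DS} used against?",
        "What would {DS} be indicated for?",
        "With {DIS} does {DS} really help?",   # * pair with Effectiveness
        "For {DIS} can {DS} do anything?",     # * pair with Effectiveness
    ],
    "Safety": [
        "Is {DS} safe?",
        "Is it safe to take {DS}?",
        "Are there any risks from taking {DS}?",
        "Should I worry about taking {DS}?",
        "Is it fine to use {DS}?",             # * pair with Background
        "Is it ok to try {DS} now?",           # * pair with Background
    ],
    "Background": [
        "What is {DS}?",
        "What exactly is {DS} made of?",
        "Can someone explain what {DS} is?",
        "Tell me more about the supplement {DS}.",
        "To use {DS} is it fine?",             # * pair with Safety
        "Now is it ok to try {DS}?",           # * pair with Safety
    ],
    "Usage": [
        "What is the right dosage of {DS}?",
        "How much {DS} should I take daily?",
        "How do I use {DS} for {DIS}?",
        "When should {DS} be taken?",
        "Can I take {DS} pills at night?",     # * pair with Availability
        "Do people take {DS} with food?",      # * pair with Availability
    ],
    "Availability": [
        "Where can I buy {DS}?",
        "Where can I buy {DS} pills?",
        "Which stores sell {DS}?",
        "Can I order {DS} online?",
        "At night can I take {DS} pills?",     # * pair with Usage
        "With food do people take {DS}?",      # * pair with Usage
    ],
    "Interaction": [
        "Does anyone know if you can take {DS} while taking {MED}?",
        "Does {DS} interact with {MED}?",
        "Is it ok to combine {DS} and {MED}?",
        "Will {DS} mess with my {MED} prescription?",
        "Any interactions between {DS} and {MED}?",
    ],
    "AdverseEffects": [
        "Does {DS} cause {SS}?",
        "What are the side effects of {DS}?",
        "Can {DS} give you {SS}?",
        "Has anyone gotten {SS} from taking {DS}?",
        "Are there bad reactions to {DS}?",
    ],
}

_FILLERS = ["hey", "guys", "please", "help", "quick", "question", "umm", "so"]
_PLACEHOLDER_RE = re.compile(r"\{(DS|DIS|MED|SS)\}")
_SLOT_LABEL = {"DS": "DS", "DIS": "DIS", "MED": "MED", "SS": "DIS"}


@dataclass(frozen=True)
class GeneratedQuestion:
    """A corpus record plus the knowledge it was generated from.

    ``expected`` is the string a correctly grounded answer must contain:
    the generating triple's object name for relation questions, the
    attribute text or first source link otherwise.
    """

    question: AnnotatedQuestion
    relation: str | None
    subject: str
    expected: str


def _fill_pattern(
    pattern: str, slots: dict[str, str], prefix: str
) -> tuple[str, tuple[EntitySpan, ...]]:
    text = prefix
    spans: list[EntitySpan] = []
    pos = 0
    for m in _PLACEHOLDER_RE.finditer(pattern):
        text += pattern[pos : m.start()]
        surface = slots[m.group(1)]
        start = len(text)
        text += surface
        spans.append(EntitySpan(start, start + len(surface), surface, _SLOT_LABEL[m.group(1)]))
        pos = m.end()
    text += pattern[pos:]
    return text, tuple(spans)


def _allocate(n: int, weights: Mapping[str, int]) -> dict[str, int]:
    """Largest-remainder allocation of n questions over the 8 types."""
    total = sum(weights.values())
    raw = {qt: n * weights[qt] / total for qt in QUESTION_TYPES}
    counts = {qt: int(raw[qt]) for qt in QUESTION_TYPES}
    short = n - sum(counts.values())
    for qt in sorted(QUESTION_TYPES, key=lambda q: raw[q] - counts[q], reverse=True)[:short]:
        counts[qt] += 1
    return counts


def generate_corpus(
    spec: FixtureSpec, store: KnowledgeStore
) -> list[GeneratedQuestion]:
    """Generate the annotated question corpus against a fixture store.

    Each question instantiates one pattern from its type's pool; relation
    questions sample a stored triple (so the gold entities always exist in
    the store and always link), attribute questions sample a supplement
    ingredient.  Supplement surfaces are lowercased with probability 0.3 to
    vary capitalization.  Output order is a seeded shuffle.
    """
    rng = np.random.RandomState((spec.seed + 1) % 2**31)
    counts = (
        dict(spec.questions_per_qtype)
        if spec.questions_per_qtype is not None
        else _allocate(spec.n_questions, TABLE_CLASS_COUNTS)
    )
    triples_by_rel: dict[str, list] = {}
    for t in store.triples:
        triples_by_rel.setdefault(t.relation, []).append(t)
    sdsi = sorted(
        c.cui for c in store.concepts.values()
        if c.semantic_type == "SDSI" and c.background
    )
    dis_names = sorted(
        c.preferred_name for c in store.concepts.values() if c.semantic_type == "DIS"
    )

    from .answers import QTYPE_RELATIONS  # late import: avoids a cycle

    out: list[GeneratedQuestion] = []
    qid = 0
    for qtype in QUESTION_TYPES:
        pool = PATTERN_POOLS[qtype]
        relations = QTYPE_RELATIONS[qtype]
        for _ in range(counts.get(qtype, 0)):
            qid += 1
            pattern = pool[int(rng.randint(len(pool)))]
            slots: dict[str, str] = {}
            if relations:
                rel = relations[0]
                cand = triples_by_rel.get(rel, [])
                if not cand:
                    raise ValueError(f"no {rel} triples in the store")
                t = cand[int(rng.randint(len(cand)))]
                subj = store.concepts[t.subject_cui]
                obj = store.concepts[t.object_cui]
                slots["DS"] = subj.preferred_name
                slots["DIS"] = obj.preferred_name if obj.semantic_type == "DIS" else ""
                slots["MED"] = obj.preferred_name if obj.semantic_type == "SPD" else ""
                slots["SS"] = obj.preferred_name if obj.semantic_type == "SS" else ""
                # patterns only reference slots their relation provides,
                # except generic DIS mentions in effectiveness-style patterns
                if "{DIS}" in pattern and not slots["DIS"]:
                    slots["DIS"] = dis_names[int(rng.randint(len(dis_names)))]
                if "{SS}" in pattern and not slots["SS"]:
                    pattern = pool[0]  # AE pool index 0 always has {SS}
                expected = obj.preferred_name
                relation = rel
            else:
                subj = store.concepts[sdsi[int(rng.randint(len(sdsi)))]]
                slots["DS"] = subj.preferred_name
                slots["DIS"] = dis_names[int(rng.randint(len(dis_names)))]
                relation = None
                if qtype == "Background":
                    expected = subj.background or ""
                elif qtype == "Safety":
                    expected = subj.safety or ""
                else:  # Availability / Usage
                    expected = subj.source_links[0] if subj.source_links else ""
            if rng.rand() < 0.3:
                slots["DS"] = slots["DS"].lower()
            prefix = ""
            if rng.rand() < spec.noise_rate:
                k = int(rng.randint(1, 4))
                words = list(rng.choice(_FILLERS, size=k, replace=False))
                rng.shuffle(words)
                prefix = " ".join(words) + " "
            text, spans = _fill_pattern(pattern, slots, prefix)
            out.append(
                GeneratedQuestion(
                    question=AnnotatedQuestion(
                        qid=f"q{qid:05d}", text=text, qtype=qtype, entities=spans
                    ),
                    relation=relation,
                    subject=subj.preferred_name,
                    expected=expected,
                )
            )
    order = rng.permutation(len(out))
    return [out[i] for i in order]


# ---------------------------------------------------------------------------
# Printed worked examples


def builtin_paper_examples() -> tuple[list[AnnotatedQuestion], list[tuple[str, str]]]:
    """The published worked examples, byte-exact.

    Returns the eight example questions (one per type, with their gold
    labels and entity offsets) and the three printed question/answer pairs
    from the end-to-end response examples.  Note the second QA pair is the
    production system's own (nonstandard) wording, preserved as printed.
    """

    def q(qid, text, qtype, ents):
        spans = []
        for surface, label in ents:
            start = text.index(surface)
            spans.append(EntitySpan(start, start + len(surface), surface, label))
        return AnnotatedQuestion(qid=qid, text=text, qtype=qtype, entities=tuple(spans))

    corpus = [
        q(
            "ex1",
            "Does anyone know if you can take ephedrine while taking levothyroxine?",
            "Interaction",
            [("ephedrine", "DS"), ("levothyroxine", "MED")],
        ),
        q(
            "ex2",
            "L-glutamine whats an appropriate dosage for ibs?",
            "Usage",
            [("L-glutamine", "DS"), ("ibs", "DIS")],
        ),
        q("ex3", "Does Niacin really work?", "Effectiveness", [("Niacin", "DS")]),
        q(
            "ex4",
            "Does acai berry cause headache?",
            "AdverseEffects",
            [("acai berry", "DS"), ("headache", "DIS")],
        ),
        q(
            "ex5",
            "Does anyone know the health benefits to barley grass?",
            "Indication",
            [("barley grass", "DS")],
        ),
        q("ex6", "What is Milk Thistle?", "Background", [("Milk Thistle", "DS")]),
        q("ex7", "Is brewer’s yeast safe?", "Safety", [("brewer’s yeast", "DS")]),
        q(
            "ex8",
            "Where can I buy Selenium pills?",
            "Availability",
            [("Selenium", "DS")],
        ),
    ]
    qa_pairs = [
        (
            "Is it safe to take melatonin?",
            "Here is what I found about pure crystalline Melatonin: Melatonin "
            "may cause drowsiness. Patients should not drive or operate heavy "
            "machinery until familiar with the effects of melatonin",
        ),
        (
            "Are there any dangerous side effects that anyone has experienced "
            "with the supplement milk thistle?",
            "The Blessed Thistle preparation has adverse effects like Eye disorders",
        ),
        (
            "Are there any proven bene- fits to taking shark cartilage?",
            "Shark Cartilage is effective for Degenerative Polyarthritis",
        ),
    ]
    return corpus, qa_pairs


def write_manifest(spec: FixtureSpec, out_dir) -> Path:
    """Record the generating spec next to the fixture files."""
    path = Path(out_dir) / "manifest.json"
    payload = asdict(spec)
    payload["concept_counts"] = dict(spec.concept_counts)
    payload["triples_per_relation"] = dict(spec.triples_per_relation)
    if spec.questions_per_qtype is not None:
        payload["questions_per_qtype"] = dict(spec.questions_per_qtype)
    path.write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n", "utf-8")
    return path
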