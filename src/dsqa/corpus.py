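"""Annotated question corpus: data model, I/O, tokenization, BIO tagging, agreement.

The corpus unit is a consumer-health question about dietary supplements,
labelled with one of eight question types (the intent driving knowledge-base
relation selection) and zero or more character-offset entity spans over four
entity types: dietary supplement (DS), disease (DIS), medication (MED) and
miscellaneous (MISC).  Offsets are 0-based, half-open, everywhere.

Corpus files are JSON-lines (UTF-8, one record per line).  Tagged sequences
can additionally be exchanged in CoNLL-style two-column text (token TAB tag,
blank line between sentences).
"""

from __future__ import annotations

import json
import logging
import re
from dataclasses import dataclass, field
from typing import Iterable, Sequence

log = logging.getLogger(__name__)

#: The eight question-type labels, alphabetical.  Order is the canonical
#: label order used for deterministic tie-breaking throughout the package.
QUESTION_TYPES: tuple[str, ...] = (
    "AdverseEffects",
    "Availability",
    "Background",
    "Effectiveness",
    "Indication",
    "Interaction",
    "Safety",
    "Usage",
)

#: The four entity types.
ENTITY_TYPES: tuple[str, ...] = ("DS", "DIS", "MED", "MISC")

#: The nine BIO tags, in canonical (alphabetical) order; used for
#: deterministic tie-breaking in decoders.
BIO_TAGS: tuple[str, ...] = tuple(
    sorted(f"{p}-{t}" for p in "BI" for t in ENTITY_TYPES)
) + ("O",)


class CorpusError(ValueError):
    """Raised for malformed or invariant-violating corpus input."""


@dataclass(frozen=True)
class EntitySpan:
    """A character-offset entity annotation.

    ``start`` is inclusive, ``end`` exclusive; ``surface`` must equal the
    question text sliced at ``[start:end]`` (checked by AnnotatedQuestion).
    """

    start: int
    end: int
    surface: str
    label: str

    def __post_init__(self) -> None:
        if self.label not in ENTITY_TYPES:
            raise CorpusError(f"unknown entity label {self.label!r}")
        if not (0 <= self.start < self.end):
            raise CorpusError(f"bad span offsets [{self.start}, {self.end})")


@dataclass(frozen=True)
class AnnotatedQuestion:
    """A question string with its type label and entity spans.

    Invariants (enforced at construction): the qtype is one of the eight
    labels; spans lie inside the text, match their surface forms, are sorted
    by start offset and do not overlap.
    """

    qid: str
    text: str
    qtype: str
    entities: tuple[EntitySpan, ...] = ()
    focus: str | None = None  # preserved from annotation, unused downstream

    def __post_init__(self) -> None:
        if self.qtype not in QUESTION_TYPES:
            raise CorpusError(f"unknown qtype {self.qtype!r}")
        object.__setattr__(self, "entities", tuple(self.entities))
        prev_end = -1
        for sp in sorted(self.entities, key=lambda s: s.start):
            if sp.end > len(self.text):
                raise CorpusError(
                    f"span [{sp.start}, {sp.end}) exceeds text length {len(self.text)}"
                )
            if self.text[sp.start : sp.end] != sp.surface:
                raise CorpusError(
                    f"surface {sp.surface!r} != text[{sp.start}:{sp.end}] "
                    f"{self.text[sp.start:sp.end]!r}"
                )
            if sp.start < prev_end:
                raise CorpusError("overlapping entity spans")
            prev_end = sp.end
        object.__setattr__(
            self, "entities", tuple(sorted(self.entities, key=lambda s: s.start))
        )


@dataclass(frozen=True)
class TaggedSequence:
    """Tokens paired with BIO tags; the bridge to the sequence taggers."""

    tokens: tuple[str, ...]
    tags: tuple[str, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "tokens", tuple(self.tokens))
        object.__setattr__(self, "tags", tuple(self.tags))
        if len(self.tokens) != len(self.tags):
            raise CorpusError("tokens and tags differ in length")
        prev = "O"
        for tag in self.tags:
            if tag not in BIO_TAGS:
                raise CorpusError(f"unknown BIO tag {tag!r}")
            if tag.startswith("I-") and prev[2:] != tag[2:]:
                raise CorpusError(f"dangling {tag} after {prev}")
            prev = tag


# ---------------------------------------------------------------------------
# Tokenization

_TOKEN_RE = re.compile(r"\w+(?:-\w+)*|[^\w\s]", re.UNICODE)


def tokenize(text: str) -> list[tuple[str, int, int]]:
    """Split ``text`` into (token, start, end) triples.

    Tokens are maximal runs of word characters, with hyphens kept when they
    join word characters on both sides ("L-glutamine" is one token); every
    other punctuation mark is its own single-character token.  Deterministic;
    offsets are 0-based half-open into ``text``.
    """
    return [(m.group(), m.start(), m.end()) for m in _TOKEN_RE.finditer(text)]


def tokens_of(text: str) -> list[str]:
    """Token strings only (convenience wrapper around :func:`tokenize`)."""
    return [t for t, _, _ in tokenize(text)]


# ---------------------------------------------------------------------------
# BIO conversion


def to_bio(q: AnnotatedQuestion) -> TaggedSequence:
    """Project character-offset entity spans onto token-level BIO tags.

    A span whose boundary falls inside a token is expanded outward to the
    covering token boundaries (with a logged warning) rather than rejected:
    annotation noise should degrade, not crash, downstream training.
    """
    toks = tokenize(q.text)
    tags = ["O"] * len(toks)
    for sp in q.entities:
        covered = [
            i for i, (_, s, e) in enumerate(toks) if s < sp.end and e > sp.start
        ]
        if not covered:
            log.warning("span %r covers no token; dropped", sp.surface)
            continue
        first, last = covered[0], covered[-1]
        if toks[first][1] != sp.start or toks[last][2] != sp.end:
            log.warning(
                "span %r misaligned with token boundaries; expanded to [%d, %d)",
                sp.surface,
                toks[first][1],
                toks[last][2],
            )
        tags[first] = f"B-{sp.label}"
        for i in covered[1:]:
            tags[i] = f"I-{sp.label}"
    return TaggedSequence(tuple(t for t, _, _ in toks), tuple(tags))


def from_bio(q_text: str, seq: TaggedSequence) -> list[EntitySpan]:
    """Recover character-offset spans from a BIO tagging of ``q_text``.

    Inverse of :func:`to_bio` for token-aligned annotations.
    """
    toks = tokenize(q_text)
    if len(toks) != len(seq.tokens):
        raise CorpusError("sequence does not tokenize from the given text")
    spans: list[EntitySpan] = []
    i = 0
    while i < len(seq.tags):
        tag = seq.tags[i]
        if tag.startswith("B-"):
            label = tag[2:]
            j = i + 1
            while j < len(seq.tags) and seq.tags[j] == f"I-{label}":
                j += 1
            start, end = toks[i][1], toks[j - 1][2]
            spans.append(EntitySpan(start, end, q_text[start:end], label))
            i = j
        else:
            i += 1
    return spans


# ---------------------------------------------------------------------------
# Corpus I/O


def _question_from_record(rec: dict, lineno: int) -> AnnotatedQuestion:
    try:
        entities = tuple(
            EntitySpan(e["start"], e["end"], e["surface"], e["label"])
            for e in rec.get("entities", [])
        )
        return AnnotatedQuestion(
            qid=str(rec.get("qid", lineno)),
            text=rec["text"],
            qtype=rec["qtype"],
            entities=entities,
            focus=rec.get("focus"),
        )
    except KeyError as exc:
        raise CorpusError(f"line {lineno}: missing field {exc}") from exc
    except CorpusError as exc:
        raise CorpusError(f"line {lineno}: {exc}") from exc


def read_corpus(path) -> list[AnnotatedQuestion]:
    """Read a JSON-lines corpus file into validated questions."""
    out: list[AnnotatedQuestion] = []
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            try:
                rec = json.loads(line)
            except json.JSONDecodeError as exc:
                raise CorpusError(f"line {lineno}: not valid JSON: {exc}") from exc
            out.append(_question_from_record(rec, lineno))
    return out


def write_corpus(questions: Iterable[AnnotatedQuestion], path) -> None:
    """Write questions as canonical JSON-lines (inverse of :func:`read_corpus`)."""
    with open(path, "w", encoding="utf-8") as fh:
        for q in questions:
            rec = {
                "qid": q.qid,
                "text": q.text,
                "qtype": q.qtype,
                "entities": [
                    {"start": s.start, "end": s.end, "surface": s.surface, "label": s.label}
                    for s in q.entities
                ],
            }
            if q.focus is not None:
                rec["focus"] = q.focus
            fh.write(json.dumps(rec, ensure_ascii=False) + "\n")


def write_conll(sequences: Iterable[TaggedSequence], path) -> None:
    """Write tagged sequences as two-column CoNLL text (token TAB tag)."""
    with open(path, "w", encoding="utf-8") as fh:
        for seq in sequences:
            for tok, tag in zip(seq.tokens, seq.tags):
                fh.write(f"{tok}\t{tag}\n")
            fh.write("\n")


def read_conll(path) -> list[TaggedSequence]:
    """Read two-column CoNLL text back into tagged sequences."""
    seqs: list[TaggedSequence] = []
    toks: list[str] = []
    tags: list[str] = []
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                if toks:
                    seqs.append(TaggedSequence(tuple(toks), tuple(tags)))
                    toks, tags = [], []
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise CorpusError(f"line {lineno}: expected 'token<TAB>tag'")
            toks.append(parts[0])
            tags.append(parts[1])
    if toks:
        seqs.append(TaggedSequence(tuple(toks), tuple(tags)))
    return seqs


# ---------------------------------------------------------------------------
# Corpus statistics


def class_distribution(corpus: Sequence[AnnotatedQuestion]) -> dict[str, int]:
    """Count questions per type; every one of the 8 labels is a key."""
    counts = {qt: 0 for qt in QUESTION_TYPES}
    for q in corpus:
        counts[q.qtype] += 1
    return counts


@dataclass(frozen=True)
class RatingTable:
    """An items x categories table of categorical rating counts.

    Row ``i`` gives how many of the ``raters_per_item`` raters assigned item
    ``i`` to each category; every row must sum to ``raters_per_item``.
    """

    counts: tuple[tuple[int, ...], ...]
    raters_per_item: int

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "counts", tuple(tuple(int(c) for c in row) for row in self.counts)
        )
        if self.raters_per_item <= 0:
            raise CorpusError("raters_per_item must be positive")
        for i, row in enumerate(self.counts):
            if any(c < 0 for c in row):
                raise CorpusError(f"negative count in row {i}")
            if sum(row) != self.raters_per_item:
                raise CorpusError(
                    f"row {i} sums to {sum(row)}, expected {self.raters_per_item}"
                )


def fleiss_kappa(table: RatingTable) -> float | None:
    """Fleiss' chance-corrected multi-rater agreement, kappa = (P - Pe)/(1 - Pe).

    P is the mean per-item pairwise agreement and Pe the agreement expected
    from the marginal category proportions.  When every rating falls in a
    single category Pe = 1 and kappa is undefined; ``None`` is returned so
    callers can decide how severe that is.
    """
    n = table.raters_per_item
    rows = table.counts
    N = len(rows)
    if N == 0:
        raise CorpusError("empty rating table")
    if n == 1:
        return None  # pairwise agreement undefined with a single rater
    total = N * n
    ncat = len(rows[0])
    p_j = [sum(row[j] for row in rows) / total for j in range(ncat)]
    p_bar = sum(
        (sum(c * c for c in row) - n) / (n * (n - 1)) for row in rows
    ) / N
    pe = sum(p * p for p in p_j)
    if abs(1.0 - pe) < 1e-15:
        return None
    return (p_bar - pe) / (1.0 - pe)
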