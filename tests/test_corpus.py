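"""Corpus data model, tokenizer, BIO projection, agreement statistic."""

import json

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from dsqa.corpus import (
    BIO_TAGS,
    CorpusError,
    AnnotatedQuestion,
    EntitySpan,
    RatingTable,
    TaggedSequence,
    class_distribution,
    fleiss_kappa,
    from_bio,
    read_conll,
    read_corpus,
    to_bio,
    tokenize,
    tokens_of,
    write_conll,
    write_corpus,
)
from dsqa.fixtures import builtin_paper_examples


# ---------------------------------------------------------------------------
# Tokenizer


@pytest.mark.parametrize(
    ("text", "expected"),
    [
        ("Does Niacin really work?", ["Does", "Niacin", "really", "work", "?"]),
        ("Is brewer’s yeast safe?", ["Is", "brewer", "’", "s", "yeast", "safe", "?"]),
        ("", []),
        ("L-glutamine whats a dosage?", ["L-glutamine", "whats", "a", "dosage", "?"]),
    ],
)
def test_tokenize_rule(text, expected):
    assert tokens_of(text) == expected


def test_tokenize_offsets_reconstruct_input():
    text = "Will Karvex root mess with my Velproxen prescription?"
    for tok, start, end in tokenize(text):
        assert text[start:end] == tok


# ---------------------------------------------------------------------------
# Data model validation


def test_span_end_beyond_text_rejected():
    with pytest.raises(CorpusError):
        AnnotatedQuestion(
            qid="x", text="short", qtype="Safety",
            entities=[EntitySpan(0, 99, "short", "DS")],
        )


def test_overlapping_spans_rejected():
    with pytest.raises(CorpusError, match="overlap"):
        AnnotatedQuestion(
            qid="x", text="acai berry", qtype="Safety",
            entities=[
                EntitySpan(0, 10, "acai berry", "DS"),
                EntitySpan(5, 10, "berry", "DIS"),
            ],
        )


def test_unknown_qtype_and_label_rejected():
    with pytest.raises(CorpusError):
        AnnotatedQuestion(qid="x", text="hi", qtype="Chitchat")
    with pytest.raises(CorpusError):
        EntitySpan(0, 2, "hi", "GENE")


def test_dangling_i_tag_rejected_by_sequence_type():
    with pytest.raises(CorpusError):
        TaggedSequence(("a", "b"), ("O", "I-DS"))


# ---------------------------------------------------------------------------
# Corpus I/O


def test_read_corpus_single_record(tmp_path):
    path = tmp_path / "c.jsonl"
    path.write_text(
        json.dumps(
            {
                "text": "Does Niacin really work?",
                "qtype": "Effectiveness",
                "entities": [
                    {"start": 5, "end": 11, "surface": "Niacin", "label": "DS"}
                ],
            }
        )
        + "\n"
    )
    (q,) = read_corpus(path)
    assert q.qtype == "Effectiveness"
    assert q.entities[0].surface == "Niacin"
    assert q.text[q.entities[0].start : q.entities[0].end] == "Niacin"


def test_read_corpus_empty_file(tmp_path):
    path = tmp_path / "c.jsonl"
    path.write_text("")
    assert read_corpus(path) == []


def test_read_corpus_malformed_line_names_lineno(tmp_path):
    path = tmp_path / "c.jsonl"
    path.write_text('{"text": "ok", "qtype": "Safety", "entities": []}\n{nope\n')
    with pytest.raises(CorpusError, match="line 2"):
        read_corpus(path)


def test_corpus_roundtrip_is_identity(tmp_path, corpus):
    sample = corpus[:50]
    p1, p2 = tmp_path / "a.jsonl", tmp_path / "b.jsonl"
    write_corpus(sample, p1)
    write_corpus(read_corpus(p1), p2)
    assert p1.read_bytes() == p2.read_bytes()


def test_conll_roundtrip(tmp_path, corpus):
    seqs = [to_bio(q) for q in corpus[:20]]
    path = tmp_path / "seqs.conll"
    write_conll(seqs, path)
    assert read_conll(path) == seqs


# ---------------------------------------------------------------------------
# BIO projection


@pytest.mark.parametrize(
    ("text", "ents", "expected_tags"),
    [
        (
            "What is Milk Thistle?",
            [("Milk Thistle", "DS")],
            ["O", "O", "B-DS", "I-DS", "O"],
        ),
        ("Does Niacin help?", [], ["O", "O", "O", "O"]),
        (
            "Does acai berry cause headache?",
            [("acai berry", "DS"), ("headache", "DIS")],
            ["O", "B-DS", "I-DS", "O", "B-DIS", "O"],
        ),
    ],
)
def test_to_bio_examples(text, ents, expected_tags):
    spans = []
    for surface, label in ents:
        s = text.index(surface)
        spans.append(EntitySpan(s, s + len(surface), surface, label))
    q = AnnotatedQuestion(qid="x", text=text, qtype="Background", entities=spans)
    assert list(to_bio(q).tags) == expected_tags


def test_misaligned_span_expands_to_token_boundaries(caplog):
    text = "Taking Selenium?"
    q = AnnotatedQuestion(
        qid="x", text=text, qtype="Safety",
        entities=[EntitySpan(7, 11, "Sele", "DS")],
    )
    seq = to_bio(q)
    assert list(seq.tags) == ["O", "B-DS", "O"]


def test_bio_roundtrip_on_fixture_and_printed_examples(corpus):
    examples, _ = builtin_paper_examples()
    for q in list(corpus[:300]) + examples:
        seq = to_bio(q)
        recovered = from_bio(q.text, seq)
        assert [(s.surface, s.label) for s in recovered] == [
            (s.surface, s.label) for s in q.entities
        ]
        # tag validity: every I-X follows B-X/I-X of the same type
        prev = "O"
        for tag in seq.tags:
            if tag.startswith("I-"):
                assert prev[2:] == tag[2:]
            prev = tag


# ---------------------------------------------------------------------------
# Distribution


def test_class_distribution_conserves_counts(corpus):
    dist = class_distribution(corpus)
    assert sum(dist.values()) == len(corpus)
    assert len(dist) == 8


def test_class_distribution_empty():
    assert sum(class_distribution([]).values()) == 0


# ---------------------------------------------------------------------------
# Fleiss' kappa


def _fleiss_oracle(counts, n):
    """Direct transcription of the agreement formula, independent of dsqa."""
    N = len(counts)
    ncat = len(counts[0])
    p_j = [sum(row[j] for row in counts) / (N * n) for j in range(ncat)]
    p_bar = sum((sum(c * c for c in row) - n) / (n * (n - 1)) for row in counts) / N
    pe = sum(p * p for p in p_j)
    return (p_bar - pe) / (1 - pe)


def test_fleiss_perfect_agreement_is_one():
    t = RatingTable(((3, 0), (0, 3), (3, 0)), raters_per_item=3)
    assert fleiss_kappa(t) == pytest.approx(1.0)


def test_fleiss_single_category_undefined():
    t = RatingTable(((3, 0), (3, 0)), raters_per_item=3)
    assert fleiss_kappa(t) is None


def test_fleiss_hand_worked_example():
    # rows [[3,0],[0,3],[2,1]]: P=7/9, Pe=41/81, kappa=22/40
    t = RatingTable(((3, 0), (0, 3), (2, 1)), raters_per_item=3)
    assert fleiss_kappa(t) == pytest.approx(0.55, abs=1e-12)


def test_fleiss_row_sum_mismatch_rejected():
    with pytest.raises(CorpusError):
        RatingTable(((2, 0), (3, 0)), raters_per_item=3)


def test_fleiss_matches_independent_oracles_on_random_tables():
    from statsmodels.stats.inter_rater import fleiss_kappa as sm_fleiss

    rng = np.random.RandomState(7)
    checked = 0
    while checked < 100:
        items, raters, cats = rng.randint(2, 12), rng.randint(2, 6), rng.randint(2, 5)
        counts = rng.multinomial(raters, np.ones(cats) / cats, size=items)
        table = RatingTable(tuple(map(tuple, counts)), raters_per_item=raters)
        ours = fleiss_kappa(table)
        if ours is None:
            continue
        assert ours == pytest.approx(_fleiss_oracle(counts.tolist(), raters), abs=1e-12)
        assert ours == pytest.approx(sm_fleiss(counts), abs=1e-9)
        checked += 1


# ---------------------------------------------------------------------------
# Property: BIO round trip on arbitrary token-aligned annotations


@settings(max_examples=100, derandomize=True)
@given(st.data())
def test_bio_roundtrip_property(data):
    words = data.draw(
        st.lists(st.from_regex(r"[a-z]{1,6}", fullmatch=True), min_size=1, max_size=8)
    )
    text = " ".join(words)
    toks = tokenize(text)
    # choose disjoint token runs as entities
    spans = []
    i = 0
    while i < len(toks):
        if data.draw(st.booleans()):
            j = min(len(toks), i + data.draw(st.integers(1, 2)))
            label = data.draw(st.sampled_from(["DS", "DIS", "MED", "MISC"]))
            start, end = toks[i][1], toks[j - 1][2]
            spans.append(EntitySpan(start, end, text[start:end], label))
            i = j
        else:
            i += 1
    q = AnnotatedQuestion(qid="p", text=text, qtype="Usage", entities=spans)
    seq = to_bio(q)
    assert set(seq.tags) <= set(BIO_TAGS)
    got = [(s.surface, s.label) for s in from_bio(text, seq)]
    assert got == [(s.surface, s.label) for s in spans]
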