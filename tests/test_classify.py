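"""Question-type classifiers: embeddings, training contracts, metrics."""

import numpy as np
import pytest

from dsqa.classify import (
    LABELS,
    ClassifierModel,
    Hyperparameters,
    classification_report,
    evaluate_classifier,
    load_classifier,
    save_classifier,
    train_classifier,
)
from dsqa.corpus import AnnotatedQuestion
from dsqa.embeddings import EmbeddingError, EmbeddingTable, load_word_vectors

SMALL_HP = Hyperparameters(filters_per_width=16, epochs=8, max_len=20)


# ---------------------------------------------------------------------------
# Embedding file parsing


def test_load_word_vectors_parses(tmp_path):
    p = tmp_path / "vecs.txt"
    p.write_text("cat 1.0 0.5 -0.5\ndog 0.0 1.0 2.0\n")
    table = load_word_vectors(p, 3)
    assert len(table.vectors) == 2
    np.testing.assert_allclose(table.lookup("cat"), [1.0, 0.5, -0.5])


def test_load_word_vectors_duplicate_keeps_first(tmp_path):
    p = tmp_path / "vecs.txt"
    p.write_text("cat 1 1 1\ncat 2 2 2\n")
    np.testing.assert_allclose(load_word_vectors(p, 3).lookup("cat"), [1, 1, 1])


def test_load_word_vectors_wrong_field_count(tmp_path):
    p = tmp_path / "vecs.txt"
    p.write_text("cat 1.0 0.5\n")
    with pytest.raises(EmbeddingError, match="line 1"):
        load_word_vectors(p, 3)


def test_oov_policy_zeros(tmp_path):
    p = tmp_path / "vecs.txt"
    p.write_text("cat 1 1 1\n")
    table = load_word_vectors(p, 3)
    np.testing.assert_array_equal(table.lookup("unknowntoken"), np.zeros(3))


def test_cased_lookup_falls_back_to_lowercase():
    table = EmbeddingTable(2, {"niacin": np.ones(2)})
    np.testing.assert_array_equal(table.lookup("Niacin"), np.ones(2))


# ---------------------------------------------------------------------------
# Training contracts


def _tiny_corpus():
    return [
        AnnotatedQuestion(qid="1", text="Is zel safe?", qtype="Safety"),
        AnnotatedQuestion(qid="2", text="Where can I buy zel?", qtype="Availability"),
    ]


def test_empty_training_set_rejected(embeddings):
    with pytest.raises(ValueError):
        train_classifier([], embeddings, kind="linear")


def test_unknown_kind_rejected(embeddings):
    with pytest.raises(ValueError, match="kind"):
        train_classifier(_tiny_corpus(), embeddings, kind="transformer")


@pytest.mark.parametrize("kind", ["linear", "cnn"])
def test_single_example_memorized(kind, embeddings):
    q = AnnotatedQuestion(qid="1", text="Does karvex interact with velpril?",
                          qtype="Interaction")
    model = train_classifier([q], embeddings, kind=kind,
                             hyperparameters=SMALL_HP, seed=0)
    assert model.predict(q.text) == "Interaction"


@pytest.mark.parametrize("kind", ["linear", "cnn"])
def test_probability_simplex(kind, embeddings):
    model = train_classifier(_tiny_corpus(), embeddings, kind=kind,
                             hyperparameters=SMALL_HP, seed=0)
    for text in ["", "xq zz!", "Is zel safe?", "@@@ 123"]:
        proba = model.predict_proba(text)
        assert proba.shape == (8,)
        assert np.all(proba >= 0)
        assert proba.sum() == pytest.approx(1.0, abs=1e-9)


def test_uniform_probability_ties_break_alphabetically(embeddings):
    class UniformStub(ClassifierModel):
        kind = "stub"

        def predict_proba(self, text):
            return np.full(8, 1 / 8)

    stub = UniformStub(embeddings, SMALL_HP)
    assert stub.predict("anything") == "AdverseEffects"
    assert LABELS[0] == "AdverseEffects"


def test_seed_determinism_cnn(split, embeddings):
    train = [g.question for g in split[0][:150]]
    held = [g.question.text for g in split[1][:40]]
    a = train_classifier(train, embeddings, kind="cnn", hyperparameters=SMALL_HP, seed=5)
    b = train_classifier(train, embeddings, kind="cnn", hyperparameters=SMALL_HP, seed=5)
    assert a.predict_many(held) == b.predict_many(held)


def test_label_permutation_permutes_predictions(split, embeddings):
    perm = dict(zip(LABELS, LABELS[1:] + LABELS[:1]))
    train = [g.question for g in split[0][:300]]
    held = [g.question.text for g in split[1][:50]]
    base = train_classifier(train, embeddings, kind="linear", seed=0)
    permuted_corpus = [
        AnnotatedQuestion(qid=q.qid, text=q.text, qtype=perm[q.qtype],
                          entities=q.entities)
        for q in train
    ]
    shifted = train_classifier(permuted_corpus, embeddings, kind="linear", seed=0)
    assert [perm[p] for p in base.predict_many(held)] == shifted.predict_many(held)


def test_missing_class_warns_but_trains(embeddings, caplog):
    import logging

    with caplog.at_level(logging.WARNING, logger="dsqa.classify"):
        model = train_classifier(_tiny_corpus(), embeddings, kind="linear")
    assert "absent" in caplog.text
    assert model.predict_proba("Is zel safe?").shape == (8,)


# ---------------------------------------------------------------------------
# Evaluation report


def _report_oracle(gold, pred):
    """Confusion-matrix arithmetic written out longhand, independent of sklearn."""
    labels = sorted(set(gold))
    out = {}
    for lab in labels:
        tp = sum(1 for g, p in zip(gold, pred) if g == lab and p == lab)
        fp = sum(1 for g, p in zip(gold, pred) if g != lab and p == lab)
        fn = sum(1 for g, p in zip(gold, pred) if g == lab and p != lab)
        prec = tp / (tp + fp) if tp + fp else 0.0
        rec = tp / (tp + fn) if tp + fn else 0.0
        f1 = 2 * prec * rec / (prec + rec) if prec + rec else 0.0
        out[lab] = (prec, rec, f1, gold.count(lab))
    n = len(gold)
    wf1 = sum(f1 * s / n for _, _, f1, s in out.values())
    wp = sum(p * s / n for p, _, _, s in out.values())
    wr = sum(r * s / n for _, r, _, s in out.values())
    acc = sum(g == p for g, p in zip(gold, pred)) / n
    return wp, wr, wf1, acc


def test_report_perfect_and_allwrong():
    gold = ["Safety", "Usage", "Safety"]
    perfect = classification_report(gold, gold)
    assert perfect["accuracy"] == 1.0
    assert perfect["weighted"]["f1"] == pytest.approx(1.0)
    wrong = classification_report(gold, ["Usage", "Safety", "Usage"])
    assert wrong["accuracy"] == 0.0


def test_report_matches_hand_confusion_oracle():
    gold = ["Safety", "Usage", "Safety", "Interaction", "Usage", "Usage"]
    pred = ["Safety", "Safety", "Usage", "Interaction", "Usage", "Interaction"]
    rep = classification_report(gold, pred)
    wp, wr, wf1, acc = _report_oracle(gold, pred)
    assert rep["weighted"]["precision"] == pytest.approx(wp, abs=1e-12)
    assert rep["weighted"]["recall"] == pytest.approx(wr, abs=1e-12)
    assert rep["weighted"]["f1"] == pytest.approx(wf1, abs=1e-12)
    assert rep["accuracy"] == pytest.approx(acc, abs=1e-12)


def test_evaluate_rejects_empty(linear_model):
    with pytest.raises(ValueError):
        evaluate_classifier(linear_model, [])


# ---------------------------------------------------------------------------
# Serialization


@pytest.mark.parametrize("kind", ["linear", "cnn"])
def test_save_load_roundtrip(kind, embeddings, tmp_path):
    model = train_classifier(_tiny_corpus(), embeddings, kind=kind,
                             hyperparameters=SMALL_HP, seed=3)
    path = tmp_path / "model.npz"
    save_classifier(model, path)
    loaded = load_classifier(path, embeddings)
    for text in ["Is zel safe?", "Where can I buy zel?", "zzz"]:
        np.testing.assert_allclose(
            loaded.predict_proba(text), model.predict_proba(text), atol=1e-12
        )
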