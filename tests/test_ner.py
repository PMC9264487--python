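"""Sequence taggers: features, HMM counts, Viterbi optimality, CRF, scoring."""

import itertools

import numpy as np
import pytest

from dsqa.corpus import BIO_TAGS, TaggedSequence
from dsqa.ner import (
    NEG_INF,
    N_TAGS,
    START_MASK,
    TRANSITION_MASK,
    HmmModel,
    bio_to_spans,
    evaluate_tagger,
    featurize_tokens,
    repair_bio,
    span_report,
    tag_spans,
    train_crf,
    train_hmm,
    viterbi_decode,
)

TAG = {t: i for i, t in enumerate(BIO_TAGS)}


# ---------------------------------------------------------------------------
# Features


def test_features_single_token_has_context_markers():
    f = featurize_tokens(["Niacin"], 0)
    assert f["0:lower=niacin"] == 1.0
    assert f["0:istitle"] == 1.0
    assert "-1:BOS" in f and "1:EOS" in f and "-2:BOS" in f


def test_features_include_neighbor_window():
    f = featurize_tokens(["take", "ephedrine"], 1)
    assert f["-1:lower=take"] == 1.0
    assert f["0:suf3=ine"] == 1.0


def test_features_deterministic_and_bounds_checked():
    toks = ["a", "b", "c"]
    assert featurize_tokens(toks, 1) == featurize_tokens(toks, 1)
    with pytest.raises(IndexError):
        featurize_tokens(toks, 3)


# ---------------------------------------------------------------------------
# HMM estimation


def test_hmm_single_observation_initial_probability():
    model = train_hmm([TaggedSequence(("Niacin",), ("B-DS",))], k=0.01)
    assert np.exp(model.init[TAG["B-DS"]]) == pytest.approx(1.0)


def test_hmm_no_i_tags_gives_zero_probability_into_i():
    train = [
        TaggedSequence(("Take", "Selenium"), ("O", "B-DS")),
        TaggedSequence(("ok",), ("O",)),
    ]
    model = train_hmm(train)
    for tag in BIO_TAGS:
        if tag.startswith("I-"):
            assert np.all(model.trans[:, TAG[tag]] <= NEG_INF)
            assert model.init[TAG[tag]] <= NEG_INF


def test_hmm_smoothing_constant_validated():
    with pytest.raises(ValueError):
        train_hmm([TaggedSequence(("a",), ("O",))], k=0.0)
    with pytest.raises(ValueError):
        train_hmm([])


def test_hmm_transitions_match_count_oracle():
    train = [
        TaggedSequence(("acai", "berry"), ("B-DS", "I-DS")),
        TaggedSequence(("ok",), ("O",)),
    ]
    k = 0.01
    model = train_hmm(train, k=k)
    # independent count-and-normalize: active tags {B-DS, I-DS, O}; from B-DS
    # the BIO-valid active targets are {B-DS, I-DS, O} with one observed
    # B-DS -> I-DS transition.
    expected = np.array([0 + k, 1 + k, 0 + k]) / (1 + 3 * k)
    got = np.exp(model.trans[TAG["B-DS"], [TAG["B-DS"], TAG["I-DS"], TAG["O"]]])
    np.testing.assert_allclose(got, expected, atol=1e-12)


# ---------------------------------------------------------------------------
# Viterbi


def _random_model(rng) -> HmmModel:
    def log_row(mask):
        p = np.where(mask, rng.rand(N_TAGS) + 1e-3, 0.0)
        p /= p.sum()
        return np.where(mask, np.log(np.maximum(p, 1e-300)), NEG_INF)

    init = log_row(START_MASK)
    trans = np.vstack([log_row(TRANSITION_MASK[i]) for i in range(N_TAGS)])
    vocab = [f"w{i}" for i in range(5)]
    emissions = {}
    em = rng.rand(len(vocab), N_TAGS) + 1e-3
    em /= em.sum(axis=0, keepdims=True)
    for i, w in enumerate(vocab):
        emissions[w] = np.log(em[i])
    unk = np.log(np.full(N_TAGS, 1e-3))
    return HmmModel(init=init, trans=trans, emissions=emissions, unk=unk, k=0.01)


def _score(model, tokens, path):
    em = model.emission_scores(tokens)
    s = model.init[path[0]] + em[0, path[0]]
    for t in range(1, len(path)):
        s += model.trans[path[t - 1], path[t]] + em[t, path[t]]
    return s


def test_viterbi_equals_bruteforce_on_random_instances():
    rng = np.random.RandomState(1234)
    for _ in range(200):
        model = _random_model(rng)
        n = rng.randint(1, 5)
        tokens = [f"w{rng.randint(6)}" for _ in range(n)]  # w5 exercises UNK
        decoded = viterbi_decode(model, tokens)
        got = _score(model, tokens, [TAG[t] for t in decoded.tags])
        scores = [
            _score(model, tokens, list(path))
            for path in itertools.product(range(N_TAGS), repeat=n)
        ]
        best = max(scores)
        assert got == pytest.approx(best, rel=1e-12)
        if sum(1 for s in scores if s == best) == 1:
            argmax = list(
                itertools.product(range(N_TAGS), repeat=n)
            )[int(np.argmax(scores))]
            assert [TAG[t] for t in decoded.tags] == list(argmax)


def test_viterbi_length_one_closed_form():
    rng = np.random.RandomState(9)
    model = _random_model(rng)
    decoded = viterbi_decode(model, ["w0"])
    best = int(np.argmax(model.init + model.emissions["w0"]))
    assert decoded.tags[0] == BIO_TAGS[best]


def test_viterbi_deterministic_emissions_dominate():
    train = [
        TaggedSequence(("take", "Karvex", "daily"), ("O", "B-DS", "O")),
        TaggedSequence(("take", "Karvex", "daily"), ("O", "B-DS", "O")),
    ]
    model = train_hmm(train, k=0.001)
    assert list(viterbi_decode(model, ["take", "Karvex", "daily"]).tags) == [
        "O", "B-DS", "O",
    ]


# ---------------------------------------------------------------------------
# CRF contracts


def test_crf_all_o_training_predicts_all_o():
    train = [
        TaggedSequence(("hello", "there"), ("O", "O")),
        TaggedSequence(("ok",), ("O",)),
    ]
    model = train_crf(train, max_iterations=20)
    assert list(model.predict_tags(["Niacin", "rocks", "!"]).tags) == ["O", "O", "O"]


def test_crf_deterministic(split):
    from dsqa.corpus import to_bio

    seqs = [to_bio(g.question) for g in split[0][:80]]
    held = [list(to_bio(g.question).tokens) for g in split[1][:20]]
    a = train_crf(seqs, max_iterations=40, seed=0)
    b = train_crf(seqs, max_iterations=40, seed=0)
    assert [a.predict_tags(t).tags for t in held] == [b.predict_tags(t).tags for t in held]


def test_crf_empty_training_rejected():
    with pytest.raises(ValueError):
        train_crf([])


@pytest.mark.parametrize("model_fixture", ["crf_model", "hmm_model"])
def test_taggers_emit_only_valid_bio(model_fixture, request):
    model = request.getfixturevalue(model_fixture)
    rng = np.random.RandomState(3)
    words = ["Karvex", "take", "zz9", "-", "daily", "Melatonin", "??", "root"]
    for _ in range(30):
        toks = [words[i] for i in rng.randint(0, len(words), size=rng.randint(1, 8))]
        seq = (
            viterbi_decode(model, toks)
            if isinstance(model, HmmModel)
            else model.predict_tags(toks)
        )
        TaggedSequence(seq.tokens, seq.tags)  # constructor re-validates BIO


# ---------------------------------------------------------------------------
# Span decoding and evaluation


def test_bio_to_spans_examples():
    assert bio_to_spans(
        ["What", "is", "Milk", "Thistle", "?"], ["O", "O", "B-DS", "I-DS", "O"]
    ) == [("Milk Thistle", "DS")]
    assert bio_to_spans(["nothing", "here"], ["O", "O"]) == []
    assert bio_to_spans(["take", "zinc"], ["O", "I-DS"]) == [("zinc", "DS")]


def test_repair_promotes_dangling_i_to_b():
    assert repair_bio(["O", "I-DS", "I-DS", "I-DIS"]) == [
        "O", "B-DS", "I-DS", "B-DIS",
    ]


class _EchoTagger:
    """Returns a fixed tagging per token tuple (test double)."""

    def __init__(self, mapping):
        self.mapping = mapping

    def predict_tags(self, tokens):
        return TaggedSequence(tuple(tokens), tuple(self.mapping[tuple(tokens)]))


def test_evaluate_tagger_perfect_and_all_o():
    gold = [
        TaggedSequence(("take", "Karvex"), ("O", "B-DS")),
        TaggedSequence(("avoid", "Zelosis"), ("O", "B-DIS")),
    ]
    echo = _EchoTagger({tuple(s.tokens): list(s.tags) for s in gold})
    rep = evaluate_tagger(echo, gold)
    assert rep["weighted"]["f1"] == pytest.approx(1.0)
    assert rep["token_accuracy"] == 1.0

    allo = _EchoTagger({tuple(s.tokens): ["O"] * len(s.tokens) for s in gold})
    rep = evaluate_tagger(allo, gold)
    assert rep["weighted"]["recall"] == 0.0


def test_span_report_matches_hand_scored_oracle():
    # sentence 1: gold DS(0,2) predicted correctly; sentence 2: gold DIS(1,2)
    # predicted as DS (one FP for DS, one FN for DIS); sentence 3: gold DS(0,1)
    # missed entirely.  Hand arithmetic: DS P=R=0.5 F1=0.5; DIS all 0;
    # weighted F1 = (2*0.5 + 1*0)/3.
    gold_pred = [
        ([(0, 2, "DS")], [(0, 2, "DS")]),
        ([(1, 2, "DIS")], [(1, 2, "DS")]),
        ([(0, 1, "DS")], []),
    ]
    rep = span_report(gold_pred)
    assert rep["per_class"]["DS"]["f1"] == pytest.approx(0.5, abs=1e-12)
    assert rep["per_class"]["DIS"]["f1"] == 0.0
    assert rep["weighted"]["f1"] == pytest.approx(1 / 3, abs=1e-12)


def test_tag_spans_positions():
    assert tag_spans(["B-DS", "I-DS", "O", "B-DIS"]) == [(0, 2, "DS"), (3, 4, "DIS")]
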