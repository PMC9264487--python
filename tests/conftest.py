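"""Shared fixtures: one synthetic study (KB + corpus + trained models) per session.

Training the four models is the expensive part of the suite, so everything
downstream shares session-scoped instances built from the default
:class:`~dsqa.fixtures.FixtureSpec` (seed 42, 2000 questions, 80/20 split).
"""

from __future__ import annotations

import pytest

from dsqa import fixtures, kb
from dsqa.classify import train_classifier
from dsqa.corpus import to_bio, tokens_of
from dsqa.embeddings import random_embeddings
from dsqa.ner import train_crf, train_hmm


@pytest.fixture(scope="session")
def spec():
    return fixtures.FixtureSpec()


@pytest.fixture(scope="session")
def store(spec, tmp_path_factory):
    paths = fixtures.generate_kb(spec, tmp_path_factory.mktemp("kb"))
    return fixtures.load_kb(paths)


@pytest.fixture(scope="session")
def indices(store, spec):
    return kb.build_relation_indices(store, max_entries=spec.max_entries)


@pytest.fixture(scope="session")
def generated(spec, store):
    return fixtures.generate_corpus(spec, store)


@pytest.fixture(scope="session")
def corpus(generated):
    return [g.question for g in generated]


@pytest.fixture(scope="session")
def split(generated):
    n = int(0.8 * len(generated))
    return generated[:n], generated[n:]


@pytest.fixture(scope="session")
def embeddings(corpus):
    vocab = {t.lower() for q in corpus for t in tokens_of(q.text)}
    return random_embeddings(vocab, dimension=50, seed=42)


@pytest.fixture(scope="session")
def cnn_model(split, embeddings):
    return train_classifier([g.question for g in split[0]], embeddings, kind="cnn", seed=42)


@pytest.fixture(scope="session")
def linear_model(split, embeddings):
    return train_classifier(
        [g.question for g in split[0]], embeddings, kind="linear", seed=42
    )


@pytest.fixture(scope="session")
def crf_model(split):
    return train_crf([to_bio(g.question) for g in split[0]], seed=42)


@pytest.fixture(scope="session")
def hmm_model(split):
    return train_hmm([to_bio(g.question) for g in split[0]])


@pytest.fixture(scope="session")
def toy_store(tmp_path_factory):
    return fixtures.toy_store(tmp_path_factory.mktemp("toy"))


@pytest.fixture(scope="session")
def toy_indices(toy_store):
    return kb.build_relation_indices(toy_store, max_entries=3)
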