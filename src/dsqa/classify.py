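"""Question-type classifiers.

Two models over the eight question-type labels:

* ``linear`` — a shallow baseline: the mean of the question's token
  embeddings fed to a multinomial logistic-regression classifier.  Order-blind
  by construction; anything it cannot separate must differ in word *content*.
* ``cnn`` — the selected model: frozen word embeddings, parallel 1-D
  convolutions of widths (1, 2, 3, 5), per-filter max-pooling over time,
  concatenation, dropout, and a dense softmax layer.  The multi-width filters
  pick up local word-order context (bigrams, trigrams, 5-grams) that the mean
  embedding discards.

The CNN is implemented directly on numpy (forward, backward, Adam); the
embedding layer is frozen, so gradients stop at the convolution weights.
Training is deterministic given (data, hyperparameters, seed).

Probability vectors are always over the full 8-label set in alphabetical
order; argmax ties therefore resolve to the alphabetically first label.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, asdict

import numpy as np
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import precision_recall_fscore_support

from .corpus import QUESTION_TYPES, AnnotatedQuestion, tokens_of
from .embeddings import EmbeddingTable

log = logging.getLogger(__name__)

LABELS: tuple[str, ...] = QUESTION_TYPES  # alphabetical; canonical order


@dataclass(frozen=True)
class Hyperparameters:
    """Training knobs shared by both classifier kinds (CNN uses all of them)."""

    filter_widths: tuple[int, ...] = (1, 2, 3, 5)
    filters_per_width: int = 100
    dropout: float = 0.5
    max_len: int = 40
    epochs: int = 20
    learning_rate: float = 1e-3
    batch_size: int = 32
    l2: float = 1.0  # inverse-C regularization for the linear baseline


def _softmax(z: np.ndarray) -> np.ndarray:
    z = z - z.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


def _encode_batch(
    texts: list[list[str]], emb: EmbeddingTable, max_len: int, min_len: int
) -> np.ndarray:
    """Stack per-token embedding rows into (N, L, D), zero-padded/truncated."""
    L = max(min_len, min(max_len, max((len(t) for t in texts), default=1)))
    X = np.zeros((len(texts), L, emb.dimension))
    for i, toks in enumerate(texts):
        for j, tok in enumerate(toks[:L]):
            X[i, j] = emb.lookup(tok)
    return X


class ClassifierModel:
    """Common surface: predict_proba over the 8 labels, argmax predict."""

    kind: str

    def __init__(self, emb: EmbeddingTable, hp: Hyperparameters):
        self.emb = emb
        self.hp = hp

    def predict_proba(self, text: str) -> np.ndarray:
        raise NotImplementedError

    def predict(self, text: str) -> str:
        proba = self.predict_proba(text)
        return LABELS[int(np.argmax(proba))]

    def predict_many(self, texts: list[str]) -> list[str]:
        return [self.predict(t) for t in texts]


class LinearClassifier(ClassifierModel):
    """Mean-embedding multinomial logistic regression."""

    kind = "linear"

    def __init__(self, emb, hp, seed: int):
        super().__init__(emb, hp)
        self.seed = seed
        self._lr = LogisticRegression(
            C=hp.l2, max_iter=2000, random_state=seed, solver="lbfgs"
        )
        self._trained_labels: list[str] = []

    def fit(self, questions: list[AnnotatedQuestion]) -> "LinearClassifier":
        X = np.array([self.emb.mean_vector(tokens_of(q.text)) for q in questions])
        y = [q.qtype for q in questions]
        if len(set(y)) == 1:
            # degenerate corpus: a constant model, no fit needed
            self._constant = y[0]
            self._trained_labels = [y[0]]
            return self
        self._constant = None
        self._lr.fit(X, y)
        self._trained_labels = list(self._lr.classes_)
        return self

    def predict_proba(self, text: str) -> np.ndarray:
        if getattr(self, "_constant", None) is not None:
            proba = np.zeros(len(LABELS))
            proba[LABELS.index(self._constant)] = 1.0
            return proba
        x = self.emb.mean_vector(tokens_of(text)).reshape(1, -1)
        raw = self._lr.predict_proba(x)[0]
        proba = np.zeros(len(LABELS))
        for p, lab in zip(raw, self._trained_labels):
            proba[LABELS.index(lab)] = p
        return proba


class CnnClassifier(ClassifierModel):
    """Multi-width convolutional classifier over frozen embeddings."""

    kind = "cnn"

    def __init__(self, emb, hp, seed: int):
        super().__init__(emb, hp)
        self.seed = seed
        rng = np.random.RandomState(seed)
        d, F = emb.dimension, hp.filters_per_width
        # Glorot-style init for each convolution and the dense layer.
        self.conv_w = {
            w: rng.normal(0.0, np.sqrt(2.0 / (w * d + F)), (w * d, F))
            for w in hp.filter_widths
        }
        self.conv_b = {w: np.zeros(F) for w in hp.filter_widths}
        n_cat = F * len(hp.filter_widths)
        self.dense_w = rng.normal(0.0, np.sqrt(2.0 / (n_cat + len(LABELS))), (n_cat, len(LABELS)))
        self.dense_b = np.zeros(len(LABELS))
        self._rng = rng

    # -- forward -----------------------------------------------------------

    def _windows(self, X: np.ndarray, w: int) -> np.ndarray:
        N, L, d = X.shape
        T = L - w + 1
        idx = np.arange(T)[:, None] + np.arange(w)[None, :]
        return X[:, idx, :].reshape(N, T, w * d)

    def _forward(self, X: np.ndarray):
        pooled, cache = [], {}
        for w in self.hp.filter_widths:
            win = self._windows(X, w)                       # (N, T, w*d)
            scores = win @ self.conv_w[w] + self.conv_b[w]  # (N, T, F)
            act = np.maximum(scores, 0.0)
            arg = act.argmax(axis=1)                        # (N, F)
            pool = act.max(axis=1)
            cache[w] = (win, scores, arg)
            pooled.append(pool)
        H = np.concatenate(pooled, axis=1)                  # (N, 4F)
        return H, cache

    def _proba_batch(self, texts: list[list[str]]) -> np.ndarray:
        X = _encode_batch(texts, self.emb, self.hp.max_len, max(self.hp.filter_widths))
        H, _ = self._forward(X)
        return _softmax(H @ self.dense_w + self.dense_b)

    def predict_proba(self, text: str) -> np.ndarray:
        return self._proba_batch([tokens_of(text)])[0]

    # -- training ----------------------------------------------------------

    def fit(self, questions: list[AnnotatedQuestion]) -> "CnnClassifier":
        hp = self.hp
        toks = [tokens_of(q.text) for q in questions]
        y = np.array([LABELS.index(q.qtype) for q in questions])
        n = len(questions)
        F = hp.filters_per_width

        params = (
            [self.conv_w[w] for w in hp.filter_widths]
            + [self.conv_b[w] for w in hp.filter_widths]
            + [self.dense_w, self.dense_b]
        )
        m = [np.zeros_like(p) for p in params]
        v = [np.zeros_like(p) for p in params]
        t = 0
        beta1, beta2, eps = 0.9, 0.999, 1e-8

        for _epoch in range(hp.epochs):
            order = self._rng.permutation(n)
            for lo in range(0, n, hp.batch_size):
                batch = order[lo : lo + hp.batch_size]
                bt = [toks[i] for i in batch]
                X = _encode_batch(bt, self.emb, hp.max_len, max(hp.filter_widths))
                Y = np.zeros((len(batch), len(LABELS)))
                Y[np.arange(len(batch)), y[batch]] = 1.0

                H, cache = self._forward(X)
                keep = (self._rng.rand(*H.shape) >= hp.dropout) / (1.0 - hp.dropout)
                Hd = H * keep
                P = _softmax(Hd @ self.dense_w + self.dense_b)

                dZ = (P - Y) / len(batch)
                g_dense_w = Hd.T @ dZ
                g_dense_b = dZ.sum(axis=0)
                dH = (dZ @ self.dense_w.T) * keep

                grads = []
                for k, w in enumerate(hp.filter_widths):
                    win, scores, arg = cache[w]
                    N_b, T, _ = win.shape
                    dpool = dH[:, k * F : (k + 1) * F]      # (N, F)
                    dscores = np.zeros((N_b, T, F))
                    ii = np.repeat(np.arange(N_b), F)
                    ff = np.tile(np.arange(F), N_b)
                    dscores[ii, arg.ravel(), ff] = dpool.ravel()
                    dscores *= scores > 0
                    g_w = win.reshape(N_b * T, -1).T @ dscores.reshape(N_b * T, F)
                    g_b = dscores.sum(axis=(0, 1))
                    grads.append((g_w, g_b))

                all_grads = (
                    [g for g, _ in grads] + [g for _, g in grads] + [g_dense_w, g_dense_b]
                )
                t += 1
                for p, g, mi, vi in zip(params, all_grads, m, v):
                    mi *= beta1
                    mi += (1 - beta1) * g
                    vi *= beta2
                    vi += (1 - beta2) * g * g
                    mhat = mi / (1 - beta1**t)
                    vhat = vi / (1 - beta2**t)
                    p -= hp.learning_rate * mhat / (np.sqrt(vhat) + eps)
        return self


def train_classifier(
    train: list[AnnotatedQuestion],
    emb: EmbeddingTable,
    kind: str = "cnn",
    hyperparameters: Hyperparameters | None = None,
    seed: int = 0,
) -> ClassifierModel:
    """Train a question-type classifier of the given ``kind``.

    Deterministic given (data, hyperparameters, seed).  A label missing from
    the training data triggers a warning; the model still scores all 8 labels
    (the missing ones just receive zero probability for the linear model, or
    whatever the untrained softmax assigns for the CNN).
    """
    if not train:
        raise ValueError("empty training set")
    if kind not in ("linear", "cnn"):
        raise ValueError(f"unknown classifier kind {kind!r}")
    hp = hyperparameters or Hyperparameters()
    present = {q.qtype for q in train}
    for lab in LABELS:
        if lab not in present:
            log.warning("question type %s absent from training data", lab)
    cls = LinearClassifier if kind == "linear" else CnnClassifier
    return cls(emb, hp, seed).fit(train)


def evaluate_classifier(
    model: ClassifierModel, test: list[AnnotatedQuestion]
) -> dict:
    """Per-class and support-weighted precision/recall/F1 plus accuracy."""
    if not test:
        raise ValueError("empty test set")
    gold = [q.qtype for q in test]
    pred = model.predict_many([q.text for q in test])
    return classification_report(gold, pred)


def classification_report(gold: list[str], pred: list[str]) -> dict:
    """Metrics for explicit gold/pred label lists (shared with the CLI)."""
    labels = list(LABELS)
    p, r, f, s = precision_recall_fscore_support(
        gold, pred, labels=labels, zero_division=0
    )
    wp, wr, wf, _ = precision_recall_fscore_support(
        gold, pred, labels=labels, average="weighted", zero_division=0
    )
    acc = float(np.mean([g == q for g, q in zip(gold, pred)]))
    return {
        "per_class": {
            lab: {
                "precision": float(p[i]),
                "recall": float(r[i]),
                "f1": float(f[i]),
                "support": int(s[i]),
            }
            for i, lab in enumerate(labels)
        },
        "weighted": {"precision": float(wp), "recall": float(wr), "f1": float(wf)},
        "accuracy": acc,
        "n": len(gold),
    }


# ---------------------------------------------------------------------------
# Serialization: one .npz artifact with hyperparameters and label order inside.


def save_classifier(model: ClassifierModel, path) -> None:
    meta = {
        "kind": model.kind,
        "labels": list(LABELS),
        "seed": model.seed,
        "hyperparameters": asdict(model.hp),
    }
    arrays: dict[str, np.ndarray] = {"meta": np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8)}
    if isinstance(model, CnnClassifier):
        for w in model.hp.filter_widths:
            arrays[f"conv_w_{w}"] = model.conv_w[w]
            arrays[f"conv_b_{w}"] = model.conv_b[w]
        arrays["dense_w"] = model.dense_w
        arrays["dense_b"] = model.dense_b
    else:
        assert isinstance(model, LinearClassifier)
        arrays["coef"] = model._lr.coef_
        arrays["intercept"] = model._lr.intercept_
        arrays["classes"] = np.array(model._trained_labels)
    with open(path, "wb") as fh:
        np.savez(fh, **arrays)


def load_classifier(path, emb: EmbeddingTable) -> ClassifierModel:
    with np.load(path, allow_pickle=False) as data:
        meta = json.loads(bytes(data["meta"]).decode())
        hp_d = meta["hyperparameters"]
        hp_d["filter_widths"] = tuple(hp_d["filter_widths"])
        hp = Hyperparameters(**hp_d)
        if meta["kind"] == "cnn":
            model = CnnClassifier(emb, hp, meta["seed"])
            for w in hp.filter_widths:
                model.conv_w[w] = data[f"conv_w_{w}"]
                model.conv_b[w] = data[f"conv_b_{w}"]
            model.dense_w = data["dense_w"]
            model.dense_b = data["dense_b"]
            return model
        model = LinearClassifier(emb, hp, meta["seed"])
        lr = model._lr
        lr.coef_ = data["coef"]
        lr.intercept_ = data["intercept"]
        lr.classes_ = data["classes"]
        model._trained_labels = list(data["classes"])
        return model
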