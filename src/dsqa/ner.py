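"""BIO sequence taggers for supplement/disease/medication mentions.

Two models over the nine BIO tags ({B,I} x {DS, DIS, MED, MISC} plus O):

* a first-order hidden Markov model with add-k smoothed count estimates and
  Viterbi decoding — the generative baseline;
* a linear-chain conditional random field (the selected model): binary
  indicator features over a +/-2 token window, trained by penalized maximum
  likelihood (L-BFGS over forward-backward gradients), decoded with the same
  constrained Viterbi.

Both decoders share one structural constraint: a transition that would break
BIO validity (such as O -> I-DS, or starting a sentence on an I tag) scores
minus infinity, so emitted sequences are valid by construction.  Tags never
seen in training are likewise excluded, so a corpus with no I tags can never
emit one.

Evaluation is entity-level exact match (span boundaries and label both
correct) — the stricter of the two common conventions — with token accuracy
reported alongside.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass

import numpy as np
import scipy.optimize
import scipy.sparse as sp

from .corpus import BIO_TAGS, TaggedSequence

N_TAGS = len(BIO_TAGS)
_TAG_INDEX = {t: i for i, t in enumerate(BIO_TAGS)}
NEG_INF = -1e30  # effective minus infinity that stays finite in arithmetic


def _valid_transition(prev: str, cur: str) -> bool:
    if cur.startswith("I-"):
        return prev[2:] == cur[2:] and prev[0] in "BI"
    return True


def _valid_start(tag: str) -> bool:
    return not tag.startswith("I-")


#: (9, 9) boolean mask of BIO-legal transitions, row = previous tag.
TRANSITION_MASK = np.array(
    [[_valid_transition(p, c) for c in BIO_TAGS] for p in BIO_TAGS]
)
START_MASK = np.array([_valid_start(t) for t in BIO_TAGS])


# ---------------------------------------------------------------------------
# Features


def _shape(token: str) -> str:
    out = []
    for ch in token:
        cls = "X" if ch.isupper() else "x" if ch.islower() else "d" if ch.isdigit() else ch
        if not out or out[-1] != cls:
            out.append(cls)
    return "".join(out)


def featurize_tokens(tokens: list[str], position: int) -> dict[str, float]:
    """Binary indicator features for one token position.

    Covers the token and its neighbors at offsets -2..+2: identity, lowercase
    form, 2- and 3-character prefixes and suffixes, collapsed word shape,
    is-digit and is-title flags; out-of-range offsets contribute BOS/EOS
    markers.  Deterministic function of the token window.
    """
    if not 0 <= position < len(tokens):
        raise IndexError(f"position {position} out of range for {len(tokens)} tokens")
    feats: dict[str, float] = {"bias": 1.0}
    for off in (-2, -1, 0, 1, 2):
        j = position + off
        if j < 0:
            feats[f"{off}:BOS"] = 1.0
            continue
        if j >= len(tokens):
            feats[f"{off}:EOS"] = 1.0
            continue
        tok = tokens[j]
        low = tok.lower()
        feats[f"{off}:word={tok}"] = 1.0
        feats[f"{off}:lower={low}"] = 1.0
        feats[f"{off}:shape={_shape(tok)}"] = 1.0
        if tok.istitle():
            feats[f"{off}:istitle"] = 1.0
        if tok.isdigit():
            feats[f"{off}:isdigit"] = 1.0
        feats[f"{off}:pre2={low[:2]}"] = 1.0
        feats[f"{off}:pre3={low[:3]}"] = 1.0
        feats[f"{off}:suf2={low[-2:]}"] = 1.0
        feats[f"{off}:suf3={low[-3:]}"] = 1.0
    return feats


# ---------------------------------------------------------------------------
# Shared Viterbi


def _viterbi(emission: np.ndarray, init: np.ndarray, trans: np.ndarray) -> list[int]:
    """Argmax path under per-token scores + transition scores, log domain.

    Ties resolve to the lowest tag index (canonical tag order).
    """
    T = emission.shape[0]
    delta = init + emission[0]
    back = np.zeros((T, N_TAGS), dtype=int)
    for t in range(1, T):
        cand = delta[:, None] + trans  # (prev, cur)
        back[t] = cand.argmax(axis=0)
        delta = cand.max(axis=0) + emission[t]
    path = [int(delta.argmax())]
    for t in range(T - 1, 0, -1):
        path.append(int(back[t, path[-1]]))
    return path[::-1]


# ---------------------------------------------------------------------------
# HMM


@dataclass
class HmmModel:
    """Count-based first-order HMM over the BIO tag set.

    ``init``/``trans`` are log probabilities with structural zeros (NEG_INF)
    for BIO-invalid or never-observed transitions; emissions use add-k
    smoothing with a single shared unknown-token column.
    """

    init: np.ndarray                      # (9,) log P(y_0)
    trans: np.ndarray                     # (9, 9) log P(y_t | y_{t-1})
    emissions: dict[str, np.ndarray]      # token -> (9,) log P(token | tag)
    unk: np.ndarray                       # (9,) log P(UNK | tag)
    k: float

    def emission_scores(self, tokens: list[str]) -> np.ndarray:
        return np.array([self.emissions.get(t, self.unk) for t in tokens])


def train_hmm(train: list[TaggedSequence], k: float = 0.01) -> HmmModel:
    """Maximum-likelihood HMM with add-k smoothing.

    Smoothing mass is spread only over tags observed in training and over
    BIO-valid transitions; everything else keeps probability exactly zero.
    """
    if not train:
        raise ValueError("empty training set")
    if k <= 0:
        raise ValueError("smoothing constant k must be positive")

    seen = sorted({t for seq in train for t in seq.tags}, key=_TAG_INDEX.get)
    seen_idx = np.array([_TAG_INDEX[t] for t in seen])
    active = np.zeros(N_TAGS, dtype=bool)
    active[seen_idx] = True

    init_c = np.zeros(N_TAGS)
    trans_c = np.zeros((N_TAGS, N_TAGS))
    emit_c: dict[str, np.ndarray] = {}
    tag_c = np.zeros(N_TAGS)
    for seq in train:
        idx = [_TAG_INDEX[t] for t in seq.tags]
        init_c[idx[0]] += 1
        for a, b in zip(idx, idx[1:]):
            trans_c[a, b] += 1
        for tok, i in zip(seq.tokens, idx):
            emit_c.setdefault(tok, np.zeros(N_TAGS))[i] += 1
            tag_c[i] += 1

    start_ok = active & START_MASK
    init_p = np.where(start_ok, init_c + k, 0.0)
    init_p /= init_p.sum()

    trans_ok = TRANSITION_MASK & active[None, :] & active[:, None]
    trans_p = np.where(trans_ok, trans_c + k, 0.0)
    row_sums = trans_p.sum(axis=1, keepdims=True)
    np.divide(trans_p, row_sums, out=trans_p, where=row_sums > 0)

    V = len(emit_c)
    denom = np.where(active, tag_c + k * (V + 1), 1.0)
    emissions = {
        tok: np.where(active, np.log(np.maximum((c + k) / denom, 1e-300)), NEG_INF)
        for tok, c in ((t, np.where(active, c, 0.0)) for t, c in emit_c.items())
    }
    unk = np.where(active, np.log(k / denom), NEG_INF)

    with np.errstate(divide="ignore"):
        log_init = np.where(init_p > 0, np.log(np.maximum(init_p, 1e-300)), NEG_INF)
        log_trans = np.where(trans_p > 0, np.log(np.maximum(trans_p, 1e-300)), NEG_INF)
    return HmmModel(init=log_init, trans=log_trans, emissions=emissions, unk=unk, k=k)


def viterbi_decode(model: HmmModel, tokens: list[str]) -> TaggedSequence:
    """Most probable valid BIO tag sequence for ``tokens`` under ``model``."""
    if not tokens:
        raise ValueError("empty token sequence")
    path = _viterbi(model.emission_scores(tokens), model.init, model.trans)
    return TaggedSequence(tuple(tokens), tuple(BIO_TAGS[i] for i in path))


# ---------------------------------------------------------------------------
# CRF


class CrfModel:
    """Linear-chain CRF with indicator features and L2 penalty.

    Scoring: sum over positions of the active feature weights for the
    position's tag, plus start weights and tag-bigram transition weights.
    Decoding is constrained Viterbi (BIO-invalid moves and unseen tags score
    minus infinity), so outputs are always valid sequences.
    """

    def __init__(self, feature_index: dict[str, int], active: np.ndarray,
                 weights: np.ndarray, init_w: np.ndarray, trans_w: np.ndarray,
                 l2: float, seed: int):
        self.feature_index = feature_index
        self.active = active            # (9,) bool: tags seen in training
        self.weights = weights          # (n_feat, 9)
        self.init_w = init_w            # (9,)
        self.trans_w = trans_w          # (9, 9)
        self.l2 = l2
        self.seed = seed

    def _emission(self, tokens: list[str]) -> np.ndarray:
        em = np.zeros((len(tokens), N_TAGS))
        for t in range(len(tokens)):
            for f in featurize_tokens(tokens, t):
                j = self.feature_index.get(f)
                if j is not None:
                    em[t] += self.weights[j]
        return em

    def predict_tags(self, tokens: list[str]) -> TaggedSequence:
        if not tokens:
            raise ValueError("empty token sequence")
        em = self._emission(tokens)
        mask = np.where(self.active & START_MASK, 0.0, NEG_INF)
        init = self.init_w + mask
        tmask = np.where(
            TRANSITION_MASK & self.active[None, :] & self.active[:, None], 0.0, NEG_INF
        )
        trans = self.trans_w + tmask
        path = _viterbi(em, init, trans)
        return TaggedSequence(tuple(tokens), tuple(BIO_TAGS[i] for i in path))


def _lse(v: np.ndarray, axis: int) -> np.ndarray:
    m = v.max(axis=axis, keepdims=True)
    return (m + np.log(np.exp(v - m).sum(axis=axis, keepdims=True))).squeeze(axis)


def _crf_nll_grad(theta, X, buckets, n_feat, l2):
    """Negative log likelihood and gradient.

    Sentences are bucketed by length so forward-backward runs batched:
    each bucket holds token-position and gold-tag matrices of shape (B, T).
    """
    W = theta[: n_feat * N_TAGS].reshape(n_feat, N_TAGS)
    init_w = theta[n_feat * N_TAGS : n_feat * N_TAGS + N_TAGS]
    trans_w = theta[n_feat * N_TAGS + N_TAGS :].reshape(N_TAGS, N_TAGS)

    em_all = X @ W  # (total_tokens, 9)
    marg = np.zeros_like(em_all)
    g_init = np.zeros(N_TAGS)
    g_trans = np.zeros((N_TAGS, N_TAGS))
    nll = 0.0

    for P, G in buckets:  # P, G: (B, T) position / gold-tag matrices
        B, T = P.shape
        em = em_all[P]  # (B, T, 9)
        alpha = np.empty((T, B, N_TAGS))
        alpha[0] = init_w + em[:, 0]
        for t in range(1, T):
            v = alpha[t - 1][:, :, None] + trans_w[None]  # (B, prev, cur)
            alpha[t] = em[:, t] + _lse(v, axis=1)
        logZ = _lse(alpha[T - 1], axis=1)  # (B,)
        beta = np.zeros((T, B, N_TAGS))
        for t in range(T - 2, -1, -1):
            v = trans_w[None] + (em[:, t + 1] + beta[t + 1])[:, None, :]
            beta[t] = _lse(v, axis=2)

        mu = np.exp(alpha + beta - logZ[None, :, None])  # (T, B, 9)
        mu /= mu.sum(axis=2, keepdims=True)
        marg[P.T.ravel()] = mu.reshape(T * B, N_TAGS)
        marg[P.ravel(), G.ravel()] -= 1.0

        score = init_w[G[:, 0]].sum() + np.take_along_axis(em, G[:, :, None], 2).sum()
        if T > 1:
            score += trans_w[G[:, :-1], G[:, 1:]].sum()
        nll += logZ.sum() - score

        g_init += mu[0].sum(axis=0)
        np.subtract.at(g_init, G[:, 0], 1.0)
        for t in range(1, T):
            pair = (
                alpha[t - 1][:, :, None]
                + trans_w[None]
                + (em[:, t] + beta[t])[:, None, :]
                - logZ[:, None, None]
            )
            pm = np.exp(pair)
            pm /= pm.sum(axis=(1, 2), keepdims=True)
            g_trans += pm.sum(axis=0)
            np.subtract.at(g_trans, (G[:, t - 1], G[:, t]), 1.0)

    gW = X.T @ marg + l2 * W
    g_init += l2 * init_w
    g_trans += l2 * trans_w
    nll += 0.5 * l2 * (np.sum(W * W) + np.sum(init_w**2) + np.sum(trans_w**2))
    grad = np.concatenate([gW.ravel(), g_init, g_trans.ravel()])
    return nll, grad


def train_crf(
    train: list[TaggedSequence],
    l2: float = 0.1,
    max_iterations: int = 100,
    seed: int = 0,
) -> CrfModel:
    """Fit the CRF by L-BFGS from a zero start (deterministic given data)."""
    if not train:
        raise ValueError("empty training set")

    feature_index: dict[str, int] = {}
    rows, cols = [], []
    gold_list: list[int] = []
    positions: list[list[int]] = []
    pos = 0
    for seq in train:
        sent_pos = []
        for t, (tok, tag) in enumerate(zip(seq.tokens, seq.tags)):
            for f in featurize_tokens(list(seq.tokens), t):
                j = feature_index.setdefault(f, len(feature_index))
                rows.append(pos)
                cols.append(j)
            gold_list.append(_TAG_INDEX[tag])
            sent_pos.append(pos)
            pos += 1
        positions.append(sent_pos)

    n_feat = len(feature_index)
    X = sp.csr_matrix(
        (np.ones(len(rows)), (rows, cols)), shape=(pos, n_feat)
    )
    gold = np.array(gold_list)
    active = np.zeros(N_TAGS, dtype=bool)
    active[np.unique(gold)] = True

    # bucket sentences by length for batched forward-backward
    by_len: dict[int, list[list[int]]] = {}
    for sent_pos in positions:
        by_len.setdefault(len(sent_pos), []).append(sent_pos)
    buckets = [
        (np.array(group), np.array([[gold[p] for p in s] for s in group]))
        for _, group in sorted(by_len.items())
    ]

    theta0 = np.zeros(n_feat * N_TAGS + N_TAGS + N_TAGS * N_TAGS)
    res = scipy.optimize.minimize(
        _crf_nll_grad,
        theta0,
        args=(X, buckets, n_feat, l2),
        method="L-BFGS-B",
        jac=True,
        options={"maxiter": max_iterations, "ftol": 1e-9, "gtol": 1e-6},
    )
    theta = res.x
    W = theta[: n_feat * N_TAGS].reshape(n_feat, N_TAGS)
    init_w = theta[n_feat * N_TAGS : n_feat * N_TAGS + N_TAGS]
    trans_w = theta[n_feat * N_TAGS + N_TAGS :].reshape(N_TAGS, N_TAGS)
    return CrfModel(feature_index, active, W, init_w, trans_w, l2, seed)


# ---------------------------------------------------------------------------
# Span decoding and evaluation


def repair_bio(tags: list[str]) -> list[str]:
    """Promote dangling I tags to B (lossless, deterministic)."""
    out = list(tags)
    prev = "O"
    for i, tag in enumerate(out):
        if tag.startswith("I-") and prev[2:] != tag[2:]:
            out[i] = "B-" + tag[2:]
        prev = out[i]
    return out


def tag_spans(tags: list[str]) -> list[tuple[int, int, str]]:
    """(start, end, label) token index spans of maximal B/I runs (repaired)."""
    tags = repair_bio(list(tags))
    spans = []
    i = 0
    while i < len(tags):
        if tags[i].startswith("B-"):
            label = tags[i][2:]
            j = i + 1
            while j < len(tags) and tags[j] == f"I-{label}":
                j += 1
            spans.append((i, j, label))
            i = j
        else:
            i += 1
    return spans


def bio_to_spans(tokens, tags=None) -> list[tuple[str, str]]:
    """Decode a BIO tagging into (surface, label) entities.

    Accepts a :class:`TaggedSequence` or separate token/tag lists; invalid
    sequences are repaired by promoting dangling I tags to B.  Surfaces are
    space-joined tokens; inverse of the corpus BIO projection on valid input.
    """
    if tags is None:
        tokens, tags = list(tokens.tokens), list(tokens.tags)
    return [
        (" ".join(tokens[i:j]), label) for i, j, label in tag_spans(list(tags))
    ]


def _decode(model, tokens: list[str]) -> TaggedSequence:
    if isinstance(model, HmmModel):
        return viterbi_decode(model, tokens)
    return model.predict_tags(tokens)


def evaluate_tagger(model, test: list[TaggedSequence]) -> dict:
    """Entity-level exact-match P/R/F1 per label + support-weighted, token accuracy."""
    if not test:
        raise ValueError("empty test set")
    gold_pred: list[tuple[list, list]] = []
    correct_tok = total_tok = 0
    for seq in test:
        pred = _decode(model, list(seq.tokens))
        correct_tok += sum(a == b for a, b in zip(seq.tags, pred.tags))
        total_tok += len(seq.tags)
        gold_pred.append((tag_spans(list(seq.tags)), tag_spans(list(pred.tags))))
    return span_report(gold_pred) | {"token_accuracy": correct_tok / total_tok}


def span_report(gold_pred: list[tuple[list, list]]) -> dict:
    """Entity-level scores from per-sentence (gold spans, predicted spans)."""
    labels = sorted({lab for g, _ in gold_pred for _, _, lab in g}
                    | {lab for _, p in gold_pred for _, _, lab in p})
    tp = {lab: 0 for lab in labels}
    n_gold = {lab: 0 for lab in labels}
    n_pred = {lab: 0 for lab in labels}
    for g, p in gold_pred:
        gset = set(g)
        for span in p:
            n_pred[span[2]] += 1
            if span in gset:
                tp[span[2]] += 1
        for span in g:
            n_gold[span[2]] += 1
    per_class = {}
    for lab in labels:
        prec = tp[lab] / n_pred[lab] if n_pred[lab] else 0.0
        rec = tp[lab] / n_gold[lab] if n_gold[lab] else 0.0
        f1 = 2 * prec * rec / (prec + rec) if prec + rec else 0.0
        per_class[lab] = {
            "precision": prec, "recall": rec, "f1": f1, "support": n_gold[lab]
        }
    support = sum(n_gold.values())
    weighted = {"precision": 0.0, "recall": 0.0, "f1": 0.0}
    if support:
        for lab in labels:
            w = n_gold[lab] / support
            for key in weighted:
                weighted[key] += w * per_class[lab][key]
    return {"per_class": per_class, "weighted": weighted, "n_entities": support}


# ---------------------------------------------------------------------------
# Serialization


def save_tagger(model, path) -> None:
    if isinstance(model, HmmModel):
        tokens = sorted(model.emissions)
        arrays = {
            "kind": np.frombuffer(b"hmm", dtype=np.uint8),
            "init": model.init,
            "trans": model.trans,
            "unk": model.unk,
            "k": np.array([model.k]),
            "emit": np.array([model.emissions[t] for t in tokens]),
            "tokens": np.frombuffer(json.dumps(tokens).encode(), dtype=np.uint8),
        }
    else:
        feats = sorted(model.feature_index, key=model.feature_index.get)
        arrays = {
            "kind": np.frombuffer(b"crf", dtype=np.uint8),
            "weights": model.weights,
            "init_w": model.init_w,
            "trans_w": model.trans_w,
            "active": model.active,
            "l2": np.array([model.l2]),
            "seed": np.array([model.seed]),
            "feats": np.frombuffer(json.dumps(feats).encode(), dtype=np.uint8),
        }
    with open(path, "wb") as fh:
        np.savez(fh, **arrays)


def load_tagger(path):
    with np.load(path, allow_pickle=False) as data:
        kind = bytes(data["kind"]).decode()
        if kind == "hmm":
            tokens = json.loads(bytes(data["tokens"]).decode())
            emit = data["emit"]
            return HmmModel(
                init=data["init"],
                trans=data["trans"],
                emissions={t: emit[i] for i, t in enumerate(tokens)},
                unk=data["unk"],
                k=float(data["k"][0]),
            )
        feats = json.loads(bytes(data["feats"]).decode())
        return CrfModel(
            feature_index={f: i for i, f in enumerate(feats)},
            active=data["active"],
            weights=data["weights"],
            init_w=data["init_w"],
            trans_w=data["trans_w"],
            l2=float(data["l2"][0]),
            seed=int(data["seed"][0]),
        )
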