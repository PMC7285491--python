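"""Hierarchical encoder models for per-criterion pass/fail classification.

Architecture (HEA): frozen token embeddings → bidirectional GRU sentence
encoder (SentEncoder) → bidirectional GRU document encoder (DocEncoder) →
global-query attention over the per-sentence joined states → affine + softmax
classifier. The HE variant is identical except the attention layer is
replaced by mean pooling of the DocEncoder outputs.

GRU cell, per step t (σ sigmoid, φ tanh or ReLU, ⊙ elementwise)::

    z_t = σ(W_z w_t + U_z h_{t-1} + b_z)          update gate
    r_t = σ(W_r w_t + U_r h_{t-1} + b_r)          reset gate
    h~_t = φ(W_h w_t + r_t ⊙ (U_h h_{t-1}) + b_h)  candidate state
    h_t = (1 - z_t) ⊙ h~_t + z_t ⊙ h_{t-1}

Attention over DocEncoder outputs O = [l_1 .. l_T] with trainable query q::

    additive score:    s_i = qᵀ tanh(W_ql l_i)
    scaled dot score:  s_i = qᵀ l_i / sqrt(D_l)
    α = softmax(s),    z = Σ_i α_i l_i

This module holds the parameter containers, the single-document numpy
forward path (used for prediction and explanation and as the reference the
batched training path is tested against), seeded initialization, and
checkpoint serialization.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np

from .corpus_io import Article
from .embeddings import EmbedderConfig, EmbeddedSentence, make_embedder
from .errors import (
    EmptySequenceError,
    NumericalError,
    ShapeError,
)

CHECKPOINT_VERSION = 1


# ---------------------------------------------------------------------------
# Parameter containers


@dataclass
class GruParameters:
    """One direction of one encoder level. Input maps are (D_h, D_w),
    recurrent maps (D_h, D_h), biases (D_h,)."""

    W_z: np.ndarray
    W_r: np.ndarray
    W_h: np.ndarray
    U_z: np.ndarray
    U_r: np.ndarray
    U_h: np.ndarray
    b_z: np.ndarray
    b_r: np.ndarray
    b_h: np.ndarray
    phi: str = "tanh"  # "tanh" | "relu"

    @property
    def d_h(self) -> int:
        return self.W_z.shape[0]

    @property
    def d_in(self) -> int:
        return self.W_z.shape[1]

    def arrays(self):
        return [self.W_z, self.W_r, self.W_h, self.U_z, self.U_r, self.U_h,
                self.b_z, self.b_r, self.b_h]


@dataclass
class AttentionParameters:
    query: np.ndarray                 # (D_q,)
    map: np.ndarray | None = None     # (D_q, D_l), additive variant only
    score_fn: str = "scaled_dot"      # "scaled_dot" | "additive"

    def arrays(self):
        return [self.query] if self.map is None else [self.query, self.map]


@dataclass
class HeaParameters:
    sent_fwd: GruParameters
    sent_bwd: GruParameters
    doc_fwd: GruParameters
    doc_bwd: GruParameters
    classifier_W: np.ndarray          # (2, D_z)
    classifier_b: np.ndarray          # (2,)
    attention: AttentionParameters | None = None  # None for the HE variant
    join_sentence: str = "concat"     # "concat" | "sum"
    join_document: str = "concat"
    dropout_p: float = 0.0

    def arrays(self) -> list[np.ndarray]:
        out = (self.sent_fwd.arrays() + self.sent_bwd.arrays()
               + self.doc_fwd.arrays() + self.doc_bwd.arrays()
               + [self.classifier_W, self.classifier_b])
        if self.attention is not None:
            out += self.attention.arrays()
        return out

    def copy(self) -> "HeaParameters":
        def g(p: GruParameters) -> GruParameters:
            return GruParameters(*(a.copy() for a in p.arrays()), phi=p.phi)

        att = None
        if self.attention is not None:
            att = AttentionParameters(
                self.attention.query.copy(),
                None if self.attention.map is None else self.attention.map.copy(),
                self.attention.score_fn,
            )
        return HeaParameters(
            g(self.sent_fwd), g(self.sent_bwd), g(self.doc_fwd), g(self.doc_bwd),
            self.classifier_W.copy(), self.classifier_b.copy(), att,
            self.join_sentence, self.join_document, self.dropout_p,
        )

    def norm_sq(self) -> float:
        return float(sum((a ** 2).sum() for a in self.arrays()))


@dataclass(frozen=True)
class ModelConfig:
    """Everything needed to build a fresh parameter set."""

    d_w: int = 16          # token embedding dimension
    d_h_sent: int = 16     # sentence-encoder hidden size per direction
    d_h_doc: int = 16      # document-encoder hidden size per direction
    join_sentence: str = "concat"
    join_document: str = "concat"
    variant: str = "HEA"   # "HEA" | "HE"
    score_fn: str = "scaled_dot"
    d_q: int | None = None  # additive-attention query size (defaults to D_l)
    phi: str = "tanh"
    dropout_p: float = 0.0
    seed: int = 0

    @property
    def d_sent(self) -> int:
        return 2 * self.d_h_sent if self.join_sentence == "concat" else self.d_h_sent

    @property
    def d_l(self) -> int:
        return 2 * self.d_h_doc if self.join_document == "concat" else self.d_h_doc


def _glorot(rng: np.random.Generator, shape: tuple[int, ...]) -> np.ndarray:
    fan_in = shape[-1] if len(shape) > 1 else shape[0]
    fan_out = shape[0]
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape)


def _init_gru(rng: np.random.Generator, d_h: int, d_in: int, phi: str) -> GruParameters:
    return GruParameters(
        W_z=_glorot(rng, (d_h, d_in)), W_r=_glorot(rng, (d_h, d_in)),
        W_h=_glorot(rng, (d_h, d_in)),
        U_z=_glorot(rng, (d_h, d_h)), U_r=_glorot(rng, (d_h, d_h)),
        U_h=_glorot(rng, (d_h, d_h)),
        b_z=np.zeros(d_h), b_r=np.zeros(d_h), b_h=np.zeros(d_h),
        phi=phi,
    )


def init_parameters(config: ModelConfig) -> HeaParameters:
    """Seeded Glorot-uniform weights, zero biases, zero initial states."""
    rng = np.random.default_rng(config.seed)
    sent_fwd = _init_gru(rng, config.d_h_sent, config.d_w, config.phi)
    sent_bwd = _init_gru(rng, config.d_h_sent, config.d_w, config.phi)
    doc_fwd = _init_gru(rng, config.d_h_doc, config.d_sent, config.phi)
    doc_bwd = _init_gru(rng, config.d_h_doc, config.d_sent, config.phi)
    d_l = config.d_l
    attention = None
    if config.variant == "HEA":
        if config.score_fn == "scaled_dot":
            attention = AttentionParameters(_glorot(rng, (d_l,)), None, "scaled_dot")
        else:
            d_q = config.d_q or d_l
            attention = AttentionParameters(
                _glorot(rng, (d_q,)), _glorot(rng, (d_q, d_l)), "additive"
            )
    return HeaParameters(
        sent_fwd=sent_fwd, sent_bwd=sent_bwd, doc_fwd=doc_fwd, doc_bwd=doc_bwd,
        classifier_W=_glorot(rng, (2, d_l)), classifier_b=np.zeros(2),
        attention=attention, join_sentence=config.join_sentence,
        join_document=config.join_document, dropout_p=config.dropout_p,
    )


# ---------------------------------------------------------------------------
# Single-instance forward path (plain numpy)


def _activation(name: str):
    if name == "tanh":
        return np.tanh
    if name == "relu":
        return lambda x: np.maximum(x, 0.0)
    raise ValueError(f"unknown activation {name!r}")


def gru_step(w_t: np.ndarray, h_prev: np.ndarray, params: GruParameters) -> np.ndarray:
    """One GRU update following the gate equations in the module docstring."""
    w_t = np.asarray(w_t, dtype=float)
    h_prev = np.asarray(h_prev, dtype=float)
    if w_t.shape != (params.d_in,) or h_prev.shape != (params.d_h,):
        raise ShapeError(
            f"gru_step got input {w_t.shape}, state {h_prev.shape}; "
            f"expected ({params.d_in},), ({params.d_h},)"
        )
    phi = _activation(params.phi)
    sig = lambda x: 1.0 / (1.0 + np.exp(-x))
    z = sig(params.W_z @ w_t + params.U_z @ h_prev + params.b_z)
    r = sig(params.W_r @ w_t + params.U_r @ h_prev + params.b_r)
    h_tilde = phi(params.W_h @ w_t + r * (params.U_h @ h_prev) + params.b_h)
    return (1.0 - z) * h_tilde + z * h_prev


def _run_gru(seq: np.ndarray, params: GruParameters) -> list[np.ndarray]:
    h = np.zeros(params.d_h)
    states = []
    for t in range(seq.shape[0]):
        h = gru_step(seq[t], h, params)
        states.append(h)
    return states


def _join(a: np.ndarray, b: np.ndarray, how: str) -> np.ndarray:
    if how == "concat":
        return np.concatenate([a, b])
    if how == "sum":
        return a + b
    raise ValueError(f"unknown join {how!r}")


def encode_sentence(
    emb: EmbeddedSentence | np.ndarray,
    fwd: GruParameters,
    bwd: GruParameters,
    join: str = "concat",
) -> np.ndarray:
    """Bidirectional GRU over a sentence's token vectors; the sentence vector
    joins the final forward state (after the last token) with the final
    backward state (after consuming back to the first token)."""
    vectors = emb.vectors if isinstance(emb, EmbeddedSentence) else np.asarray(emb)
    if vectors.shape[0] == 0:
        raise EmptySequenceError("cannot encode a zero-length sentence")
    h_fwd = _run_gru(vectors, fwd)[-1]
    h_bwd = _run_gru(vectors[::-1], bwd)[-1]
    return _join(h_fwd, h_bwd, join)


def encode_document(
    sent_vectors: Sequence[np.ndarray],
    fwd: GruParameters,
    bwd: GruParameters,
    join: str = "concat",
) -> list[np.ndarray]:
    """Bidirectional GRU over the sentence-vector sequence. Unlike the
    sentence level, forward and backward states are joined *per position*,
    yielding one vector l_i per sentence."""
    if len(sent_vectors) == 0:
        raise EmptySequenceError("cannot encode an empty document")
    seq = np.stack(sent_vectors)
    states_fwd = _run_gru(seq, fwd)
    states_bwd = _run_gru(seq[::-1], bwd)[::-1]
    return [_join(f, b, join) for f, b in zip(states_fwd, states_bwd)]


def attention_score(q: np.ndarray, l: np.ndarray, params: AttentionParameters) -> float:
    q = np.asarray(q, dtype=float)
    l = np.asarray(l, dtype=float)
    if params.score_fn == "scaled_dot":
        if q.shape != l.shape:
            raise ShapeError("scaled_dot requires D_q == D_l")
        return float(q @ l / np.sqrt(l.shape[0]))
    if params.score_fn == "additive":
        if params.map is None or params.map.shape != (q.shape[0], l.shape[0]):
            raise ShapeError("additive scoring needs a (D_q, D_l) map")
        return float(q @ np.tanh(params.map @ l))
    raise ValueError(f"unknown score_fn {params.score_fn!r}")


def attention_weights(scores: np.ndarray) -> np.ndarray:
    """Stable softmax over the score vector; weights sum to one."""
    scores = np.asarray(scores, dtype=float)
    if scores.size == 0:
        raise EmptySequenceError("no scores to normalize")
    if not np.all(np.isfinite(scores)):
        raise NumericalError("non-finite attention score")
    e = np.exp(scores - scores.max())
    return e / e.sum()


def document_vector(O: Sequence[np.ndarray], alpha: np.ndarray) -> np.ndarray:
    """z = Σ_i α_i l_i."""
    if len(O) != len(alpha):
        raise ShapeError(f"{len(alpha)} weights for {len(O)} vectors")
    return np.einsum("t,td->d", np.asarray(alpha, dtype=float), np.stack(O))


def mean_pool(O: Sequence[np.ndarray]) -> np.ndarray:
    """The HE variant's pooling: average of the DocEncoder outputs.

    Implemented as the uniform-weight case of :func:`document_vector` so
    that HE is bit-identical to HEA under uniform attention."""
    if len(O) == 0:
        raise EmptySequenceError("cannot mean-pool an empty sequence")
    return document_vector(O, np.full(len(O), 1.0 / len(O)))


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max()
    e = np.exp(z)
    return e / e.sum()


def classify(z: np.ndarray, W: np.ndarray, b: np.ndarray) -> np.ndarray:
    """softmax(W z + b) — probability distribution over {fail, pass}."""
    z = np.asarray(z, dtype=float)
    if W.shape[1] != z.shape[0] or b.shape[0] != W.shape[0]:
        raise ShapeError(
            f"classifier shapes W{W.shape}, b{b.shape} vs z{z.shape}"
        )
    return softmax(W @ z + b)


# ---------------------------------------------------------------------------
# Results of a forward pass


@dataclass(frozen=True)
class Prediction:
    doc_id: str
    criterion: str
    probs: np.ndarray  # (P(fail), P(pass))

    @property
    def predicted_label(self) -> int:
        return int(np.argmax(self.probs))

    @property
    def confidence(self) -> float:
        return float(self.probs.max())


@dataclass(frozen=True)
class DocumentEncoding:
    O: np.ndarray                 # (T_Doc, D_l)
    alpha: np.ndarray | None      # attention weights; None for HE
    z: np.ndarray                 # document vector (D_z,)


def forward(
    article: Article,
    params: HeaParameters,
    embedder_config: EmbedderConfig | None = None,
    variant: str = "HEA",
    mode: str = "eval",
    criterion: str = "",
    embedder=None,
    rng: np.random.Generator | None = None,
) -> tuple[Prediction, DocumentEncoding]:
    """Full composition for one document: embed → SentEncoder → DocEncoder →
    attention / mean-pool → classify. Eval mode is deterministic; train mode
    applies dropout to sentence vectors and to z (rng required)."""
    if not article.sentences:
        raise EmptySequenceError(f"article {article.doc_id} has no sentences")
    embedder = embedder or make_embedder(embedder_config or EmbedderConfig())
    train = mode == "train"
    if train and rng is None:
        rng = np.random.default_rng(0)

    sent_vecs = []
    for sent in article.sentences:
        emb = embedder.embed_tokens(sent.tokens)
        sv = encode_sentence(emb, params.sent_fwd, params.sent_bwd, params.join_sentence)
        if train and params.dropout_p > 0:
            keep = (rng.random(sv.shape) >= params.dropout_p) / (1 - params.dropout_p)
            sv = sv * keep
        sent_vecs.append(sv)

    O = encode_document(sent_vecs, params.doc_fwd, params.doc_bwd, params.join_document)
    if variant == "HEA":
        if params.attention is None:
            raise ShapeError("HEA forward requires attention parameters")
        scores = np.array(
            [attention_score(params.attention.query, l, params.attention) for l in O]
        )
        alpha = attention_weights(scores)
        z = document_vector(O, alpha)
    elif variant == "HE":
        alpha = None
        z = mean_pool(O)
    else:
        raise ValueError(f"unknown variant {variant!r}")

    if train and params.dropout_p > 0:
        keep = (rng.random(z.shape) >= params.dropout_p) / (1 - params.dropout_p)
        z = z * keep
    probs = classify(z, params.classifier_W, params.classifier_b)
    return (
        Prediction(article.doc_id, criterion, probs),
        DocumentEncoding(O=np.stack(O), alpha=alpha, z=z),
    )


# ---------------------------------------------------------------------------
# Checkpoint serialization (single .npz with a JSON metadata entry)

_GRU_NAMES = ("sent_fwd", "sent_bwd", "doc_fwd", "doc_bwd")
_GRU_FIELDS = ("W_z", "W_r", "W_h", "U_z", "U_r", "U_h", "b_z", "b_r", "b_h")


def save_checkpoint(path: str | Path, params: HeaParameters,
                    metadata: dict | None = None) -> None:
    arrays: dict[str, np.ndarray] = {}
    for name in _GRU_NAMES:
        gru: GruParameters = getattr(params, name)
        for f in _GRU_FIELDS:
            arrays[f"{name}.{f}"] = getattr(gru, f)
    arrays["classifier_W"] = params.classifier_W
    arrays["classifier_b"] = params.classifier_b
    if params.attention is not None:
        arrays["attention.query"] = params.attention.query
        if params.attention.map is not None:
            arrays["attention.map"] = params.attention.map
    meta = {
        "version": CHECKPOINT_VERSION,
        "join_sentence": params.join_sentence,
        "join_document": params.join_document,
        "dropout_p": params.dropout_p,
        "phi": params.sent_fwd.phi,
        "score_fn": None if params.attention is None else params.attention.score_fn,
        "extra": metadata or {},
    }
    arrays["__meta__"] = np.frombuffer(
        json.dumps(meta).encode("utf-8"), dtype=np.uint8
    )
    np.savez(path, **arrays)


def load_checkpoint(path: str | Path) -> tuple[HeaParameters, dict]:
    with np.load(path) as data:
        meta = json.loads(bytes(data["__meta__"]).decode("utf-8"))
        if meta["version"] != CHECKPOINT_VERSION:
            raise ValueError(f"unsupported checkpoint version {meta['version']}")
        grus = {}
        for name in _GRU_NAMES:
            grus[name] = GruParameters(
                *(data[f"{name}.{f}"] for f in _GRU_FIELDS), phi=meta["phi"]
            )
        attention = None
        if "attention.query" in data:
            attention = AttentionParameters(
                data["attention.query"],
                data["attention.map"] if "attention.map" in data else None,
                meta["score_fn"],
            )
        params = HeaParameters(
            sent_fwd=grus["sent_fwd"], sent_bwd=grus["sent_bwd"],
            doc_fwd=grus["doc_fwd"], doc_bwd=grus["doc_bwd"],
            classifier_W=data["classifier_W"], classifier_b=data["classifier_b"],
            attention=attention, join_sentence=meta["join_sentence"],
            join_document=meta["join_document"], dropout_p=meta["dropout_p"],
        )
    return params, meta["extra"]
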