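"""Mini-batched, differentiable forward pass used by the trainer.

Documents in a batch are right-padded to a common sentence count and all
sentences in the batch are right-padded to a common token count, with masks
keeping padded positions inert (GRU states carry through them unchanged and
attention assigns them zero weight). The math is identical to the
single-document path in :mod:`discernet.model`, which the tests assert.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from . import tape
from .model import HeaParameters, GruParameters
from .tape import Tensor


@dataclass
class ParamTensors:
    """Tape leaves wrapping (not copying) a HeaParameters' arrays, so an
    optimizer can update the arrays in place between batches."""

    tensors: dict[str, Tensor]
    order: list[str]

    @classmethod
    def from_params(cls, params: HeaParameters) -> "ParamTensors":
        tensors: dict[str, Tensor] = {}
        for enc in ("sent_fwd", "sent_bwd", "doc_fwd", "doc_bwd"):
            gru: GruParameters = getattr(params, enc)
            for f in ("W_z", "W_r", "W_h", "U_z", "U_r", "U_h", "b_z", "b_r", "b_h"):
                tensors[f"{enc}.{f}"] = tape.parameter(getattr(gru, f))
        tensors["classifier_W"] = tape.parameter(params.classifier_W)
        tensors["classifier_b"] = tape.parameter(params.classifier_b)
        if params.attention is not None:
            tensors["attention.query"] = tape.parameter(params.attention.query)
            if params.attention.map is not None:
                tensors["attention.map"] = tape.parameter(params.attention.map)
        return cls(tensors=tensors, order=sorted(tensors))

    def values(self) -> list[np.ndarray]:
        return [self.tensors[k].value for k in self.order]

    def grads(self) -> list[np.ndarray]:
        out = []
        for k in self.order:
            t = self.tensors[k]
            out.append(t.grad if t.grad is not None else np.zeros_like(t.value))
        return out

    def zero_grads(self) -> None:
        for t in self.tensors.values():
            t.grad = None

    def norm_sq(self) -> float:
        return float(sum((v ** 2).sum() for v in self.values()))


def _phi(name: str):
    return tape.tanh if name == "tanh" else tape.relu


def _gru_sweep(
    x: Tensor,
    mask: np.ndarray,
    pt: ParamTensors,
    prefix: str,
    phi_name: str,
    reverse: bool,
    collect: bool,
) -> tuple[Tensor, list[Tensor]]:
    """Run one GRU direction over x (N, T, D_in). Padded steps (mask 0)
    leave the state untouched, so the final state equals the state after each
    row's last real step. Returns final state and (optionally) per-step states
    in document order."""
    g = lambda f: pt.tensors[f"{prefix}.{f}"]
    n, T, _ = x.value.shape
    d_h = g("b_z").value.shape[0]
    h = tape.constant(np.zeros((n, d_h)))
    phi = _phi(phi_name)
    steps = range(T - 1, -1, -1) if reverse else range(T)
    states: list[Tensor | None] = [None] * T if collect else []
    for t in steps:
        x_t = tape.select_step(x, t)
        z = tape.sigmoid(tape.add(tape.add(tape.matmul_t(x_t, g("W_z")),
                                           tape.matmul_t(h, g("U_z"))), g("b_z")))
        r = tape.sigmoid(tape.add(tape.add(tape.matmul_t(x_t, g("W_r")),
                                           tape.matmul_t(h, g("U_r"))), g("b_r")))
        h_tilde = phi(tape.add(tape.add(tape.matmul_t(x_t, g("W_h")),
                                        tape.mul(r, tape.matmul_t(h, g("U_h")))),
                               g("b_h")))
        h_new = tape.add(tape.mul(tape.scale_add(z, -1.0, 1.0), h_tilde),
                         tape.mul(z, h))
        m = mask[:, t:t + 1]
        h = tape.add(tape.mul(h_new, tape.constant(m)),
                     tape.mul(h, tape.constant(1.0 - m)))
        if collect:
            states[t] = h
    return h, (states if collect else [])


def _join(a: Tensor, b: Tensor, how: str) -> Tensor:
    return tape.concat([a, b], axis=-1) if how == "concat" else tape.add(a, b)


@dataclass
class BatchOutput:
    loss: Tensor            # mean weighted cross-entropy (no L2 term)
    probs: np.ndarray       # (B, 2)
    alpha: np.ndarray | None  # (B, T_doc) attention weights (HEA only)
    doc_mask: np.ndarray    # (B, T_doc)


def batched_forward(
    pt: ParamTensors,
    doc_embeddings: Sequence[Sequence[np.ndarray]],
    labels: np.ndarray,
    weights: np.ndarray,
    join_sentence: str,
    join_document: str,
    variant: str,
    score_fn: str,
    phi: str = "tanh",
    dropout_p: float = 0.0,
    train: bool = False,
    rng: np.random.Generator | None = None,
) -> BatchOutput:
    """Loss and probabilities for a batch of documents, each given as a list
    of per-sentence embedding matrices (T_S x D_w)."""
    if train and dropout_p > 0 and rng is None:
        raise ValueError("train-mode dropout needs an rng")

    # --- flatten sentences across the batch, right-pad tokens
    sent_mats = [m for doc in doc_embeddings for m in doc]
    n_sent = len(sent_mats)
    t_tok = max(m.shape[0] for m in sent_mats)
    d_w = sent_mats[0].shape[1]
    x = np.zeros((n_sent, t_tok, d_w))
    tok_mask = np.zeros((n_sent, t_tok))
    for i, m in enumerate(sent_mats):
        x[i, : m.shape[0]] = m
        tok_mask[i, : m.shape[0]] = 1.0
    x_t = tape.constant(x)

    h_f, _ = _gru_sweep(x_t, tok_mask, pt, "sent_fwd", phi, reverse=False, collect=False)
    h_b, _ = _gru_sweep(x_t, tok_mask, pt, "sent_bwd", phi, reverse=True, collect=False)
    s_vec = _join(h_f, h_b, join_sentence)          # (N_sent, D_s)
    if train and dropout_p > 0:
        s_vec = tape.dropout(s_vec, dropout_p, rng)

    # --- scatter sentence vectors into a (B, T_doc, D_s) grid
    batch = len(doc_embeddings)
    t_doc = max(len(doc) for doc in doc_embeddings)
    grid = -np.ones((batch, t_doc), dtype=int)
    pos = 0
    doc_mask = np.zeros((batch, t_doc))
    for b, doc in enumerate(doc_embeddings):
        grid[b, : len(doc)] = np.arange(pos, pos + len(doc))
        doc_mask[b, : len(doc)] = 1.0
        pos += len(doc)
    seq = tape.gather_rows(s_vec, grid)             # (B, T_doc, D_s)

    _, states_f = _gru_sweep(seq, doc_mask, pt, "doc_fwd", phi, reverse=False, collect=True)
    _, states_b = _gru_sweep(seq, doc_mask, pt, "doc_bwd", phi, reverse=True, collect=True)
    joined = [_join(f, b, join_document) for f, b in zip(states_f, states_b)]
    O = tape.stack(joined, axis=1)                  # (B, T_doc, D_l)
    d_l = O.value.shape[-1]

    alpha_value: np.ndarray | None = None
    if variant == "HEA":
        if score_fn == "scaled_dot":
            scores = tape.dot_last(O, pt.tensors["attention.query"],
                                   scale=1.0 / np.sqrt(d_l))
        else:
            mapped = tape.tanh(tape.matmul_t(O, pt.tensors["attention.map"]))
            scores = tape.dot_last(mapped, pt.tensors["attention.query"])
        alpha = tape.masked_softmax(scores, doc_mask)
        alpha_value = alpha.value
    else:  # HE: uniform weights over real positions == masked mean pooling
        uniform = doc_mask / doc_mask.sum(axis=1, keepdims=True)
        alpha = tape.constant(uniform)
    z = tape.weighted_sum(alpha, O)                 # (B, D_z)
    if train and dropout_p > 0:
        z = tape.dropout(z, dropout_p, rng)

    logits = tape.add(tape.matmul_t(z, pt.tensors["classifier_W"]),
                      pt.tensors["classifier_b"])
    loss, probs = tape.softmax_cross_entropy(logits, labels, weights)
    return BatchOutput(loss=loss, probs=probs, alpha=alpha_value, doc_mask=doc_mask)
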