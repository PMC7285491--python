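"""Token-embedding backends.

Both backends map a tokenized sentence to a ``T_S x D_w`` float matrix with
exactly one row per original token, and both are frozen feature extractors:
nothing downstream ever updates them.

* ``hashed_test`` — deterministic, download-free: each token string is hashed
  to seed a pseudo-random unit vector. Context-free by construction; the
  default for tests and synthetic experiments.
* ``pretrained_lm`` — last-hidden-layer vectors from a pretrained contextual
  language model (generic or biomedical checkpoint chosen by ``model_name``),
  with subword vectors pooled back onto the original tokens. Requires the
  optional ``transformers`` dependency and local model files.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np

from .corpus_io import Sentence
from .errors import AlignmentError, BackendUnavailableError, EmptySequenceError

EMBED_CACHE_VERSION = 1


@dataclass(frozen=True)
class EmbedderConfig:
    backend: str = "hashed_test"  # "hashed_test" | "pretrained_lm"
    model_name: str = ""          # pretrained_lm only
    dim: int = 16                 # D_w (hashed backend; pretrained_lm reports its own)
    subword_pooling: str = "mean"  # "mean" | "first"
    layer_index: int = -1          # hidden layer to read (pretrained_lm)
    seed: int = 0                  # hashed backend salt


@dataclass(frozen=True)
class EmbeddedSentence:
    doc_id: str
    sentence_index: int
    vectors: np.ndarray  # shape (T_S, D_w)


def _hashed_token_vector(token: str, dim: int, seed: int) -> np.ndarray:
    digest = hashlib.blake2b(
        f"{seed}:{token}".encode("utf-8"), digest_size=8
    ).digest()
    rng = np.random.default_rng(int.from_bytes(digest, "little"))
    v = rng.standard_normal(dim)
    return v / np.linalg.norm(v)


class HashedEmbedder:
    """Seeded-hash backend: token string → pseudo-random unit vector.

    The same token always maps to the same vector (for a given dim and seed),
    independent of context — which is exactly what makes it a reproducible,
    download-free stand-in for tests and synthetic benchmarks.
    """

    def __init__(self, config: EmbedderConfig):
        if config.dim <= 0:
            raise ValueError("embedding dim must be positive")
        self.config = config
        self._cache: dict[str, np.ndarray] = {}

    @property
    def dim(self) -> int:
        return self.config.dim

    def token_vector(self, token: str) -> np.ndarray:
        vec = self._cache.get(token)
        if vec is None:
            vec = _hashed_token_vector(token, self.config.dim, self.config.seed)
            self._cache[token] = vec
        return vec

    def embed_tokens(self, tokens: Sequence[str]) -> np.ndarray:
        if not tokens:
            raise EmptySequenceError("cannot embed an empty sentence")
        return np.stack([self.token_vector(t) for t in tokens])


class PretrainedLmEmbedder:
    """Frozen last-layer vectors from a pretrained contextual language model,
    realigned to one vector per original token via subword pooling."""

    def __init__(self, config: EmbedderConfig):
        try:
            import torch  # noqa: F401
            from transformers import AutoModel, AutoTokenizer
        except ImportError as exc:
            raise BackendUnavailableError(
                "pretrained_lm backend needs the optional 'transformers' and "
                "'torch' dependencies"
            ) from exc
        self.config = config
        self._torch = torch
        self._tokenizer = AutoTokenizer.from_pretrained(config.model_name)
        self._model = AutoModel.from_pretrained(config.model_name)
        self._model.eval()
        for p in self._model.parameters():
            p.requires_grad_(False)

    @property
    def dim(self) -> int:
        return int(self._model.config.hidden_size)

    def embed_tokens(self, tokens: Sequence[str]) -> np.ndarray:
        if not tokens:
            raise EmptySequenceError("cannot embed an empty sentence")
        enc = self._tokenizer(
            list(tokens), is_split_into_words=True, return_tensors="pt",
            truncation=True,
        )
        with self._torch.no_grad():
            out = self._model(**enc, output_hidden_states=True)
        hidden = out.hidden_states[self.config.layer_index][0].numpy()
        word_ids = enc.word_ids(0)
        alignment = [w for w in word_ids if w is not None]
        sub = np.stack([hidden[i] for i, w in enumerate(word_ids) if w is not None])
        return subword_realign(sub, alignment, self.config.subword_pooling,
                               n_tokens=len(tokens))


def subword_realign(
    subword_vectors: np.ndarray,
    alignment: Sequence[int],
    pooling: str = "mean",
    n_tokens: int | None = None,
) -> np.ndarray:
    """Collapse subword rows onto original tokens.

    ``alignment[j]`` is the original-token index owning subword row ``j``.
    ``mean`` averages a token's rows; ``first`` keeps the first. Every token
    in ``0..n_tokens-1`` must own at least one subword.
    """
    subword_vectors = np.asarray(subword_vectors, dtype=float)
    alignment = list(alignment)
    if len(alignment) != subword_vectors.shape[0]:
        raise AlignmentError("alignment length != number of subword rows")
    if n_tokens is None:
        n_tokens = max(alignment) + 1 if alignment else 0
    owned: list[list[int]] = [[] for _ in range(n_tokens)]
    for row, tok in enumerate(alignment):
        if not 0 <= tok < n_tokens:
            raise AlignmentError(f"alignment index {tok} out of range")
        owned[tok].append(row)
    out = np.empty((n_tokens, subword_vectors.shape[1]))
    for tok, rows in enumerate(owned):
        if not rows:
            raise AlignmentError(f"original token {tok} owns no subwords")
        if pooling == "mean":
            out[tok] = subword_vectors[rows].mean(axis=0)
        elif pooling == "first":
            out[tok] = subword_vectors[rows[0]]
        else:
            raise ValueError(f"unknown pooling {pooling!r}")
    return out


def make_embedder(config: EmbedderConfig):
    if config.backend == "hashed_test":
        return HashedEmbedder(config)
    if config.backend == "pretrained_lm":
        return PretrainedLmEmbedder(config)
    raise ValueError(f"unknown embedding backend {config.backend!r}")


def embed_sentence(sentence: Sentence, config: EmbedderConfig,
                   embedder=None, doc_id: str = "") -> EmbeddedSentence:
    """Embed one tokenized sentence as a ``T_S x D_w`` matrix (one row per
    token; deterministic for a fixed config)."""
    embedder = embedder or make_embedder(config)
    return EmbeddedSentence(
        doc_id=doc_id,
        sentence_index=sentence.index,
        vectors=embedder.embed_tokens(sentence.tokens),
    )


class EmbeddingCache:
    """Versioned on-disk cache of per-document embedding matrices, keyed by
    (backend, model_name, doc_id). Stored as one ``.npz`` per document."""

    def __init__(self, root: str | Path, config: EmbedderConfig):
        self.root = Path(root)
        self.config = config
        key = f"{config.backend}_{config.model_name or 'none'}_d{config.dim}_s{config.seed}"
        self.dir = self.root / f"v{EMBED_CACHE_VERSION}" / key
        self.dir.mkdir(parents=True, exist_ok=True)

    def _path(self, doc_id: str) -> Path:
        safe = hashlib.blake2b(doc_id.encode(), digest_size=12).hexdigest()
        return self.dir / f"{safe}.npz"

    def get(self, doc_id: str) -> list[np.ndarray] | None:
        path = self._path(doc_id)
        if not path.exists():
            return None
        with np.load(path) as data:
            return [data[k] for k in sorted(data.files, key=lambda s: int(s[1:]))]

    def put(self, doc_id: str, matrices: Sequence[np.ndarray]) -> None:
        arrays = {f"s{i}": m for i, m in enumerate(matrices)}
        np.savez(self._path(doc_id), **arrays)
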