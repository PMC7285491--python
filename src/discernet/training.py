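"""Per-criterion model optimization.

Objective: mean class-weighted cross-entropy over the batch plus an L2
penalty, L(θ) = (1/N) Σ_j w_j · l_j + (λ/2)‖θ‖². One model is trained per
criterion; embeddings stay frozen throughout. Each epoch the validation
F1-macro is recorded and the parameters from the best epoch (earliest on
ties) are returned, not the last.

The optimizer is Adam with gradient-norm clipping; the L2 term enters the
gradients analytically (λθ) rather than through the tape.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
from sklearn.metrics import f1_score

from .batched import ParamTensors, batched_forward
from .corpus_io import Article, ClassWeights, FoldSplit, compute_class_weights
from .errors import ConfigError, DegenerateLabelsError, DivergenceError
from .model import HeaParameters, ModelConfig, init_parameters


@dataclass
class TrainingConfig:
    l2_lambda: float = 0.0
    learning_rate: float = 1e-3
    batch_size: int = 8
    max_epochs: int = 30
    seed: int = 0
    optimizer_name: str = "adam"
    grad_clip: float = 5.0
    class_weights: ClassWeights | None = None  # derived from train split if None

    def __post_init__(self):
        if self.l2_lambda < 0:
            raise ConfigError("l2_lambda must be >= 0")
        if self.max_epochs < 1:
            raise ConfigError("max_epochs must be >= 1")


@dataclass
class EpochRecord:
    epoch: int
    train_loss: float
    val_f1_macro: float


@dataclass
class TrainingTrace:
    records: list[EpochRecord] = field(default_factory=list)
    best_epoch: int = -1
    best_val_f1: float = -1.0

    def note(self, record: EpochRecord) -> bool:
        """Append a record; returns True if it sets a new best (strict
        improvement, so the earliest epoch wins ties)."""
        self.records.append(record)
        if record.val_f1_macro > self.best_val_f1:
            self.best_val_f1 = record.val_f1_macro
            self.best_epoch = record.epoch
            return True
        return False


def example_loss(probs: np.ndarray, true_label: int, weight: float = 1.0) -> float:
    """Weighted cross-entropy for one example: weight · (−log p_true),
    with p_true floored at 1e-12 so the loss is never infinite."""
    p = float(np.asarray(probs)[true_label])
    return weight * -math.log(max(p, 1e-12))


def objective(batch_losses: Sequence[float], theta_norm_sq: float,
              l2_lambda: float, n: int | None = None) -> float:
    """Mean loss plus (λ/2)·‖θ‖²; reduces to the plain mean at λ = 0."""
    losses = list(batch_losses)
    n = n if n is not None else len(losses)
    if n <= 0:
        raise ConfigError("objective needs at least one example")
    return sum(losses) / n + 0.5 * l2_lambda * theta_norm_sq


class Adam:
    """Standard Adam on a list of parameter arrays, updated in place."""

    def __init__(self, arrays: list[np.ndarray], lr: float = 1e-3,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.arrays = arrays
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(a) for a in arrays]
        self.v = [np.zeros_like(a) for a in arrays]
        self.t = 0

    def step(self, grads: list[np.ndarray]) -> None:
        self.t += 1
        b1c = 1 - self.beta1 ** self.t
        b2c = 1 - self.beta2 ** self.t
        for a, g, m, v in zip(self.arrays, grads, self.m, self.v):
            m += (1 - self.beta1) * (g - m)
            v += (1 - self.beta2) * (g * g - v)
            a -= self.lr * (m / b1c) / (np.sqrt(v / b2c) + self.eps)


def clip_gradients(grads: list[np.ndarray], max_norm: float) -> list[np.ndarray]:
    total = math.sqrt(sum(float((g ** 2).sum()) for g in grads))
    if max_norm > 0 and total > max_norm:
        scale = max_norm / total
        return [g * scale for g in grads]
    return grads


@dataclass
class EncodedDataset:
    """Articles reduced to per-sentence embedding matrices plus labels —
    the trainer's working representation (embeddings are frozen, so they are
    computed once up front)."""

    doc_ids: list[str]
    doc_embeddings: list[list[np.ndarray]]
    labels: np.ndarray

    @classmethod
    def from_articles(cls, articles: Sequence[Article], labels: Sequence[int],
                      embedder) -> "EncodedDataset":
        embs = [[embedder.embed_tokens(s.tokens) for s in a.sentences]
                for a in articles]
        return cls([a.doc_id for a in articles], embs,
                   np.asarray(labels, dtype=int))

    def __len__(self) -> int:
        return len(self.doc_ids)


def _predict_dataset(pt: ParamTensors, data: EncodedDataset,
                     model_config: ModelConfig, batch_size: int = 32) -> np.ndarray:
    """Eval-mode probabilities (n, 2) for a dataset, batched."""
    probs = []
    for start in range(0, len(data), batch_size):
        chunk = data.doc_embeddings[start:start + batch_size]
        out = batched_forward(
            pt, chunk, np.zeros(len(chunk), dtype=int), np.ones(len(chunk)),
            model_config.join_sentence, model_config.join_document,
            model_config.variant, model_config.score_fn, model_config.phi,
            dropout_p=0.0, train=False,
        )
        probs.append(out.probs)
    return np.vstack(probs)


def evaluate_f1(pt: ParamTensors, data: EncodedDataset,
                model_config: ModelConfig) -> float:
    probs = _predict_dataset(pt, data, model_config)
    preds = probs.argmax(axis=1)
    return float(f1_score(data.labels, preds, labels=[0, 1], average="macro",
                          zero_division=0))


def train_model(
    train: EncodedDataset,
    val: EncodedDataset,
    params_init: HeaParameters,
    config: TrainingConfig,
    model_config: ModelConfig,
) -> tuple[HeaParameters, TrainingTrace]:
    """Epoch loop with best-validation-F1 checkpointing.

    Returns the parameters as they were at the best epoch (a copy; the
    initial parameters object is left at its final-epoch state) and the
    per-epoch trace.
    """
    if len(np.unique(train.labels)) < 2:
        raise DegenerateLabelsError("training split must contain both classes")
    weights_map = config.class_weights or compute_class_weights(train.labels)
    example_weights = np.array([weights_map[int(y)] for y in train.labels])

    params = params_init
    pt = ParamTensors.from_params(params)
    opt = Adam(pt.values(), lr=config.learning_rate)
    rng = np.random.default_rng(config.seed)
    trace = TrainingTrace()
    best_params = params.copy()

    n = len(train)
    for epoch in range(1, config.max_epochs + 1):
        order = rng.permutation(n)
        epoch_losses = []
        for start in range(0, n, config.batch_size):
            idx = order[start:start + config.batch_size]
            pt.zero_grads()
            out = batched_forward(
                pt,
                [train.doc_embeddings[i] for i in idx],
                train.labels[idx],
                example_weights[idx],
                model_config.join_sentence, model_config.join_document,
                model_config.variant, model_config.score_fn, model_config.phi,
                dropout_p=params.dropout_p, train=True, rng=rng,
            )
            loss_val = float(out.loss.value)
            if not math.isfinite(loss_val):
                raise DivergenceError(
                    f"non-finite loss at epoch {epoch}", trace=trace
                )
            out.loss.backward()
            grads = pt.grads()
            if config.l2_lambda > 0:
                grads = [g + config.l2_lambda * v
                         for g, v in zip(grads, pt.values())]
            grads = clip_gradients(grads, config.grad_clip)
            opt.step(grads)
            epoch_losses.append(loss_val)

        train_loss = objective(
            epoch_losses, pt.norm_sq(), config.l2_lambda, n=len(epoch_losses)
        )
        val_f1 = evaluate_f1(pt, val, model_config) if len(val) else 0.0
        if trace.note(EpochRecord(epoch, train_loss, val_f1)):
            best_params = params.copy()
    return best_params, trace


def predict_probs(params: HeaParameters, data: EncodedDataset,
                  model_config: ModelConfig) -> np.ndarray:
    """Eval-mode class probabilities for a dataset under fixed parameters."""
    return _predict_dataset(ParamTensors.from_params(params), data, model_config)


# ---------------------------------------------------------------------------
# Uniform random hyperparameter search


@dataclass
class SearchSpace:
    """Named axes: each value is either a list/tuple of choices or a
    (low, high) pair sampled log-uniformly when ``log`` names the axis."""

    axes: dict
    n_trials: int = 10
    seed: int = 0
    log_axes: tuple[str, ...] = ("learning_rate", "l2_lambda")

    def sample(self, rng: np.random.Generator) -> dict:
        if not self.axes:
            raise ConfigError("empty search space")
        config = {}
        for name, spec in self.axes.items():
            if isinstance(spec, (list, tuple)) and len(spec) == 2 and all(
                isinstance(v, float) for v in spec
            ):
                lo, hi = spec
                if name in self.log_axes:
                    config[name] = float(np.exp(rng.uniform(np.log(lo), np.log(hi))))
                else:
                    config[name] = float(rng.uniform(lo, hi))
            elif isinstance(spec, (list, tuple)):
                config[name] = spec[int(rng.integers(len(spec)))]
            else:
                config[name] = spec
        return config

    def sample_trials(self) -> list[dict]:
        rng = np.random.default_rng(self.seed)
        return [self.sample(rng) for _ in range(self.n_trials)]


def random_search(
    space: SearchSpace,
    train: EncodedDataset,
    val: EncodedDataset,
    base_model_config: ModelConfig,
    base_training_config: TrainingConfig,
) -> tuple[dict, list[tuple[dict, float]]]:
    """Sample configurations uniformly at random, train each, and rank by
    validation F1-macro. Returns (best configuration, all trials ranked)."""
    if space.n_trials < 1:
        raise ConfigError("need at least one trial")
    model_fields = set(ModelConfig.__dataclass_fields__)
    train_fields = set(TrainingConfig.__dataclass_fields__)
    results = []
    for trial in space.sample_trials():
        mc = replace(base_model_config,
                     **{k: v for k, v in trial.items() if k in model_fields})
        tc = replace(base_training_config,
                     **{k: v for k, v in trial.items() if k in train_fields})
        params = init_parameters(mc)
        _, trace = train_model(train, val, params, tc, mc)
        results.append((trial, trace.best_val_f1))
    ranked = sorted(results, key=lambda r: -r[1])
    return ranked[0][0], ranked
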