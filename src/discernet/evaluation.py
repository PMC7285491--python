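"""Metrics, cross-fold aggregation, selective prediction, explanations.

Selective prediction: for a coverage target c, the confidence threshold is
the empirical (1−c)-quantile (lower / type-1) of the prediction confidences;
documents whose confidence falls below it are abstained and metrics are
computed on the covered remainder. Coverage 1 maps to threshold 0.5 — for a
binary softmax every confidence is ≥ 0.5, so nothing abstains.

Explanations: for the most confidently predicted documents, report the
sentences carrying the highest attention weight — the model's own evidence
for its call.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.metrics import (
    accuracy_score,
    f1_score,
    precision_score,
    recall_score,
)

from .corpus_io import Article
from .errors import (
    CoverageError,
    ExplainabilityUnavailableError,
    ValidationError,
)
from .model import DocumentEncoding, Prediction

PREDICTION_COLUMNS = ("doc_id", "criterion", "prob_fail", "prob_pass",
                      "predicted", "confidence", "fold_id")


def _check_aligned(predictions, truths):
    predictions = np.asarray(predictions)
    truths = np.asarray(truths)
    if predictions.size == 0 or predictions.shape != truths.shape:
        raise ValidationError(
            f"predictions {predictions.shape} and truths {truths.shape} "
            "must be aligned and non-empty"
        )
    return predictions, truths


def f1_macro(predictions, truths) -> float:
    """Unweighted mean of per-class F1 over {fail, pass}. A class absent
    from both truths and predictions contributes 0 with a warning."""
    predictions, truths = _check_aligned(predictions, truths)
    present = set(np.unique(truths)) | set(np.unique(predictions))
    if not {0, 1} <= present:
        warnings.warn("a class is absent; its F1 counts as 0", stacklevel=2)
    return float(f1_score(truths, predictions, labels=[0, 1],
                          average="macro", zero_division=0))


def accuracy(predictions, truths) -> float:
    predictions, truths = _check_aligned(predictions, truths)
    return float(accuracy_score(truths, predictions))


def precision(predictions, truths) -> float:
    predictions, truths = _check_aligned(predictions, truths)
    return float(precision_score(truths, predictions, zero_division=0))


def recall(predictions, truths) -> float:
    predictions, truths = _check_aligned(predictions, truths)
    return float(recall_score(truths, predictions, zero_division=0))


# ---------------------------------------------------------------------------
# Selective prediction / coverage analysis


def coverage_threshold(confidences: Sequence[float], coverage: float) -> float:
    """Confidence threshold realizing a coverage target.

    coverage = 1 returns 0.5 (every binary-softmax confidence is at least
    0.5, so all documents are covered). Otherwise the threshold is the lower
    empirical (1−coverage)-quantile: with n confidences, the
    floor(n·(1−coverage))-th order statistic; documents strictly below it
    abstain, documents at or above it are covered.
    """
    conf = np.asarray(list(confidences), dtype=float)
    if conf.size == 0:
        raise ValidationError("no confidences")
    if not 0 < coverage <= 1:
        raise ValidationError(f"coverage {coverage} outside (0, 1]")
    if coverage == 1.0:
        return 0.5
    # epsilon guards binary-representation artifacts like 10*(1-0.8)=1.999...
    k = int(np.floor(conf.size * (1.0 - coverage) + 1e-9))
    return float(np.sort(conf)[min(k, conf.size - 1)])


@dataclass(frozen=True)
class CoveragePoint:
    coverage_target: float
    confidence_threshold: float
    coverage_achieved: float
    accuracy: float
    precision: float
    recall: float
    f1_macro: float
    abstained_doc_ids: tuple[str, ...]


@dataclass
class CoverageCurve:
    points: list[CoveragePoint]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([
            {"coverage_target": p.coverage_target,
             "confidence_threshold": p.confidence_threshold,
             "coverage_achieved": p.coverage_achieved,
             "accuracy": p.accuracy, "precision": p.precision,
             "recall": p.recall, "f1_macro": p.f1_macro,
             "n_abstained": len(p.abstained_doc_ids)}
            for p in self.points
        ])


def accuracy_at_coverage(
    predictions: Sequence[int],
    truths: Sequence[int],
    confidences: Sequence[float],
    coverage: float,
    doc_ids: Sequence[str] | None = None,
) -> CoveragePoint:
    """Metrics on the covered subset at one coverage target; abstained
    documents are identified so they can be routed to manual review."""
    predictions, truths = _check_aligned(predictions, truths)
    conf = np.asarray(list(confidences), dtype=float)
    if doc_ids is None:
        doc_ids = [str(i) for i in range(len(conf))]
    threshold = coverage_threshold(conf, coverage)
    covered = conf >= threshold
    if not covered.any():
        raise CoverageError(f"no documents covered at coverage {coverage}")
    p, t = predictions[covered], truths[covered]
    return CoveragePoint(
        coverage_target=coverage,
        confidence_threshold=threshold,
        coverage_achieved=float(covered.mean()),
        accuracy=accuracy(p, t),
        precision=precision(p, t),
        recall=recall(p, t),
        f1_macro=f1_macro(p, t),
        abstained_doc_ids=tuple(d for d, c in zip(doc_ids, covered) if not c),
    )


def coverage_curve(
    predictions, truths, confidences,
    grid: Sequence[float] = (1.0, 0.9, 0.8, 0.7, 0.6, 0.5),
    doc_ids=None,
) -> CoverageCurve:
    return CoverageCurve([
        accuracy_at_coverage(predictions, truths, confidences, c, doc_ids)
        for c in grid
    ])


# ---------------------------------------------------------------------------
# Attention-based explanations


@dataclass(frozen=True)
class ExplanationSentence:
    sentence_index: int
    raw_text: str
    attention_weight: float


@dataclass(frozen=True)
class Explanation:
    doc_id: str
    criterion: str
    confidence: float
    top_sentences: tuple[ExplanationSentence, ...]


def extract_explanations(
    encodings: Sequence[DocumentEncoding],
    predictions: Sequence[Prediction],
    articles: Sequence[Article],
    k_docs: int = 3,
    k_sents: int = 3,
) -> list[Explanation]:
    """The most confidently predicted ``k_docs`` documents, each with its
    ``k_sents`` highest-attention sentences (weights exactly as produced by
    the forward pass; ties broken toward the lower sentence index)."""
    if len(encodings) != len(predictions) or len(predictions) != len(articles):
        raise ValidationError("encodings, predictions, articles must align")
    for enc in encodings:
        if enc.alpha is None:
            raise ExplainabilityUnavailableError(
                "attention weights unavailable (HE variant has no attention)"
            )
    order = sorted(
        range(len(predictions)),
        key=lambda i: (-predictions[i].confidence, predictions[i].doc_id),
    )[:k_docs]
    out = []
    for i in order:
        alpha = encodings[i].alpha
        sents = articles[i].sentences
        top = sorted(range(len(alpha)), key=lambda j: (-alpha[j], j))[:k_sents]
        out.append(Explanation(
            doc_id=predictions[i].doc_id,
            criterion=predictions[i].criterion,
            confidence=predictions[i].confidence,
            top_sentences=tuple(
                ExplanationSentence(j, sents[j].raw_text, float(alpha[j]))
                for j in top
            ),
        ))
    return out


# ---------------------------------------------------------------------------
# Cross-fold aggregation and the shared prediction table


@dataclass
class MetricReport:
    criterion: str
    per_fold: pd.DataFrame  # fold_id, f1_macro, accuracy, precision, recall
    mean: pd.Series
    std: pd.Series


def fold_metrics(predictions, truths, fold_id: int) -> dict:
    return {
        "fold_id": fold_id,
        "f1_macro": f1_macro(predictions, truths),
        "accuracy": accuracy(predictions, truths),
        "precision": precision(predictions, truths),
        "recall": recall(predictions, truths),
    }


def aggregate_folds(per_fold_metrics: Sequence[dict],
                    criterion: str = "") -> MetricReport:
    """Mean and (population) standard deviation of each metric across folds."""
    if not per_fold_metrics:
        raise ValidationError("no folds to aggregate")
    df = pd.DataFrame(list(per_fold_metrics))
    cols = [c for c in df.columns if c != "fold_id"]
    return MetricReport(
        criterion=criterion,
        per_fold=df,
        mean=df[cols].mean(),
        std=df[cols].std(ddof=0),
    )


def predictions_frame(
    predictions: Sequence[Prediction], fold_id: int = 0
) -> pd.DataFrame:
    """The prediction table shared by the neural and baseline pipelines."""
    return pd.DataFrame([
        {"doc_id": p.doc_id, "criterion": p.criterion,
         "prob_fail": float(p.probs[0]), "prob_pass": float(p.probs[1]),
         "predicted": p.predicted_label, "confidence": p.confidence,
         "fold_id": fold_id}
        for p in predictions
    ], columns=list(PREDICTION_COLUMNS))


def read_predictions_csv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"doc_id": str})
    missing = set(PREDICTION_COLUMNS) - set(df.columns)
    if missing:
        raise ValidationError(f"prediction table missing columns {sorted(missing)}")
    return df
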