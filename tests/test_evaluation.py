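"""Metrics, selective prediction and explanation extraction."""

import numpy as np
import pytest

from conftest import random_article
from discernet.errors import (
    CoverageError,
    ExplainabilityUnavailableError,
    ValidationError,
)
from discernet.evaluation import (
    PREDICTION_COLUMNS,
    accuracy,
    accuracy_at_coverage,
    aggregate_folds,
    coverage_curve,
    coverage_threshold,
    extract_explanations,
    f1_macro,
    fold_metrics,
    predictions_frame,
)
from discernet.model import DocumentEncoding, Prediction


def brute_force_f1_macro(preds, truths):
    out = []
    for cls in (0, 1):
        tp = sum(1 for p, t in zip(preds, truths) if p == cls and t == cls)
        fp = sum(1 for p, t in zip(preds, truths) if p == cls and t != cls)
        fn = sum(1 for p, t in zip(preds, truths) if p != cls and t == cls)
        prec = tp / (tp + fp) if tp + fp else 0.0
        rec = tp / (tp + fn) if tp + fn else 0.0
        out.append(2 * prec * rec / (prec + rec) if prec + rec else 0.0)
    return sum(out) / 2


class TestF1Macro:
    def test_perfect(self):
        assert f1_macro([0, 1, 1], [0, 1, 1]) == 1.0

    def test_symmetric_confusion_half(self):
        # TP=FP=FN=TN=1 for each class -> per-class F1 = 0.5, macro = 0.5
        assert f1_macro([1, 1, 0, 0], [1, 0, 1, 0]) == pytest.approx(0.5)

    def test_matches_confusion_matrix_oracle(self, rng):
        for _ in range(50):
            n = int(rng.integers(2, 30))
            preds = rng.integers(0, 2, n)
            truths = rng.integers(0, 2, n)
            assert f1_macro(preds, truths) == pytest.approx(
                brute_force_f1_macro(preds, truths))

    def test_label_swap_invariance(self, rng):
        preds = rng.integers(0, 2, 40)
        truths = rng.integers(0, 2, 40)
        assert f1_macro(preds, truths) == pytest.approx(
            f1_macro(1 - preds, 1 - truths))

    def test_absent_class_warns(self):
        with pytest.warns(UserWarning):
            f1_macro([1, 1], [1, 1])

    def test_empty_rejected(self):
        with pytest.raises(ValidationError):
            f1_macro([], [])


class TestCoverageThreshold:
    def test_full_coverage_is_half(self):
        conf = [0.9, 0.6, 0.75]
        assert coverage_threshold(conf, 1.0) == 0.5

    def test_ten_confidences_two_abstain(self):
        conf = [0.51 + 0.01 * i for i in range(10)]
        thr = coverage_threshold(conf, 0.8)
        abstained = [c for c in conf if c < thr]
        assert len(abstained) == 2
        assert thr == pytest.approx(0.53)

    def test_all_ties_never_partial(self):
        conf = [0.7] * 8
        for cov in (0.9, 0.5, 0.2):
            thr = coverage_threshold(conf, cov)
            covered = [c for c in conf if c >= thr]
            assert len(covered) in (0, len(conf))
            assert len(covered) == len(conf)  # ties sit at the threshold

    def test_quantile_against_sorting_oracle(self, rng):
        for _ in range(30):
            conf = 0.5 + 0.5 * rng.random(int(rng.integers(1, 40)))
            cov = float(rng.uniform(0.05, 0.99))
            thr = coverage_threshold(conf, cov)
            k = int(np.floor(len(conf) * (1 - cov)))
            assert thr == sorted(conf)[min(k, len(conf) - 1)]

    def test_invalid_coverage(self):
        with pytest.raises(ValidationError):
            coverage_threshold([0.6], 0.0)
        with pytest.raises(ValidationError):
            coverage_threshold([0.6], 1.2)


class TestAccuracyAtCoverage:
    def test_full_coverage_reproduces_plain_accuracy(self, rng):
        n = 20
        preds = rng.integers(0, 2, n)
        truths = rng.integers(0, 2, n)
        conf = 0.5 + 0.5 * rng.random(n)
        point = accuracy_at_coverage(preds, truths, conf, 1.0)
        assert point.accuracy == pytest.approx(accuracy(preds, truths))
        assert point.coverage_achieved == 1.0
        assert point.abstained_doc_ids == ()

    def test_correct_top_half_yields_perfect_covered_accuracy(self):
        # predictions correct exactly where confidence is in the top half
        truths = [1] * 10
        preds = [1] * 5 + [0] * 5
        conf = [0.9] * 5 + [0.6] * 5
        point = accuracy_at_coverage(preds, truths, conf, 0.5)
        assert point.accuracy == 1.0
        assert len(point.abstained_doc_ids) == 5

    def test_threshold_monotone_over_sweep(self, rng):
        n = 50
        preds = rng.integers(0, 2, n)
        truths = rng.integers(0, 2, n)
        conf = 0.5 + 0.5 * rng.random(n)
        curve = coverage_curve(preds, truths, conf,
                               grid=[1.0, 0.9, 0.8, 0.7, 0.6, 0.5, 0.4, 0.3,
                                     0.2, 0.1])
        thresholds = [p.confidence_threshold for p in curve.points]
        assert thresholds == sorted(thresholds)
        cov = [p.coverage_achieved for p in curve.points]
        assert cov == sorted(cov, reverse=True)

    def test_covered_fraction_quantile_bound(self, rng):
        n = 37
        conf = 0.5 + 0.5 * rng.random(n)
        for target in (0.9, 0.6, 0.3):
            point = accuracy_at_coverage(np.ones(n, int), np.ones(n, int),
                                         conf, target)
            assert point.coverage_achieved >= target - 1.0 / n


class TestExplanations:
    def _enc(self, alpha):
        alpha = np.asarray(alpha, dtype=float)
        T = len(alpha)
        return DocumentEncoding(O=np.zeros((T, 2)), alpha=alpha, z=np.zeros(2))

    def _pred(self, doc_id, conf):
        return Prediction(doc_id, "Q5", np.array([1 - conf, conf]))

    def test_defaults_three_docs_three_sentences(self, rng):
        arts = [random_article(rng, f"d{i}", n_sentences=5) for i in range(6)]
        encs = [self._enc(np.full(5, 0.2)) for _ in arts]
        preds = [self._pred(a.doc_id, 0.6 + 0.05 * i)
                 for i, a in enumerate(arts)]
        out = extract_explanations(encs, preds, arts)
        assert len(out) == 3
        assert [e.doc_id for e in out] == ["d5", "d4", "d3"]  # most confident
        assert all(len(e.top_sentences) == 3 for e in out)

    def test_short_document_returns_what_exists(self, rng):
        art = random_article(rng, "d0", n_sentences=2)
        out = extract_explanations([self._enc([0.7, 0.3])],
                                   [self._pred("d0", 0.9)], [art], k_sents=3)
        assert len(out[0].top_sentences) == 2

    def test_weights_are_raw_alphas_sorted_with_index_ties(self, rng):
        art = random_article(rng, "d0", n_sentences=4)
        alpha = [0.1, 0.4, 0.4, 0.1]
        out = extract_explanations([self._enc(alpha)],
                                   [self._pred("d0", 0.8)], [art], k_sents=4)
        got = [(s.sentence_index, s.attention_weight)
               for s in out[0].top_sentences]
        assert got == [(1, 0.4), (2, 0.4), (0, 0.1), (3, 0.1)]

    def test_he_encodings_rejected(self, rng):
        art = random_article(rng, "d0", n_sentences=2)
        enc = DocumentEncoding(O=np.zeros((2, 2)), alpha=None, z=np.zeros(2))
        with pytest.raises(ExplainabilityUnavailableError):
            extract_explanations([enc], [self._pred("d0", 0.9)], [art])


class TestAggregation:
    def test_identical_folds_zero_std(self):
        folds = [{"fold_id": i, "f1_macro": 0.8, "accuracy": 0.9,
                  "precision": 0.7, "recall": 0.6} for i in range(5)]
        rep = aggregate_folds(folds, "Q4")
        assert rep.std["f1_macro"] == 0.0
        assert rep.mean["accuracy"] == pytest.approx(0.9)

    def test_two_point_mean(self):
        folds = [{"fold_id": 1, "f1_macro": 0.6},
                 {"fold_id": 2, "f1_macro": 0.8}]
        rep = aggregate_folds(folds)
        assert rep.mean["f1_macro"] == pytest.approx(0.7)

    def test_random_folds_vs_direct_arithmetic(self, rng):
        vals = rng.random(7)
        folds = [{"fold_id": i, "f1_macro": float(v)}
                 for i, v in enumerate(vals)]
        rep = aggregate_folds(folds)
        assert rep.mean["f1_macro"] == pytest.approx(vals.mean())
        assert rep.std["f1_macro"] == pytest.approx(vals.std())
        assert rep.per_fold["f1_macro"].min() <= rep.mean["f1_macro"] \
            <= rep.per_fold["f1_macro"].max()


def test_prediction_frame_schema():
    preds = [Prediction("d1", "Q4", np.array([0.3, 0.7]))]
    df = predictions_frame(preds, fold_id=2)
    assert tuple(df.columns) == PREDICTION_COLUMNS
    row = df.iloc[0]
    assert row["predicted"] == 1
    assert row["confidence"] == pytest.approx(0.7)
    assert row["fold_id"] == 2


def test_fold_metrics_keys(rng):
    m = fold_metrics(rng.integers(0, 2, 10), rng.integers(0, 2, 10), 3)
    assert set(m) == {"fold_id", "f1_macro", "accuracy", "precision", "recall"}
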