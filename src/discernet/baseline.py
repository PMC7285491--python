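"""Traditional baseline: TF-IDF + engineered features, RFE-CV, Random Forest.

The bag-of-words representation uses the smoothed TF-IDF convention
idf(t) = ln((1+n)/(1+df(t))) + 1 with L2-normalized rows (scikit-learn's
default, delegated to :class:`TfidfVectorizer`). Engineered document
features: presence of HTML links, bibliography-keyword count, medical-term
count from a pluggable lexicon, a capitalized-span named-entity heuristic,
and lexicon polarity in [−1, 1]. Vocabulary and feature selection are always
fitted on the training split only.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import sparse
from sklearn.ensemble import RandomForestClassifier
from sklearn.feature_extraction.text import TfidfVectorizer
from sklearn.feature_selection import RFECV
from sklearn.model_selection import StratifiedKFold

from .corpus_io import Article
from .errors import DegenerateLabelsError, FeatureError
from .lexicons import LexiconSet
from .model import Prediction

ENGINEERED_NAMES = ("has_html_link", "bibliography_keyword_count",
                    "medical_term_count", "named_entity_count", "polarity")


class TfidfFeaturizer:
    """TF-IDF over pre-tokenized articles. Fit on the training split; terms
    unseen at fit time are ignored at transform time."""

    def __init__(self, lowercase: bool = True, min_df: int = 1):
        self.lowercase = lowercase
        self.vectorizer = TfidfVectorizer(
            analyzer=self._analyze, min_df=min_df,
            norm="l2", smooth_idf=True, sublinear_tf=False,
        )

    def _analyze(self, article: Article) -> list[str]:
        tokens = [t for s in article.sentences for t in s.tokens]
        return [t.lower() for t in tokens] if self.lowercase else tokens

    def fit_transform(self, corpus: Sequence[Article]) -> sparse.csr_matrix:
        if not corpus:
            raise FeatureError("empty corpus")
        try:
            return self.vectorizer.fit_transform(corpus)
        except ValueError as exc:
            raise FeatureError(f"empty vocabulary: {exc}") from None

    def transform(self, corpus: Sequence[Article]) -> sparse.csr_matrix:
        return self.vectorizer.transform(corpus)

    @property
    def vocabulary(self) -> dict[str, int]:
        return self.vectorizer.vocabulary_


def tfidf_features(corpus: Sequence[Article]) -> tuple[sparse.csr_matrix, TfidfFeaturizer]:
    """Fit-and-transform convenience for a training corpus."""
    feat = TfidfFeaturizer()
    return feat.fit_transform(corpus), feat


_LINK_RE = re.compile(r"<a\s[^>]*href|https?://", re.IGNORECASE)
# Capitalized spans not at sentence start: crude named-entity surrogate.
_CAP_SPAN_RE = re.compile(r"(?<![.!?]\s)(?<!^)\b([A-Z][a-z]+(?:\s+[A-Z][a-z]+)*)\b")


def engineered_features(article: Article,
                        lexicons: LexiconSet | None = None) -> dict[str, float]:
    """Deterministic document-level features (see module docstring)."""
    lex = lexicons or LexiconSet()
    tokens = [t.lower() for s in article.sentences for t in s.tokens]
    token_set_text = " ".join(tokens)

    has_link = 1.0 if article.raw_html and _LINK_RE.search(article.raw_html) else 0.0
    bib_count = float(sum(1 for t in tokens if t in lex.bibliography_keywords))
    med_count = float(sum(1 for t in tokens if t in lex.medical_terms))
    # multi-word lexicon terms
    med_count += float(sum(
        token_set_text.count(term) for term in lex.medical_terms if " " in term
    ))
    ner_count = 0.0
    for s in article.sentences:
        for m in _CAP_SPAN_RE.finditer(s.raw_text):
            if m.start() > 0:  # skip the sentence-initial capital
                ner_count += 1
    pos = sum(1 for t in tokens if t in lex.positive_words)
    neg = sum(1 for t in tokens if t in lex.negative_words)
    polarity = (pos - neg) / (pos + neg) if (pos + neg) else 0.0
    return {
        "has_html_link": has_link,
        "bibliography_keyword_count": bib_count,
        "medical_term_count": med_count,
        "named_entity_count": ner_count,
        "polarity": float(polarity),
    }


def engineered_matrix(corpus: Sequence[Article],
                      lexicons: LexiconSet | None = None) -> np.ndarray:
    rows = [engineered_features(a, lexicons) for a in corpus]
    return np.array([[r[name] for name in ENGINEERED_NAMES] for r in rows])


@dataclass
class FeatureSelection:
    surviving_indices: np.ndarray
    cv_score_per_subset_size: dict[int, float]
    selector: RFECV


def rfe_cv(
    features: np.ndarray | sparse.spmatrix,
    labels: Sequence[int],
    n_folds: int = 3,
    seed: int = 0,
    step: float = 0.2,
    estimator=None,
) -> FeatureSelection:
    """Recursive feature elimination with cross-validation: iteratively drop
    the least-important features (random-forest importances by default) and
    keep the subset size with the best CV score."""
    y = np.asarray(labels)
    if len(np.unique(y)) < 2:
        raise DegenerateLabelsError("feature selection needs both classes")
    X = features.toarray() if sparse.issparse(features) else np.asarray(features)
    if X.shape[1] < 2:
        raise FeatureError("need at least two features to eliminate")
    estimator = estimator or RandomForestClassifier(
        n_estimators=100, random_state=seed, class_weight="balanced"
    )
    selector = RFECV(
        estimator, step=step, min_features_to_select=1,
        cv=StratifiedKFold(n_folds, shuffle=True, random_state=seed),
        scoring="f1_macro",
    )
    selector.fit(X, y)
    sizes = selector.cv_results_["n_features"]
    scores = selector.cv_results_["mean_test_score"]
    return FeatureSelection(
        surviving_indices=np.flatnonzero(selector.support_),
        cv_score_per_subset_size={int(n): float(s) for n, s in zip(sizes, scores)},
        selector=selector,
    )


@dataclass
class RandomForestConfig:
    n_estimators: int = 500
    max_depth: int | None = None
    seed: int = 0
    class_weight: str | dict | None = "balanced"


def train_rf(features, labels: Sequence[int],
             config: RandomForestConfig | None = None) -> RandomForestClassifier:
    """Seeded random forest with inverse-frequency class weighting; exposes
    predict_proba for the shared coverage analysis."""
    config = config or RandomForestConfig()
    y = np.asarray(labels)
    if len(np.unique(y)) < 2:
        raise DegenerateLabelsError("random forest needs both classes")
    clf = RandomForestClassifier(
        n_estimators=config.n_estimators, max_depth=config.max_depth,
        random_state=config.seed, class_weight=config.class_weight,
    )
    clf.fit(features.toarray() if sparse.issparse(features) else features, y)
    return clf


@dataclass
class BaselineRun:
    predictions: list[Prediction]
    selection: FeatureSelection | None
    classifier: RandomForestClassifier


def run_baseline_fold(
    train_articles: Sequence[Article], train_labels: Sequence[int],
    test_articles: Sequence[Article],
    criterion: str = "",
    lexicons: LexiconSet | None = None,
    rf_config: RandomForestConfig | None = None,
    use_rfe: bool = False,
    seed: int = 0,
) -> BaselineRun:
    """One train/test fold of the full baseline pipeline; the vocabulary,
    any feature selection, and the forest are fitted on the training
    articles only. Emits the same Prediction objects as the neural models,
    so both flow through the same evaluation code."""
    feat = TfidfFeaturizer()
    X_tr = sparse.hstack(
        [feat.fit_transform(train_articles),
         sparse.csr_matrix(engineered_matrix(train_articles, lexicons))]
    ).tocsr()
    X_te = sparse.hstack(
        [feat.transform(test_articles),
         sparse.csr_matrix(engineered_matrix(test_articles, lexicons))]
    ).tocsr()

    selection = None
    if use_rfe:
        selection = rfe_cv(X_tr, train_labels, seed=seed)
        X_tr = X_tr[:, selection.surviving_indices]
        X_te = X_te[:, selection.surviving_indices]

    rf_config = rf_config or RandomForestConfig(seed=seed)
    clf = train_rf(X_tr, train_labels, rf_config)
    probs = clf.predict_proba(X_te.toarray())
    # align columns to (fail, pass)
    col = {c: i for i, c in enumerate(clf.classes_)}
    preds = [
        Prediction(a.doc_id, criterion,
                   np.array([p[col.get(0, 0)], p[col.get(1, -1)]]))
        for a, p in zip(test_articles, probs)
    ]
    return BaselineRun(predictions=preds, selection=selection, classifier=clf)
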