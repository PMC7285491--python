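"""Corpus ingestion: HTML → sentences, DISCERN label handling, CV splits.

An article enters the pipeline as raw HTML plus a row per criterion in a label
table (two human raters, 1-5 DISCERN scores each). This module turns the HTML
into an ordered list of tokenized sentences, aggregates and binarizes the
scores (3-5 passes, 1-2 fails), and builds stratified cross-validation folds
with inverse-frequency class weights.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import lxml.etree
import lxml.html
import numpy as np
import pandas as pd
from sklearn.model_selection import StratifiedKFold, train_test_split

from .errors import (
    DegenerateLabelsError,
    EmptyDocument,
    StratificationError,
    ValidationError,
)

CRITERIA = ("Q4", "Q5", "Q9", "Q10", "Q11")
TOPICS = ("breast_cancer", "arthritis", "depression", "other")

# Tags whose subtree is never visible article text.
_NONCONTENT_TAGS = frozenset(
    {"script", "style", "head", "nav", "footer", "header", "noscript",
     "template", "aside", "form", "button", "iframe"}
)
# Tags that force a segment boundary (text across them is never one sentence).
_BLOCK_TAGS = frozenset(
    {"p", "div", "li", "ul", "ol", "h1", "h2", "h3", "h4", "h5", "h6", "br",
     "tr", "td", "th", "table", "section", "article", "blockquote", "title",
     "dt", "dd", "pre", "figcaption", "main", "body", "html"}
)

_TOKEN_RE = re.compile(r"\w+(?:[-/']\w+)*|[^\w\s]", re.UNICODE)
_SENT_BOUNDARY_RE = re.compile(r"(?<=[.!?])\s+")


@dataclass(frozen=True)
class SegmenterConfig:
    """Knobs for the rule-based sentence splitter and tokenizer.

    max_sentence_tokens / max_doc_sentences bound memory for very long pages;
    articles in this domain average ~130 sentences so 300 is a loose cap.
    """

    max_sentence_tokens: int = 128
    max_doc_sentences: int = 300
    lowercase: bool = False


@dataclass(frozen=True)
class Sentence:
    index: int
    tokens: tuple[str, ...]
    raw_text: str


@dataclass(frozen=True)
class Article:
    doc_id: str
    topic: str
    sentences: tuple[Sentence, ...]
    raw_html: str = ""

    @property
    def n_tokens(self) -> int:
        return sum(len(s.tokens) for s in self.sentences)

    def token_lists(self) -> list[list[str]]:
        return [list(s.tokens) for s in self.sentences]


@dataclass(frozen=True)
class CriterionLabel:
    doc_id: str
    criterion: str
    rater_scores: tuple[int, ...]
    aggregated_score: float
    binary_label: int  # 0 = fail, 1 = pass


@dataclass(frozen=True)
class FoldSplit:
    fold_id: int
    train_ids: tuple[str, ...]
    val_ids: tuple[str, ...]
    test_ids: tuple[str, ...]


@dataclass(frozen=True)
class ClassWeights:
    weight_per_label: Mapping[int, float]

    def __getitem__(self, label: int) -> float:
        return self.weight_per_label[label]


def tokenize(text: str, config: SegmenterConfig | None = None) -> list[str]:
    """Whitespace+punctuation tokenizer; hyphen/slash/apostrophe-joined words stay whole."""
    config = config or SegmenterConfig()
    tokens = _TOKEN_RE.findall(text)
    if config.lowercase:
        tokens = [t.lower() for t in tokens]
    return tokens


def split_sentences(segment: str) -> list[str]:
    """Rule-based sentence split inside one text segment: break after . ! ?
    followed by whitespace. Dates like 11/17/2012 and decimals survive intact."""
    parts = [p.strip() for p in _SENT_BOUNDARY_RE.split(segment)]
    return [p for p in parts if p]


def _collect_segments(element, out: list[str]) -> None:
    if not isinstance(element.tag, str):  # comments, PIs
        return
    tag = element.tag.lower()
    if tag in _NONCONTENT_TAGS:
        return
    block = tag in _BLOCK_TAGS
    if block:
        out.append("\n")
    if element.text:
        out.append(element.text)
    for child in element:
        _collect_segments(child, out)
        if child.tail:
            out.append(child.tail)
    if block:
        out.append("\n")


def extract_sentences(
    raw_html: str, segmenter_config: SegmenterConfig | None = None
) -> list[Sentence]:
    """Reduce HTML to an ordered, tokenized sentence list.

    Script/style/navigation subtrees are removed, block elements delimit
    segments, and each segment is sentence-split and tokenized. Malformed
    markup is repaired by the parser; entities are decoded. Empty visible
    text raises :class:`EmptyDocument`.
    """
    config = segmenter_config or SegmenterConfig()
    if not raw_html or not raw_html.strip():
        raise EmptyDocument("no markup provided")
    try:
        root = lxml.html.fromstring(raw_html)
    except (lxml.etree.ParserError, ValueError) as exc:
        raise EmptyDocument(f"unparseable markup: {exc}") from None

    pieces: list[str] = []
    _collect_segments(root, pieces)
    text = "".join(pieces)

    sentences: list[Sentence] = []
    for segment in text.split("\n"):
        segment = re.sub(r"\s+", " ", segment).strip()
        if not segment:
            continue
        for raw in split_sentences(segment):
            tokens = tokenize(raw, config)
            if not tokens:
                continue
            tokens = tokens[: config.max_sentence_tokens]
            sentences.append(Sentence(len(sentences), tuple(tokens), raw))
            if len(sentences) >= config.max_doc_sentences:
                break
        if len(sentences) >= config.max_doc_sentences:
            break

    if not sentences:
        raise EmptyDocument("document has no visible text after cleaning")
    return sentences


def aggregate_scores(rater_scores: Sequence[int]) -> float:
    """Arithmetic mean of the raters' 1-5 scores."""
    if not rater_scores:
        raise ValidationError("no rater scores")
    for s in rater_scores:
        if not 1 <= s <= 5:
            raise ValidationError(f"rater score {s} outside [1, 5]")
    return float(np.mean(rater_scores))


def binarize_score(aggregated_score: float) -> int:
    """3-5 passes (1), 1-2 fails (0). The aggregated mean is rounded half-up
    before the cut, so a 2.5 tie between raters counts as a pass."""
    if not 1.0 <= aggregated_score <= 5.0:
        raise ValidationError(
            f"aggregated score {aggregated_score} outside [1, 5]"
        )
    rounded = int(np.floor(aggregated_score + 0.5))
    return 1 if rounded >= 3 else 0


def make_label(doc_id: str, criterion: str, rater_scores: Sequence[int]) -> CriterionLabel:
    if criterion not in CRITERIA:
        raise ValidationError(f"unknown criterion {criterion!r}")
    agg = aggregate_scores(rater_scores)
    return CriterionLabel(
        doc_id=doc_id,
        criterion=criterion,
        rater_scores=tuple(int(s) for s in rater_scores),
        aggregated_score=agg,
        binary_label=binarize_score(agg),
    )


def make_stratified_folds(
    labels: Sequence[CriterionLabel],
    k: int = 5,
    val_fraction: float = 0.1,
    seed: int = 0,
) -> list[FoldSplit]:
    """Stratified k-fold splits: test folds partition the corpus (~1/k each),
    and a stratified ``val_fraction`` of each fold's training portion is held
    out for early stopping / model selection. Deterministic under ``seed``."""
    doc_ids = np.array([lab.doc_id for lab in labels])
    y = np.array([lab.binary_label for lab in labels])
    if len(set(doc_ids)) != len(doc_ids):
        raise ValidationError("duplicate doc_id in labels")
    counts = np.bincount(y, minlength=2)
    if counts.min() < k:
        raise StratificationError(
            f"class counts {counts.tolist()} cannot fill {k} stratified folds"
        )
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    folds: list[FoldSplit] = []
    for fold_id, (train_idx, test_idx) in enumerate(skf.split(doc_ids, y), start=1):
        n_val = int(round(val_fraction * len(train_idx)))
        if n_val >= 1:
            # stratify only when the held-out part can hold both classes
            stratify = y[train_idx] if n_val >= 2 else None
            tr_idx, val_idx = train_test_split(
                train_idx,
                test_size=n_val,
                random_state=seed + fold_id,
                stratify=stratify,
            )
        else:
            tr_idx, val_idx = train_idx, np.array([], dtype=int)
        folds.append(
            FoldSplit(
                fold_id=fold_id,
                train_ids=tuple(sorted(doc_ids[tr_idx])),
                val_ids=tuple(sorted(doc_ids[val_idx])),
                test_ids=tuple(sorted(doc_ids[test_idx])),
            )
        )
    return folds


def compute_class_weights(labels: Iterable[int]) -> ClassWeights:
    """Per-class loss weights inversely proportional to class frequency,
    normalized so they average 1 over examples (the minority class gets the
    larger weight)."""
    y = np.asarray(list(labels))
    if y.size == 0:
        raise DegenerateLabelsError("empty label list")
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) < 2:
        raise DegenerateLabelsError("class weights need both classes present")
    n, k = y.size, len(classes)
    return ClassWeights({int(c): n / (k * cnt) for c, cnt in zip(classes, counts)})


# ---------------------------------------------------------------------------
# Disk formats: labels.csv in, preprocessed corpus as JSON-lines out.

def read_labels_csv(path: str | Path) -> list[CriterionLabel]:
    """labels.csv columns: doc_id, topic, criterion, rater1_score, rater2_score."""
    df = pd.read_csv(path, dtype={"doc_id": str})
    required = {"doc_id", "criterion", "rater1_score", "rater2_score"}
    missing = required - set(df.columns)
    if missing:
        raise ValidationError(f"labels table missing columns {sorted(missing)}")
    return [
        make_label(row.doc_id, row.criterion, (int(row.rater1_score), int(row.rater2_score)))
        for row in df.itertuples()
    ]


def read_topics_csv(path: str | Path) -> dict[str, str]:
    df = pd.read_csv(path, dtype={"doc_id": str})
    if "topic" not in df.columns:
        return {}
    return dict(zip(df["doc_id"], df["topic"]))


def preprocess_directory(
    input_dir: str | Path,
    topics: Mapping[str, str] | None = None,
    segmenter_config: SegmenterConfig | None = None,
) -> list[Article]:
    """Parse every ``*.html`` file in a directory into an Article (doc_id =
    file stem). Files with no visible text are skipped with a warning tuple
    rather than aborting the corpus."""
    topics = topics or {}
    articles: list[Article] = []
    for path in sorted(Path(input_dir).glob("*.html")):
        raw = path.read_text(encoding="utf-8")
        try:
            sentences = extract_sentences(raw, segmenter_config)
        except EmptyDocument:
            continue
        articles.append(
            Article(
                doc_id=path.stem,
                topic=topics.get(path.stem, "other"),
                sentences=tuple(sentences),
                raw_html=raw,
            )
        )
    return articles


def write_corpus_jsonl(articles: Iterable[Article], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for art in articles:
            record = {
                "doc_id": art.doc_id,
                "topic": art.topic,
                "sentences": [
                    {"tokens": list(s.tokens), "raw_text": s.raw_text}
                    for s in art.sentences
                ],
            }
            fh.write(json.dumps(record, ensure_ascii=False) + "\n")


def read_corpus_jsonl(path: str | Path) -> list[Article]:
    articles = []
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            if not line.strip():
                continue
            rec = json.loads(line)
            sentences = tuple(
                Sentence(i, tuple(s["tokens"]), s.get("raw_text", " ".join(s["tokens"])))
                for i, s in enumerate(rec["sentences"])
            )
            articles.append(
                Article(doc_id=rec["doc_id"], topic=rec.get("topic", "other"),
                        sentences=sentences)
            )
    return articles
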