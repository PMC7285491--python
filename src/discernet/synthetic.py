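"""Synthetic HTML corpora with plantable quality signals.

Real corpora for this task pair each article with per-criterion pass/fail
outcomes that hinge on a handful of tell-tale sentences — citation lines for
"are sources given?", "Review Date:" lines for "is it dated?", sentences
about mechanism, benefits and side effects for the treatment criteria. The
generator emulates exactly that structure: an article passes a criterion iff
at least one trigger sentence from that criterion's template list was planted
in it, and ground-truth trigger positions are recorded so localization can be
scored exhaustively.

Filler prose is order-1 Markov text over a small embedded word list, kept
disjoint from the templates' signature vocabulary so the planted signal is
the only usable one (the Bayes-optimal rule is "trigger present").
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .corpus_io import (
    Article,
    SegmenterConfig,
    extract_sentences,
    tokenize,
)
from .errors import GeneratorConsistencyError

# Default positive-class prevalence per criterion, matching the averages of
# the three disease topics in the study corpus this generator emulates.
DEFAULT_PREVALENCE: dict[str, float] = {
    "Q4": 0.14,  # sources / references
    "Q5": 0.23,  # dated content
    "Q9": 0.55,  # how treatment works
    "Q10": 0.78,  # treatment benefits
    "Q11": 0.37,  # treatment risks
}

# Original template sentences; the *kind* of signal (citations, review dates,
# mechanism / benefit / side-effect phrasing) mirrors what attention models
# latch onto in real articles. Templates contain no internal ". " so each
# survives sentence segmentation as exactly one sentence.
DEFAULT_TRIGGER_TEMPLATES: dict[str, tuple[str, ...]] = {
    "Q4": (
        "Journal of Clinical Practice 2013; 31(2): 112-119.",
        "Annals of General Medicine 2010; 170(5): 441-448.",
        "International Oncology Reports 2011; 377(9770): 1019-1031.",
        "Quarterly Rheumatology Review 2012; 366(26): 2443-2454.",
    ),
    "Q5": (
        "Review Date: 4/12/2014.",
        "Last Revised: 10/03/2015.",
        "Page last updated: 7-Jan-2016.",
        "Article updated: 22 March 2013.",
    ),
    "Q9": (
        "This treatment works by blocking the enzyme that tells cells to multiply.",
        "The drug works by damping the immune signals that drive the inflammation.",
        "During the procedure the surgeon removes the damaged tissue so recovery can begin.",
        "The therapy works by retraining unhelpful thought patterns across weekly sessions.",
    ),
    "Q10": (
        "The main benefit of this treatment is a lower chance of the disease returning.",
        "Patients often benefit from reduced pain and better daily functioning within weeks.",
        "A clear benefit is that symptoms improve for most people who complete the course.",
        "Another benefit is that the dose can be tapered once improvement is stable.",
    ),
    "Q11": (
        "Common side effects include nausea, dizziness, and fatigue.",
        "Risks of this treatment include bleeding, infection, and allergic reaction.",
        "Side effects such as drowsiness and dry mouth may occur at higher doses.",
        "Serious risks are rare but can include damage to nearby organs.",
    ),
}

# Embedded filler corpus for the Markov noise model. Deliberately avoids the
# templates' signature vocabulary (works, benefit, side, effects, risks,
# review, revised, updated, journal names, dates).
_FILLER_SENTENCES = (
    "many people visit their doctor when symptoms first appear",
    "a healthy diet and regular exercise support overall wellbeing",
    "your care team can answer questions about daily management",
    "some conditions develop slowly over months or years",
    "talking with family members can make decisions easier",
    "clinics offer appointments during the week and some weekends",
    "keeping a symptom diary helps the doctor understand patterns",
    "support groups meet in person and online across the country",
    "sleep and stress both influence how people feel day to day",
    "a nurse may call to check how things are going at home",
    "written plans help patients remember the next steps",
    "most hospitals provide interpreters when they are needed",
    "asking questions during the visit is always encouraged",
    "small changes in routine can make a large difference over time",
    "the information on this page is intended for a general audience",
    "every person responds to care in a slightly different way",
    "community programs can help with transport to appointments",
    "pharmacists can explain how and when to take each medicine",
)


def _signature_tokens(template: str) -> set[str]:
    return {t.lower() for t in tokenize(template) if t.isalpha()}


class _MarkovNoise:
    """Order-1 Markov sentence generator over the embedded filler corpus."""

    def __init__(self, sentences: Sequence[str]):
        self.starts: list[str] = []
        self.chain: dict[str, list[str]] = {}
        for sent in sentences:
            words = sent.split()
            self.starts.append(words[0])
            for a, b in zip(words, words[1:]):
                self.chain.setdefault(a, []).append(b)
        self.vocabulary = {w for s in sentences for w in s.split()}

    def sentence(self, rng: np.random.Generator, min_len: int = 6,
                 max_len: int = 14) -> str:
        length = int(rng.integers(min_len, max_len + 1))
        word = self.starts[int(rng.integers(len(self.starts)))]
        words = [word]
        while len(words) < length:
            nxt = self.chain.get(word)
            if not nxt:
                word = self.starts[int(rng.integers(len(self.starts)))]
            else:
                word = nxt[int(rng.integers(len(nxt)))]
            words.append(word)
        return words[0].capitalize() + " " + " ".join(words[1:]) + "."


@dataclass
class GeneratorConfig:
    n_articles: int = 100
    sentences_mean: float = 130.0
    sentences_sd: float = 15.0
    sentences_min: int = 20
    sentences_max: int = 200
    prevalence_per_criterion: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_PREVALENCE)
    )
    trigger_templates: Mapping[str, Sequence[str]] = field(
        default_factory=lambda: {k: tuple(v) for k, v in DEFAULT_TRIGGER_TEMPLATES.items()}
    )
    triggers_per_positive: tuple[int, int] = (1, 2)  # inclusive range
    noise_sentences: Sequence[str] = _FILLER_SENTENCES
    topics: Sequence[str] = ("breast_cancer", "arthritis", "depression")
    seed: int = 0

    def validate(self) -> None:
        for crit, p in self.prevalence_per_criterion.items():
            if not 0 < p < 1:
                raise ValueError(f"prevalence for {crit} must be in (0,1), got {p}")
            if not self.trigger_templates.get(crit):
                raise ValueError(f"criterion {crit} enabled without templates")
        noise_vocab = {w.lower() for s in self.noise_sentences for w in s.split()}
        for crit, templates in self.trigger_templates.items():
            for tpl in templates:
                sig = _signature_tokens(tpl)
                if sig and sig <= noise_vocab:
                    raise GeneratorConsistencyError(
                        f"{crit} template {tpl!r} is fully reproducible from "
                        f"the noise vocabulary"
                    )


@dataclass
class SyntheticDocument:
    doc_id: str
    topic: str
    html: str
    sentences: list[str]
    # criterion -> sentence indices where its triggers sit (empty = fail)
    trigger_indices: dict[str, list[int]]


@dataclass
class SyntheticCorpus:
    documents: list[SyntheticDocument]
    labels: pd.DataFrame  # doc_id, topic, criterion, rater1_score, rater2_score

    def triggers(self) -> dict[str, dict[str, list[int]]]:
        return {d.doc_id: d.trigger_indices for d in self.documents}


_NAV_CHROME = (
    '<nav><ul><li><a href="/home">Home</a></li>'
    '<li><a href="/topics">Topics</a></li></ul></nav>'
    "<script>var tracker = 1;</script>"
)


def _render_html(title: str, sentences: Sequence[str]) -> str:
    body = "\n".join(f"<p>{s}</p>" for s in sentences)
    return (
        f"<html><head><title>{title}</title><style>p{{margin:0}}</style></head>"
        f"<body>{_NAV_CHROME}\n{body}\n</body></html>"
    )


def generate_corpus(config: GeneratorConfig) -> SyntheticCorpus:
    """Generate labeled articles: per criterion, pass ⇔ at least one trigger
    sentence planted. Deterministic under ``config.seed``; trigger positions
    are the indices in the final sentence list (and therefore in the
    sentence list recovered by HTML preprocessing)."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    noise = _MarkovNoise(config.noise_sentences)
    criteria = sorted(config.prevalence_per_criterion)

    documents: list[SyntheticDocument] = []
    label_rows = []
    for i in range(config.n_articles):
        doc_id = f"syn{i:04d}"
        topic = config.topics[int(rng.integers(len(config.topics)))]
        n_sent = int(np.clip(
            round(rng.normal(config.sentences_mean, config.sentences_sd)),
            config.sentences_min, config.sentences_max,
        ))
        sentences: list[tuple[str, str | None]] = [
            (noise.sentence(rng), None) for _ in range(n_sent)
        ]
        passing: dict[str, bool] = {}
        for crit in criteria:
            is_pass = bool(rng.random() < config.prevalence_per_criterion[crit])
            passing[crit] = is_pass
            if is_pass:
                lo, hi = config.triggers_per_positive
                templates = config.trigger_templates[crit]
                for _ in range(int(rng.integers(lo, hi + 1))):
                    tpl = templates[int(rng.integers(len(templates)))]
                    pos = int(rng.integers(len(sentences) + 1))
                    sentences.insert(pos, (tpl, crit))
        texts = [s for s, _ in sentences]
        trigger_indices: dict[str, list[int]] = {c: [] for c in criteria}
        for idx, (_, crit) in enumerate(sentences):
            if crit is not None:
                trigger_indices[crit].append(idx)
        for crit in criteria:
            if passing[crit]:
                score = lambda: int(rng.integers(3, 6))
            else:
                score = lambda: int(rng.integers(1, 3))
            label_rows.append({
                "doc_id": doc_id, "topic": topic, "criterion": crit,
                "rater1_score": score(), "rater2_score": score(),
            })
        documents.append(SyntheticDocument(
            doc_id=doc_id, topic=topic,
            html=_render_html(f"Synthetic article {doc_id}", texts),
            sentences=texts, trigger_indices=trigger_indices,
        ))
    labels = pd.DataFrame(
        label_rows, columns=["doc_id", "topic", "criterion",
                             "rater1_score", "rater2_score"]
    )
    return SyntheticCorpus(documents=documents, labels=labels)


def write_corpus(corpus: SyntheticCorpus, out_dir: str | Path) -> None:
    """Materialize a generated corpus as .html files + labels.csv +
    triggers.json (ground truth)."""
    import json

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for doc in corpus.documents:
        (out / f"{doc.doc_id}.html").write_text(doc.html, encoding="utf-8")
    corpus.labels.to_csv(out / "labels.csv", index=False)
    (out / "triggers.json").write_text(
        json.dumps(corpus.triggers(), indent=1), encoding="utf-8"
    )


def corpus_articles(corpus: SyntheticCorpus,
                    segmenter_config: SegmenterConfig | None = None) -> list[Article]:
    """Run every generated document through the HTML preprocessing path."""
    articles = []
    for doc in corpus.documents:
        sentences = extract_sentences(doc.html, segmenter_config)
        articles.append(Article(doc_id=doc.doc_id, topic=doc.topic,
                                sentences=tuple(sentences), raw_html=doc.html))
    return articles


# ---------------------------------------------------------------------------
# Separable benchmark task


@dataclass
class SeparableTask:
    """A low-noise single-criterion task whose Bayes-optimal rule is
    "trigger sentence present": balanced classes, short documents, one or two
    strong triggers per positive."""

    criterion: str
    train_articles: list[Article]
    train_labels: np.ndarray
    val_articles: list[Article]
    val_labels: np.ndarray
    test_articles: list[Article]
    test_labels: np.ndarray
    trigger_indices: dict[str, list[int]]  # doc_id -> planted positions
    templates: tuple[str, ...]

    def bayes_rule(self, article: Article) -> int:
        """Ground-truth rule: pass iff any sentence matches a template."""
        texts = {s.raw_text for s in article.sentences}
        return int(any(t in texts for t in self.templates))


def generate_separable_task(
    n_articles: int = 200,
    criterion: str = "Q5",
    sentences_min: int = 10,
    sentences_max: int = 40,
    prevalence: float = 0.5,
    seed: int = 0,
    permute_labels: bool = False,
) -> SeparableTask:
    """Build train/val/test splits (70/10/20, stratified by construction of
    a balanced prevalence) for the signal-recovery benchmark. With
    ``permute_labels`` the labels are shuffled after generation, destroying
    the signal while keeping the marginal class balance."""
    config = GeneratorConfig(
        n_articles=n_articles,
        sentences_mean=(sentences_min + sentences_max) / 2,
        sentences_sd=(sentences_max - sentences_min) / 4,
        sentences_min=sentences_min,
        sentences_max=sentences_max,
        prevalence_per_criterion={criterion: prevalence},
        trigger_templates={criterion: DEFAULT_TRIGGER_TEMPLATES[criterion]},
        seed=seed,
    )
    corpus = generate_corpus(config)
    articles = corpus_articles(corpus)
    label_map = {
        row.doc_id: int(row.rater1_score >= 3)
        for row in corpus.labels.itertuples()
    }
    labels = np.array([label_map[a.doc_id] for a in articles])
    rng = np.random.default_rng(seed + 1)
    if permute_labels:
        labels = labels[rng.permutation(len(labels))]
    order = rng.permutation(len(articles))
    n_test = int(round(0.2 * len(articles)))
    n_val = int(round(0.1 * len(articles)))
    test_idx = order[:n_test]
    val_idx = order[n_test:n_test + n_val]
    train_idx = order[n_test + n_val:]
    pick = lambda idx: [articles[i] for i in idx]
    return SeparableTask(
        criterion=criterion,
        train_articles=pick(train_idx), train_labels=labels[train_idx],
        val_articles=pick(val_idx), val_labels=labels[val_idx],
        test_articles=pick(test_idx), test_labels=labels[test_idx],
        trigger_indices={d.doc_id: d.trigger_indices[criterion]
                         for d in corpus.documents},
        templates=tuple(DEFAULT_TRIGGER_TEMPLATES[criterion]),
    )
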