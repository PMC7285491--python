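"""Generate a synthetic labeled corpus and run it through preprocessing.

Each article is HTML with navigation/script chrome plus one sentence per
paragraph; an article passes a criterion exactly when a criterion-specific
trigger sentence (citation line, review date, mechanism/benefit/risk
sentence) was planted in it.
"""

from discernet.corpus_io import extract_sentences
from discernet.synthetic import GeneratorConfig, generate_corpus

config = GeneratorConfig(n_articles=6, sentences_mean=18, sentences_sd=4,
                         sentences_min=10, sentences_max=30, seed=7)
corpus = generate_corpus(config)

print(f"articles: {len(corpus.documents)}")
print(f"label rows (article x criterion): {len(corpus.labels)}")
print(corpus.labels.head(10).to_string(index=False))

doc = corpus.documents[0]
sentences = extract_sentences(doc.html)
print(f"\n{doc.doc_id} ({doc.topic}): {len(sentences)} sentences recovered "
      f"from HTML, {sum(len(s.tokens) for s in sentences)} tokens")
for crit, idxs in doc.trigger_indices.items():
    for i in idxs:
        print(f"  planted {crit} trigger at sentence {i}: "
              f"{sentences[i].raw_text!r}")
# The recovered sentence list matches the generated one exactly, so the
# recorded trigger indices are valid positions in the preprocessed article.
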