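"""Inspect which sentences the attention model used as evidence.

After training, the per-sentence attention weights of the most confidently
predicted documents are an explanation: for the dated-content criterion they
should point at the planted "Review Date" style sentences.
"""

from discernet.embeddings import EmbedderConfig, make_embedder
from discernet.evaluation import extract_explanations
from discernet.model import ModelConfig, forward, init_parameters
from discernet.synthetic import generate_separable_task
from discernet.training import EncodedDataset, TrainingConfig, train_model

task = generate_separable_task(n_articles=120, sentences_min=8,
                               sentences_max=25, seed=0)
embedder = make_embedder(EmbedderConfig(dim=16, seed=0))
encode = lambda arts, labs: EncodedDataset.from_articles(arts, labs, embedder)

model_config = ModelConfig(d_w=16, d_h_sent=16, d_h_doc=16, seed=1)
params, _ = train_model(
    encode(task.train_articles, task.train_labels),
    encode(task.val_articles, task.val_labels),
    init_parameters(model_config),
    TrainingConfig(max_epochs=15, learning_rate=3e-3, seed=1), model_config,
)

preds, encodings = [], []
for art in task.test_articles:
    pred, enc = forward(art, params, embedder=embedder, variant="HEA",
                        criterion=task.criterion)
    preds.append(pred)
    encodings.append(enc)

for e in extract_explanations(encodings, preds, task.test_articles,
                              k_docs=3, k_sents=3):
    print(f"\n{e.doc_id} (confidence {e.confidence:.3f}):")
    for s in e.top_sentences:
        marker = ("<- planted trigger"
                  if s.sentence_index in task.trigger_indices[e.doc_id] else "")
        print(f"  alpha={s.attention_weight:.3f} [{s.sentence_index:3d}] "
              f"{s.raw_text[:60]!r} {marker}")
# High-alpha sentences should be the planted date lines in passing articles;
# the weights are the model's own softmax attention, not a post-hoc score.
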