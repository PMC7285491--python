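"""Train a small hierarchical attention model on the separable benchmark.

The task: 120 short articles, balanced pass/fail on the "is it dated?"
criterion, where passing articles contain a planted "Review Date: ..." style
sentence. A model that learns the rule should approach perfect test accuracy.
"""

import numpy as np
from sklearn.metrics import accuracy_score, f1_score

from discernet.embeddings import EmbedderConfig, make_embedder
from discernet.model import ModelConfig, init_parameters
from discernet.synthetic import generate_separable_task
from discernet.training import (
    EncodedDataset, TrainingConfig, predict_probs, train_model,
)

task = generate_separable_task(n_articles=120, sentences_min=8,
                               sentences_max=25, seed=0)
embedder = make_embedder(EmbedderConfig(dim=16, seed=0))
encode = lambda arts, labs: EncodedDataset.from_articles(arts, labs, embedder)
train = encode(task.train_articles, task.train_labels)
val = encode(task.val_articles, task.val_labels)
test = encode(task.test_articles, task.test_labels)

model_config = ModelConfig(d_w=16, d_h_sent=16, d_h_doc=16, seed=1)
params, trace = train_model(
    train, val, init_parameters(model_config),
    TrainingConfig(max_epochs=15, learning_rate=3e-3, seed=1), model_config,
)

print(f"best epoch {trace.best_epoch} (validation F1 {trace.best_val_f1:.3f})")
preds = predict_probs(params, test, model_config).argmax(1)
print(f"test accuracy {accuracy_score(test.labels, preds):.3f}, "
      f"F1-macro {f1_score(test.labels, preds, average='macro'):.3f}")
# Accuracy near 1.0 means the model recovered the planted trigger rule from
# raw token embeddings alone; ~0.5 would mean it learned nothing.
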