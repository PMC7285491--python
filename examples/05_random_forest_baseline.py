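"""The traditional baseline on the same benchmark: TF-IDF bag of words plus
engineered document features into a random forest.

Because pass/fail hinges on trigger sentences with distinctive vocabulary,
a bag-of-words model is also strong here; the comparison mirrors how a
classical pipeline stacks up against the hierarchical encoders.
"""

import numpy as np
from sklearn.metrics import accuracy_score, f1_score

from discernet.baseline import (
    RandomForestConfig, engineered_features, run_baseline_fold,
)
from discernet.synthetic import generate_separable_task

task = generate_separable_task(n_articles=120, sentences_min=8,
                               sentences_max=25, seed=0)

print("engineered features of one test article:")
for name, value in engineered_features(task.test_articles[0]).items():
    print(f"  {name} = {value}")

run = run_baseline_fold(
    task.train_articles + task.val_articles,
    np.concatenate([task.train_labels, task.val_labels]),
    task.test_articles, criterion=task.criterion,
    rf_config=RandomForestConfig(seed=0),
)
preds = np.array([p.predicted_label for p in run.predictions])
print(f"\nrandom forest: test accuracy "
      f"{accuracy_score(task.test_labels, preds):.3f}, F1-macro "
      f"{f1_score(task.test_labels, preds, average='macro'):.3f}")
# The baseline shares the Prediction schema with the neural models, so the
# same evaluation and coverage code applies to both.
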