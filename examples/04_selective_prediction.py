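"""Trade coverage for accuracy with confidence thresholds.

A deployed rater can abstain on low-confidence articles (sending them to a
human) instead of guessing. Sweeping the coverage target shows the
accuracy/coverage trade-off and the confidence threshold realizing each
point; at coverage 1.0 the threshold is 0.5 and nothing is abstained.
"""

import numpy as np

from discernet.evaluation import coverage_curve

rng = np.random.default_rng(0)
n = 200
truths = rng.integers(0, 2, n)
# emulate a model that is right more often when it is more confident
confidence = 0.5 + 0.5 * rng.random(n)
correct = rng.random(n) < confidence
preds = np.where(correct, truths, 1 - truths)

curve = coverage_curve(preds, truths, confidence,
                       grid=[1.0, 0.9, 0.8, 0.7, 0.6, 0.5])
print(curve.to_frame().to_string(index=False))
# Accuracy rises as coverage falls: restricting predictions to confident
# cases buys correctness at the price of answering fewer articles.
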