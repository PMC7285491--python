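# discernet

Automatic quality rating of online health articles against **Brief DISCERN**
criteria, using hierarchical GRU encoders with sentence-level attention.

Lay readers routinely consult web articles about treatments for breast
cancer, arthritis, or depression, and most cannot judge whether an article
cites its sources, states when it was written, or explains how a treatment
works, what it promises and what it risks. The DISCERN instrument
operationalizes those judgments as rater questions; this package trains one
binary classifier per criterion (Q4 sources, Q5 date, Q9 mechanism, Q10
benefits, Q11 risks) that predicts pass/fail for an article and — because
the evidence for most criteria is a handful of tell-tale sentences — points
at the sentences that drove the decision.

## The model

An article is a sequence of sentences, each a sequence of tokens with frozen
embeddings `w̄_t ∈ R^{D_w}`. Two stacked bidirectional GRU encoders build the
document representation:

* **SentEncoder** runs a GRU over each sentence's tokens in both directions
  (update gate `z_t = σ(W_z w_t + U_z h_{t-1} + b_z)`, reset gate
  `r_t = σ(W_r w_t + U_r h_{t-1} + b_r)`, candidate
  `h̃_t = φ(W_h w_t + r_t ⊙ U_h h_{t-1} + b_h)`,
  `h_t = (1−z_t) ⊙ h̃_t + z_t ⊙ h_{t-1}`) and joins the final forward and
  backward states (concatenation or sum) into a sentence vector `S̄_i`.
* **DocEncoder** runs a bidirectional GRU over `[S̄_1 … S̄_T]`, joining the
  two states **per position** into outputs `O = [l̄_1 … l̄_T]`.
* **Attention (HEA)**: a trainable query `q̄` scores each position —
  scaled dot product `q̄ᵀ l̄_i / √D_l` or additive `q̄ᵀ tanh(W_ql l̄_i)` —
  softmax normalizes the scores into weights `α`, and the document vector is
  `z̄ = Σ_i α_i l̄_i`. The **HE** variant replaces attention with mean
  pooling of `O`.
* A softmax classifier `ŷ = softmax(W z̄ + b)` yields P(fail), P(pass).

Training minimizes class-weighted cross-entropy plus L2,
`L(θ) = (1/N) Σ_j w_j ℓ_j + (λ/2)‖θ‖²`, with Adam, per-epoch validation
F1-macro checkpointing (best epoch kept, earliest on ties), stratified
5-fold cross-validation, and inverse-class-frequency example weights. The
`α` weights double as explanations: the top-attended sentences of the most
confident predictions. A selective-prediction analysis converts softmax
confidence into coverage/accuracy trade-offs, and a TF-IDF + engineered
features random-forest baseline shares the prediction schema and evaluation
code.

The neural core (GRU cell, encoders, attention, classifier and the
reverse-mode autodiff tape behind training) is implemented in numpy within
this package; standard steps (HTML parsing, TF-IDF, random forest, CV
splitting, metrics) use lxml and scikit-learn.

Because no rated article corpus is distributed, the package ships a
synthetic-corpus generator whose pass/fail labels are *constructed* from
plantable sentence signals (citation lines, "Review Date:" lines,
mechanism/benefit/risk sentences) at realistic prevalences — so signal
recovery, attention localization, and coverage behavior are all checkable
against known ground truth.

## Worked example

```bash
python examples/02_train_hea.py
```

trains a 16-dimensional HEA model on 120 generated articles (the
dated-content criterion) and prints:

```
best epoch 14 (validation F1 0.748)
test accuracy 0.917, F1-macro 0.911
```

meaning the model largely recovered the planted "Review Date …" rule on
held-out articles (this example is deliberately small; the benchmark run in
`scripts/acceptance.py` uses more data and scores higher).
`examples/03_attention_explanations.py` then shows the evidence, e.g.:

```
syn0005 (confidence 1.000):
  alpha=0.066 [  2] 'Article updated: 22 March 2013.' <- planted trigger
  alpha=0.064 [  7] 'Last Revised: 10/03/2015.' <- planted trigger
  alpha=0.061 [  8] 'Every person and online across the.'
```

— the planted trigger sentences rank highest among a passing article's
attention weights. The other
examples cover corpus generation/preprocessing, the coverage/accuracy
trade-off, and the random-forest baseline. The `discernet` CLI
(`preprocess`, `generate`, `train`, `tune`, `baseline`, `evaluate`,
`coverage`, `explain`) wraps the same library functions for shell use.

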