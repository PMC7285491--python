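"""The math core checked against independent naive-loop oracles.

Every encoder and attention operation is re-derived here with explicit
per-element python loops (no vectorized shortcuts shared with the
implementation) and compared on many random small instances, alongside the
closed-form identities the architecture must satisfy.
"""

import math

import numpy as np
import pytest

from discernet.corpus_io import Article, Sentence
from discernet.embeddings import EmbedderConfig, make_embedder
from discernet.errors import (
    EmptySequenceError,
    NumericalError,
    ShapeError,
)
from discernet.model import (
    AttentionParameters,
    GruParameters,
    ModelConfig,
    attention_score,
    attention_weights,
    classify,
    document_vector,
    encode_document,
    encode_sentence,
    forward,
    gru_step,
    init_parameters,
    load_checkpoint,
    mean_pool,
    save_checkpoint,
)

N_INSTANCES = 120
TOL = 1e-6


def random_gru(rng, d_h, d_in, phi="tanh"):
    g = lambda *s: rng.standard_normal(s)
    return GruParameters(
        W_z=g(d_h, d_in), W_r=g(d_h, d_in), W_h=g(d_h, d_in),
        U_z=g(d_h, d_h), U_r=g(d_h, d_h), U_h=g(d_h, d_h),
        b_z=g(d_h), b_r=g(d_h), b_h=g(d_h), phi=phi,
    )


# ---------------------------------------------------------------------------
# Naive scalar-arithmetic oracles


def oracle_gru_step(w, h_prev, p):
    d_h = len(h_prev)
    sig = lambda x: 1.0 / (1.0 + math.exp(-x))
    act = math.tanh if p.phi == "tanh" else lambda x: max(x, 0.0)
    h = np.zeros(d_h)
    for i in range(d_h):
        z = sig(sum(p.W_z[i, j] * w[j] for j in range(len(w)))
                + sum(p.U_z[i, j] * h_prev[j] for j in range(d_h)) + p.b_z[i])
        r = sig(sum(p.W_r[i, j] * w[j] for j in range(len(w)))
                + sum(p.U_r[i, j] * h_prev[j] for j in range(d_h)) + p.b_r[i])
        uh = sum(p.U_h[i, j] * h_prev[j] for j in range(d_h))
        h_tilde = act(sum(p.W_h[i, j] * w[j] for j in range(len(w)))
                      + r * uh + p.b_h[i])
        h[i] = (1.0 - z) * h_tilde + z * h_prev[i]
    return h


def oracle_run(seq, p):
    h = np.zeros(p.d_h)
    states = []
    for t in range(len(seq)):
        h = oracle_gru_step(seq[t], h, p)
        states.append(h)
    return states


def oracle_softmax(scores):
    m = max(scores)
    e = [math.exp(s - m) for s in scores]
    tot = sum(e)
    return np.array([x / tot for x in e])


class TestGruStep:
    def test_zero_parameters_halve_state(self):
        d_h = 2
        p = GruParameters(*(np.zeros((d_h, 3)) for _ in range(3)),
                          *(np.zeros((d_h, d_h)) for _ in range(3)),
                          *(np.zeros(d_h) for _ in range(3)))
        h = gru_step(np.ones(3), np.array([0.4, -0.2]), p)
        # zero weights: z = r = 0.5, candidate = 0, so h = 0.5 * h_prev
        assert np.allclose(h, [0.2, -0.1], atol=1e-12)

    def test_zero_state_fixed_point(self):
        p = GruParameters(*(np.zeros((2, 3)) for _ in range(3)),
                          *(np.zeros((2, 2)) for _ in range(3)),
                          *(np.zeros(2) for _ in range(3)))
        assert np.allclose(gru_step(np.zeros(3), np.zeros(2), p), 0.0)

    @pytest.mark.parametrize("phi", ["tanh", "relu"])
    def test_matches_scalar_oracle(self, rng, phi):
        for _ in range(N_INSTANCES):
            d_h, d_in = int(rng.integers(1, 9)), int(rng.integers(1, 9))
            p = random_gru(rng, d_h, d_in, phi)
            w, h_prev = rng.standard_normal(d_in), rng.standard_normal(d_h)
            assert np.allclose(gru_step(w, h_prev, p),
                               oracle_gru_step(w, h_prev, p), atol=TOL)

    def test_shape_mismatch(self, rng):
        p = random_gru(rng, 3, 4)
        with pytest.raises(ShapeError):
            gru_step(np.zeros(5), np.zeros(3), p)

    def test_tanh_states_bounded(self, rng):
        # with phi=tanh and h0=0, every state is a convex combination of
        # values in [-1, 1], so coordinates never escape it
        for _ in range(20):
            p = random_gru(rng, 4, 3)
            seq = 5 * rng.standard_normal((int(rng.integers(1, 11)), 3))
            h = np.zeros(4)
            for t in range(seq.shape[0]):
                h = gru_step(seq[t], h, p)
                assert np.all(np.abs(h) <= 1.0 + 1e-12)


class TestSentenceEncoder:
    def test_single_token_symmetry(self, rng):
        p = random_gru(rng, 3, 4)
        emb = rng.standard_normal((1, 4))
        s = encode_sentence(emb, p, p, join="concat")
        assert np.allclose(s[:3], s[3:])

    def test_dimensionality_contract(self, rng):
        fwd, bwd = random_gru(rng, 5, 4), random_gru(rng, 5, 4)
        emb = rng.standard_normal((3, 4))
        assert encode_sentence(emb, fwd, bwd, "concat").shape == (10,)
        assert encode_sentence(emb, fwd, bwd, "sum").shape == (5,)

    def test_matches_unrolled_oracle(self, rng):
        for _ in range(N_INSTANCES):
            d_h, d_w = int(rng.integers(1, 9)), int(rng.integers(1, 9))
            t_s = int(rng.integers(1, 11))
            fwd, bwd = random_gru(rng, d_h, d_w), random_gru(rng, d_h, d_w)
            emb = rng.standard_normal((t_s, d_w))
            expected = np.concatenate([
                oracle_run(emb, fwd)[-1], oracle_run(emb[::-1], bwd)[-1]])
            assert np.allclose(encode_sentence(emb, fwd, bwd, "concat"),
                               expected, atol=TOL)

    def test_empty_sentence_rejected(self, rng):
        p = random_gru(rng, 2, 3)
        with pytest.raises(EmptySequenceError):
            encode_sentence(np.empty((0, 3)), p, p)


class TestDocumentEncoder:
    def test_singleton_sequence(self, rng):
        p = random_gru(rng, 3, 4)
        O = encode_document([rng.standard_normal(4)], p, p)
        assert len(O) == 1

    def test_order_sensitivity(self, rng):
        # fixed counterexample: permuting sentences changes the outputs
        p, q = random_gru(rng, 3, 4), random_gru(rng, 3, 4)
        vecs = [rng.standard_normal(4) for _ in range(3)]
        O1 = encode_document(vecs, p, q)
        O2 = encode_document([vecs[2], vecs[0], vecs[1]], p, q)
        assert not np.allclose(np.stack(O1), np.stack(O2))

    @pytest.mark.parametrize("join", ["concat", "sum"])
    def test_matches_unrolled_oracle(self, rng, join):
        for _ in range(N_INSTANCES // 2):
            d_h, d_s = int(rng.integers(1, 9)), int(rng.integers(1, 9))
            t_doc = int(rng.integers(1, 11))
            fwd, bwd = random_gru(rng, d_h, d_s), random_gru(rng, d_h, d_s)
            vecs = [rng.standard_normal(d_s) for _ in range(t_doc)]
            O = encode_document(vecs, fwd, bwd, join)
            f_states = oracle_run(np.stack(vecs), fwd)
            b_states = oracle_run(np.stack(vecs)[::-1], bwd)[::-1]
            for i in range(t_doc):
                if join == "concat":
                    expected = np.concatenate([f_states[i], b_states[i]])
                else:
                    expected = f_states[i] + b_states[i]
                assert np.allclose(O[i], expected, atol=TOL)

    def test_empty_document_rejected(self, rng):
        p = random_gru(rng, 2, 3)
        with pytest.raises(EmptySequenceError):
            encode_document([], p, p)


class TestAttention:
    def test_scaled_dot_forced_arithmetic(self):
        p = AttentionParameters(np.ones(4), None, "scaled_dot")
        assert attention_score(np.ones(4), np.ones(4), p) == pytest.approx(2.0)

    def test_scaled_dot_orthogonal(self):
        p = AttentionParameters(np.array([1.0, 0.0]), None, "scaled_dot")
        assert attention_score(p.query, np.array([0.0, 5.0]), p) == 0.0

    def test_additive_zero_map_collapses(self, rng):
        q = rng.standard_normal(3)
        p = AttentionParameters(q, np.zeros((3, 5)), "additive")
        for _ in range(10):
            assert attention_score(q, rng.standard_normal(5), p) == 0.0

    def test_both_variants_match_formula(self, rng):
        for _ in range(N_INSTANCES):
            d_l, d_q = int(rng.integers(1, 9)), int(rng.integers(1, 9))
            q, l = rng.standard_normal(d_l), rng.standard_normal(d_l)
            p = AttentionParameters(q, None, "scaled_dot")
            expected = sum(q[i] * l[i] for i in range(d_l)) / math.sqrt(d_l)
            assert attention_score(q, l, p) == pytest.approx(expected, abs=TOL)
            q2 = rng.standard_normal(d_q)
            W = rng.standard_normal((d_q, d_l))
            p2 = AttentionParameters(q2, W, "additive")
            expected2 = sum(
                q2[i] * math.tanh(sum(W[i, j] * l[j] for j in range(d_l)))
                for i in range(d_q))
            assert attention_score(q2, l, p2) == pytest.approx(expected2, abs=TOL)

    def test_weights_uniform_for_equal_scores(self):
        assert np.allclose(attention_weights(np.zeros(4)), 0.25)

    def test_weights_singleton(self):
        assert np.allclose(attention_weights(np.array([3.7])), [1.0])

    def test_weights_closed_form(self):
        alpha = attention_weights(np.array([0.0, math.log(2.0)]))
        assert np.allclose(alpha, [1 / 3, 2 / 3])

    def test_weights_shift_invariant_and_normalized(self, rng):
        for _ in range(50):
            s = rng.standard_normal(int(rng.integers(1, 11))) * 10
            alpha = attention_weights(s)
            assert abs(alpha.sum() - 1.0) < 1e-6
            assert np.all(alpha > 0)
            assert np.allclose(alpha, attention_weights(s + 123.4), atol=1e-9)

    def test_nonfinite_scores_rejected(self):
        with pytest.raises(NumericalError):
            attention_weights(np.array([0.0, np.inf]))

    def test_weights_match_oracle(self, rng):
        for _ in range(N_INSTANCES):
            s = rng.standard_normal(int(rng.integers(1, 11)))
            assert np.allclose(attention_weights(s), oracle_softmax(s), atol=TOL)


class TestPooling:
    def test_uniform_alpha_equals_mean(self, rng):
        O = [rng.standard_normal(4) for _ in range(5)]
        z = document_vector(O, np.full(5, 0.2))
        assert np.allclose(z, mean_pool(O), atol=1e-12)

    def test_one_hot_selects(self, rng):
        O = [rng.standard_normal(4) for _ in range(3)]
        assert np.allclose(document_vector(O, np.array([0, 1, 0])), O[1])

    def test_weighted_sum_oracle(self, rng):
        O = [rng.standard_normal(4) for _ in range(3)]
        alpha = attention_weights(rng.standard_normal(3))
        expected = np.zeros(4)
        for i in range(3):
            for j in range(4):
                expected[j] += alpha[i] * O[i][j]
        assert np.allclose(document_vector(O, alpha), expected, atol=TOL)

    def test_mean_pool_singleton_and_cancellation(self, rng):
        v = rng.standard_normal(4)
        assert np.allclose(mean_pool([v]), v)
        assert np.allclose(mean_pool([v, -v]), 0.0)

    def test_length_mismatch(self, rng):
        with pytest.raises(ShapeError):
            document_vector([rng.standard_normal(3)], np.array([0.5, 0.5]))

    def test_mean_pool_empty(self):
        with pytest.raises(EmptySequenceError):
            mean_pool([])


class TestClassifier:
    def test_zero_logits_uniform(self):
        assert np.allclose(classify(np.zeros(3), np.zeros((2, 3)), np.zeros(2)), 0.5)

    def test_closed_form(self):
        W = np.zeros((2, 1))
        b = np.array([0.0, math.log(3.0)])
        assert np.allclose(classify(np.zeros(1), W, b), [0.25, 0.75])

    def test_normalization_sweep(self, rng):
        for _ in range(N_INSTANCES):
            d = int(rng.integers(1, 9))
            probs = classify(rng.standard_normal(d),
                             rng.standard_normal((2, d)), rng.standard_normal(2))
            assert abs(probs.sum() - 1.0) < 1e-6
            assert np.all(probs > 0)


class TestForward:
    def _toy_article(self, rng, n_sent=3):
        from conftest import random_article
        return random_article(rng, "toy", n_sentences=n_sent)

    def test_zero_query_hea_equals_he(self, rng):
        cfg = ModelConfig(d_w=8, d_h_sent=4, d_h_doc=4, seed=9)
        params = init_parameters(cfg)
        params.attention.query[:] = 0.0
        emb = make_embedder(EmbedderConfig(dim=8, seed=0))
        art = self._toy_article(rng)
        p_hea, e_hea = forward(art, params, embedder=emb, variant="HEA")
        p_he, e_he = forward(art, params, embedder=emb, variant="HE")
        assert np.array_equal(p_hea.probs, p_he.probs)  # bit-equal
        assert np.allclose(e_hea.alpha, 1.0 / len(art.sentences))
        assert e_he.alpha is None

    def test_eval_mode_deterministic(self, rng):
        cfg = ModelConfig(d_w=8, d_h_sent=4, d_h_doc=3, seed=2, dropout_p=0.5)
        params = init_parameters(cfg)
        emb = make_embedder(EmbedderConfig(dim=8, seed=0))
        art = self._toy_article(rng)
        p1, _ = forward(art, params, embedder=emb, mode="eval")
        p2, _ = forward(art, params, embedder=emb, mode="eval")
        assert p1.probs.tobytes() == p2.probs.tobytes()

    def test_train_mode_dropout_changes_output(self, rng):
        cfg = ModelConfig(d_w=8, d_h_sent=4, d_h_doc=3, seed=2, dropout_p=0.5)
        params = init_parameters(cfg)
        emb = make_embedder(EmbedderConfig(dim=8, seed=0))
        art = self._toy_article(rng)
        p_eval, _ = forward(art, params, embedder=emb, mode="eval")
        p_train, _ = forward(art, params, embedder=emb, mode="train",
                             rng=np.random.default_rng(1))
        assert not np.array_equal(p_eval.probs, p_train.probs)

    def test_end_to_end_matches_composed_oracle(self, rng):
        """3-sentence article vs a fully hand-composed pipeline of oracles."""
        cfg = ModelConfig(d_w=4, d_h_sent=3, d_h_doc=3, seed=5)
        params = init_parameters(cfg)
        emb = make_embedder(EmbedderConfig(dim=4, seed=0))
        art = self._toy_article(rng, n_sent=3)
        pred, enc = forward(art, params, embedder=emb, variant="HEA")

        sent_vecs = []
        for s in art.sentences:
            mats = emb.embed_tokens(s.tokens)
            f = oracle_run(mats, params.sent_fwd)[-1]
            b = oracle_run(mats[::-1], params.sent_bwd)[-1]
            sent_vecs.append(np.concatenate([f, b]))
        f_states = oracle_run(np.stack(sent_vecs), params.doc_fwd)
        b_states = oracle_run(np.stack(sent_vecs)[::-1], params.doc_bwd)[::-1]
        O = [np.concatenate([f, b]) for f, b in zip(f_states, b_states)]
        q = params.attention.query
        scores = [sum(q[i] * l[i] for i in range(len(q))) / math.sqrt(len(q))
                  for l in O]
        alpha = oracle_softmax(scores)
        z = sum(a * l for a, l in zip(alpha, O))
        logits = params.classifier_W @ z + params.classifier_b
        probs = oracle_softmax(logits)
        assert np.allclose(enc.alpha, alpha, atol=TOL)
        assert np.allclose(pred.probs, probs, atol=TOL)

    def test_confidence_in_half_open_interval(self, rng):
        cfg = ModelConfig(d_w=8, d_h_sent=4, d_h_doc=3, seed=2)
        params = init_parameters(cfg)
        emb = make_embedder(EmbedderConfig(dim=8, seed=0))
        pred, _ = forward(self._toy_article(rng), params, embedder=emb)
        assert 0.5 <= pred.confidence < 1.0


def test_checkpoint_round_trip(tmp_path, rng):
    cfg = ModelConfig(d_w=6, d_h_sent=4, d_h_doc=3, seed=11, score_fn="additive")
    params = init_parameters(cfg)
    save_checkpoint(tmp_path / "ck.npz", params, {"criterion": "Q5"})
    back, meta = load_checkpoint(tmp_path / "ck.npz")
    assert meta == {"criterion": "Q5"}
    for a, b in zip(params.arrays(), back.arrays()):
        assert np.array_equal(a, b)
    assert back.attention.score_fn == "additive"
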