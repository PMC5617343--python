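"""The CNN/highway/LSTM primitives against independent brute-force oracles."""

import numpy as np
import pytest
from scipy.special import expit as sigmoid

from threadstance.features import EmbeddingMatrix, Vocabulary
from threadstance.neural_core import (
    ConvFilter,
    DebateNet,
    FilterBank,
    HighwayParams,
    LSTMParams,
    LSTMState,
    NetConfig,
    SoftmaxParams,
    conv_feature_map,
    encode_post,
    highway,
    label_distribution,
    lstm_step,
    max_over_time,
    sequence_nll,
)

RNG = np.random.default_rng(20240617)


# ---------------------------------------------------------------------------
# brute-force oracles (independent of the library code paths)
# ---------------------------------------------------------------------------


def conv_oracle(W, H, b):
    d, l = W.shape
    k = H.shape[1]
    out = []
    for i in range(l - k + 1):
        acc = 0.0
        for r in range(d):
            for c in range(k):
                acc += W[r, i + c] * H[r, c]
        out.append(np.tanh(acc + b))
    return np.array(out)


def highway_oracle(l, A_H, b_H, A_T, b_T):
    h = len(l)
    z = np.empty(h)
    for i in range(h):
        t = 1.0 / (1.0 + np.exp(-(A_T[i] @ l + b_T[i])))
        g = np.tanh(A_H[i] @ l + b_H[i])
        z[i] = t * g + (1.0 - t) * l[i]
    return z


def lstm_oracle(x, h_prev, c_prev, params):
    m = params.m
    h, c = np.empty(m), np.empty(m)
    for r in range(m):
        i = sigmoid(params.U["i"][r] @ x + params.V["i"][r] @ h_prev + params.b["i"][r])
        f = sigmoid(params.U["f"][r] @ x + params.V["f"][r] @ h_prev + params.b["f"][r])
        o = sigmoid(params.U["o"][r] @ x + params.V["o"][r] @ h_prev + params.b["o"][r])
        g = np.tanh(params.U["g"][r] @ x + params.V["g"][r] @ h_prev + params.b["g"][r])
        c[r] = f * c_prev[r] + i * g
        h[r] = o * np.tanh(c[r])
    return h, c


def softmax_oracle(h, Z, b):
    logits = [Z[j] @ h + b[j] for j in range(len(b))]
    e = [np.exp(x - max(logits)) for x in logits]
    return np.array(e) / sum(e)


def random_lstm_params(m, h):
    return LSTMParams(
        U={j: RNG.normal(size=(m, h)) for j in "ifog"},
        V={j: RNG.normal(size=(m, m)) for j in "ifog"},
        b={j: RNG.normal(size=m) for j in "ifog"},
    )


# ---------------------------------------------------------------------------
# convolution + pooling
# ---------------------------------------------------------------------------


class TestConvFeatureMap:
    def test_zero_filter_gives_zero_map(self):
        W = RNG.normal(size=(3, 6))
        f = conv_feature_map(W, ConvFilter(np.zeros((3, 2)), 0.0))
        np.testing.assert_array_equal(f, np.zeros(5))

    def test_width_one_identity_filter(self):
        W = np.array([[1.0, 2.0, 3.0]])
        f = conv_feature_map(W, ConvFilter(np.array([[1.0]]), 0.0))
        np.testing.assert_allclose(f, np.tanh([1.0, 2.0, 3.0]))

    def test_matches_frobenius_double_loop(self):
        for _ in range(20):
            d, l, k = RNG.integers(1, 5), RNG.integers(2, 8), 0
            k = int(RNG.integers(1, l + 1))
            W = RNG.normal(size=(d, l))
            H = RNG.normal(size=(d, k))
            b = float(RNG.normal())
            got = conv_feature_map(W, ConvFilter(H, b))
            np.testing.assert_allclose(got, conv_oracle(W, H, b), atol=1e-10)

    def test_post_shorter_than_filter_rejected(self):
        with pytest.raises(ValueError):
            conv_feature_map(np.ones((2, 2)), ConvFilter(np.ones((2, 3)), 0.0))

    def test_entries_in_tanh_range(self):
        W = RNG.normal(size=(4, 10))
        f = conv_feature_map(W, ConvFilter(RNG.normal(size=(4, 3)) * 0.3, 0.5))
        assert np.all(np.abs(f) < 1.0)


class TestMaxOverTime:
    def test_examples(self):
        assert max_over_time(np.array([0.2, -0.5, 0.9])) == 0.9
        assert max_over_time(np.array([-0.3])) == -0.3

    def test_matches_sort_oracle(self):
        for _ in range(10):
            f = RNG.normal(size=int(RNG.integers(1, 30)))
            assert max_over_time(f) == sorted(f)[-1]

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            max_over_time(np.array([]))


class TestEncodePost:
    @pytest.fixture()
    def emb(self):
        vocab = Vocabulary(["alpha", "beta", "gamma"])
        return EmbeddingMatrix(RNG.normal(size=(4, 3)), vocab)

    def test_zero_bank_gives_zero_vector(self, emb):
        bank = FilterBank([ConvFilter(np.zeros((4, k)), 0.0) for k in (2, 3)])
        v = encode_post(["alpha", "beta"], emb, bank)
        np.testing.assert_array_equal(v, np.zeros(2))

    def test_output_length_equals_filter_count(self, emb):
        bank = FilterBank([ConvFilter(RNG.normal(size=(4, k)), 0.1)
                           for k in (2, 3, 4, 5) for _ in range(3)])
        v = encode_post(["alpha", "gamma", "beta"], emb, bank)
        assert v.shape == (12,)

    def test_short_post_padded_to_widest_filter(self, emb):
        bank = FilterBank([ConvFilter(RNG.normal(size=(4, 5)), 0.0)])
        v = encode_post(["alpha"], emb, bank)
        assert np.all(np.isfinite(v))

    def test_oov_tokens_use_oov_vector(self, emb):
        bank = FilterBank([ConvFilter(RNG.normal(size=(4, 2)), 0.0)])
        oov = RNG.normal(size=4)
        a = encode_post(["nope", "nada"], emb, bank, oov_vector=oov)
        W = np.column_stack([oov, oov])
        np.testing.assert_allclose(
            a, [max_over_time(conv_feature_map(W, bank.filters[0]))])

    def test_empty_bank_rejected(self, emb):
        with pytest.raises(ValueError):
            encode_post(["alpha"], emb, FilterBank([]))


# ---------------------------------------------------------------------------
# highway, LSTM, softmax, NLL
# ---------------------------------------------------------------------------


class TestHighway:
    def test_carry_gate_limit_is_identity(self):
        h = 6
        l = RNG.normal(size=h)
        p = HighwayParams(RNG.normal(size=(h, h)), RNG.normal(size=h),
                          np.zeros((h, h)), np.full(h, -1e6))
        np.testing.assert_allclose(highway(l, p), l)

    def test_transform_gate_limit(self):
        h = 6
        l = RNG.normal(size=h)
        A_H, b_H = RNG.normal(size=(h, h)), RNG.normal(size=h)
        p = HighwayParams(A_H, b_H, np.zeros((h, h)), np.full(h, 1e6))
        np.testing.assert_allclose(highway(l, p), np.tanh(A_H @ l + b_H))

    def test_matches_elementwise_oracle(self):
        for _ in range(20):
            h = int(RNG.integers(1, 9))
            l = RNG.normal(size=h)
            A_H, b_H = RNG.normal(size=(h, h)), RNG.normal(size=h)
            A_T, b_T = RNG.normal(size=(h, h)), RNG.normal(size=h)
            got = highway(l, HighwayParams(A_H, b_H, A_T, b_T))
            np.testing.assert_allclose(
                got, highway_oracle(l, A_H, b_H, A_T, b_T), atol=1e-10)

    def test_dimension_mismatch_rejected(self):
        p = HighwayParams(np.zeros((3, 3)), np.zeros(3),
                          np.zeros((3, 3)), np.zeros(3))
        with pytest.raises(ValueError):
            highway(np.zeros(4), p)


class TestLSTMStep:
    def test_zero_parameters_keep_zero_state(self):
        p = LSTMParams(U={j: np.zeros((3, 2)) for j in "ifog"},
                       V={j: np.zeros((3, 3)) for j in "ifog"},
                       b={j: np.zeros(3) for j in "ifog"})
        s = lstm_step(RNG.normal(size=2), LSTMState.zero(3), p)
        np.testing.assert_array_equal(s.h, np.zeros(3))
        np.testing.assert_array_equal(s.c, np.zeros(3))

    def test_hand_worked_scalar_step(self):
        # m = 1, all weights 1, biases 0, x = 0, h_prev = 0, c_prev = 1:
        # every gate is sigma(0) = 0.5, candidate tanh(0) = 0, so
        # c = 0.5 * 1 + 0.5 * 0 = 0.5 and h = 0.5 * tanh(0.5)
        p = LSTMParams(U={j: np.ones((1, 1)) for j in "ifog"},
                       V={j: np.ones((1, 1)) for j in "ifog"},
                       b={j: np.zeros(1) for j in "ifog"})
        s = lstm_step(np.zeros(1), LSTMState(np.zeros(1), np.ones(1)), p)
        assert s.c[0] == pytest.approx(0.5)
        assert s.h[0] == pytest.approx(0.5 * np.tanh(0.5), abs=1e-10)
        assert s.h[0] == pytest.approx(0.2311, abs=1e-4)

    def test_matches_scalar_loop_oracle(self):
        for _ in range(20):
            m, hdim = int(RNG.integers(1, 5)), int(RNG.integers(1, 5))
            p = random_lstm_params(m, hdim)
            x = RNG.normal(size=hdim)
            st = LSTMState(RNG.normal(size=m), RNG.normal(size=m))
            got = lstm_step(x, st, p)
            h, c = lstm_oracle(x, st.h, st.c, p)
            np.testing.assert_allclose(got.h, h, atol=1e-10)
            np.testing.assert_allclose(got.c, c, atol=1e-10)

    def test_shape_mismatch_rejected(self):
        p = random_lstm_params(2, 3)
        with pytest.raises(ValueError):
            lstm_step(np.zeros(5), LSTMState.zero(2), p)


class TestLabelDistribution:
    def test_zero_parameters_give_uniform(self):
        p = SoftmaxParams(np.zeros((4, 3)), np.zeros(4))
        np.testing.assert_allclose(label_distribution(np.ones(3), p),
                                   np.full(4, 0.25))

    def test_equal_logits_split_evenly(self):
        p = SoftmaxParams(np.ones((2, 2)), np.zeros(2))
        np.testing.assert_allclose(label_distribution(np.array([0.5, 0.5]), p),
                                   [0.5, 0.5])

    def test_extreme_logits_do_not_overflow(self):
        p = SoftmaxParams(np.array([[1000.0], [0.0]]), np.zeros(2))
        probs = label_distribution(np.ones(1), p)
        assert np.isfinite(probs).all()
        assert probs[0] == pytest.approx(1.0)

    def test_matches_oracle_and_sums_to_one(self):
        for _ in range(20):
            m, j = int(RNG.integers(1, 6)), int(RNG.integers(2, 5))
            Z, b = RNG.normal(size=(j, m)), RNG.normal(size=j)
            h = RNG.normal(size=m)
            got = label_distribution(h, SoftmaxParams(Z, b))
            np.testing.assert_allclose(got, softmax_oracle(h, Z, b), atol=1e-10)
            assert got.sum() == pytest.approx(1.0, abs=1e-9)


class TestSequenceNLL:
    def test_perfect_predictions_have_zero_loss(self):
        probs = [np.array([1.0, 0.0]), np.array([0.0, 1.0])]
        assert sequence_nll(probs, [0, 1]) == 0.0

    def test_closed_form_half_probabilities(self):
        probs = [np.array([0.5, 0.5])] * 2
        assert sequence_nll(probs, [0, 1]) == pytest.approx(2 * np.log(2))

    def test_matches_per_step_sum(self):
        T, j = 6, 3
        probs = []
        for _ in range(T):
            p = RNG.random(j)
            probs.append(p / p.sum())
        labels = [int(RNG.integers(j)) for _ in range(T)]
        want = -sum(np.log(probs[t][labels[t]]) for t in range(T))
        assert sequence_nll(probs, labels) == pytest.approx(want, abs=1e-12)

    def test_loss_is_nonnegative_and_clipped(self):
        probs = [np.array([0.0, 1.0])]
        loss = sequence_nll(probs, [0])
        assert np.isfinite(loss) and loss > 0

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            sequence_nll([np.array([1.0])], [0, 1])


# ---------------------------------------------------------------------------
# the trainable net agrees with the composition of reference operations
# ---------------------------------------------------------------------------


class TestNetMatchesReferenceOps:
    def test_forward_thread_equals_op_composition(self):
        cfg = NetConfig(embedding_dim=3, filter_widths=(2, 3),
                        filters_per_width=2, hidden_dim=4, n_classes=2,
                        use_highway=True, seed=9)
        vocab = Vocabulary(["a", "b", "c", "d"])
        net = DebateNet(cfg, vocab_size=4)
        token_threads = [["a", "c"], ["d", "b", "a", "zz"], ["c"]]
        ids = [np.array([{"a": 0, "b": 1, "c": 2, "d": 3}.get(t, 4)
                         for t in toks]) for toks in token_threads]
        got = np.array(net.predict_thread(ids))

        # reference path: pure ops with the same parameters
        emb = EmbeddingMatrix(net.params["E"][:, :4], vocab)
        oov = net.params["E"][:, 4]
        bank = FilterBank([
            ConvFilter(net.params[f"H{k}"][i], float(net.params[f"bH{k}"][i]))
            for k in cfg.filter_widths for i in range(cfg.filters_per_width)
        ])
        hw = HighwayParams(net.params["A_H"], net.params["b_H"],
                           net.params["A_T"], net.params["b_T"])
        lstm = net.lstm.to_reference()
        soft = SoftmaxParams(net.params["Z"], net.params["b_s"])
        state = LSTMState.zero(cfg.hidden_dim)
        want = []
        for toks in token_threads:
            lvec = encode_post(toks, emb, bank, oov_vector=oov)
            z = highway(lvec, hw)
            state = lstm_step(z, state, lstm)
            want.append(label_distribution(state.h, soft))
        np.testing.assert_allclose(got, np.array(want), atol=1e-12)

    def test_threads_are_independent_of_batch_order(self):
        cfg = NetConfig(embedding_dim=3, filter_widths=(2,),
                        filters_per_width=3, hidden_dim=3, n_classes=2, seed=1)
        net = DebateNet(cfg, vocab_size=5)
        t1 = [np.array([0, 1]), np.array([2])]
        t2 = [np.array([3, 4, 0])]
        a1 = net.predict_thread(t1)
        _ = net.predict_thread(t2)
        a1_again = net.predict_thread(t1)
        np.testing.assert_array_equal(np.array(a1), np.array(a1_again))
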