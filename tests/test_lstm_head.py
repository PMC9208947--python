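import numpy as np
import pytest
from hypothesis import given, strategies as st

from harnet._nn import softmax
from harnet.lstm_head import (GateParams, LSTMState, classify, lstm_cell_step,
                              reduce_rows, temporal_forward)


def zero_gates(input_size, hidden):
    z = np.zeros((hidden, hidden + input_size))
    return GateParams(W_f=z.copy(), W_i=z.copy(), W_c=z.copy(), W_o=z.copy(),
                      b_f=np.zeros(hidden), b_i=np.zeros(hidden),
                      b_c=np.zeros(hidden), b_o=np.zeros(hidden))


def scalar_step_oracle(h, c, x, p):
    """Step-by-step scalar-loop evaluation of the gate equations."""
    def sig(v):
        return 1.0 / (1.0 + np.exp(-v))

    H = p.hidden_size
    z = np.concatenate([h, x])
    f = np.array([sig(sum(p.W_f[r, j] * z[j] for j in range(len(z))) + p.b_f[r]) for r in range(H)])
    i = np.array([sig(sum(p.W_i[r, j] * z[j] for j in range(len(z))) + p.b_i[r]) for r in range(H)])
    g = np.array([np.tanh(sum(p.W_c[r, j] * z[j] for j in range(len(z))) + p.b_c[r]) for r in range(H)])
    c_new = f * c + i * g
    o = np.array([sig(sum(p.W_o[r, j] * z[j] for j in range(len(z))) + p.b_o[r]) for r in range(H)])
    return o * np.tanh(c_new), c_new


class TestCellStep:
    def test_zero_parameters_zero_state(self):
        p = zero_gates(3, 4)
        state = lstm_cell_step(LSTMState(h=np.zeros(4), c=np.zeros(4)), np.ones(3), p)
        np.testing.assert_array_equal(state.h, np.zeros(4))
        np.testing.assert_array_equal(state.c, np.zeros(4))

    def test_perfect_memory_limit(self, rng):
        # saturate forget gate open and input gate closed: c_t = c_{t-1}
        p = zero_gates(2, 3)
        p.b_f[:] = 50.0
        p.b_i[:] = -50.0
        c0 = rng.normal(size=3)
        state = lstm_cell_step(LSTMState(h=np.zeros(3), c=c0), rng.normal(size=2), p)
        np.testing.assert_allclose(state.c, c0, rtol=1e-12)

    def test_three_steps_match_scalar_oracle(self, rng):
        p = GateParams.random(3, 4, rng=np.random.default_rng(9))
        state = LSTMState(h=np.zeros(4), c=np.zeros(4))
        h_o, c_o = np.zeros(4), np.zeros(4)
        for _ in range(3):
            x = rng.normal(size=3)
            state = lstm_cell_step(state, x, p)
            h_o, c_o = scalar_step_oracle(h_o, c_o, x, p)
            np.testing.assert_allclose(state.h, h_o, rtol=1e-10)
            np.testing.assert_allclose(state.c, c_o, rtol=1e-10)

    def test_dimension_mismatch_error(self):
        p = zero_gates(3, 4)
        with pytest.raises(ValueError, match="input size"):
            lstm_cell_step(LSTMState(h=np.zeros(4), c=np.zeros(4)), np.ones(5), p)

    def test_gate_matrices_must_share_shape(self):
        with pytest.raises(ValueError, match="share shape"):
            GateParams(W_f=np.zeros((2, 4)), W_i=np.zeros((2, 5)),
                       W_c=np.zeros((2, 4)), W_o=np.zeros((2, 4)),
                       b_f=np.zeros(2), b_i=np.zeros(2), b_c=np.zeros(2), b_o=np.zeros(2))

    @given(seed=st.integers(0, 300))
    def test_state_bounds(self, seed):
        rng = np.random.default_rng(seed)
        p = GateParams.random(2, 3, rng=rng)
        state = LSTMState(h=np.zeros(3), c=np.zeros(3))
        for _ in range(4):
            state = lstm_cell_step(state, rng.normal(scale=3, size=2), p)
        assert np.all(np.abs(state.h) < 1.0)  # h = o * tanh(c), both factors < 1


class TestTemporalForward:
    def test_single_row_is_one_cell_step(self, rng):
        p = GateParams.random(3, 4, rng=np.random.default_rng(1))
        fm = rng.normal(size=(1, 3, 5))
        h = temporal_forward(fm, p)
        expected = lstm_cell_step(LSTMState(h=np.zeros(4), c=np.zeros(4)),
                                  fm[0].mean(axis=1), p).h
        np.testing.assert_allclose(h, expected)

    def test_four_rows_match_iterated_cell_oracle(self, rng):
        p = GateParams.random(2, 3, rng=np.random.default_rng(2))
        fm = rng.normal(size=(4, 2, 6))
        h = temporal_forward(fm, p)
        state = LSTMState(h=np.zeros(3), c=np.zeros(3))
        for t in range(4):
            state = lstm_cell_step(state, fm[t].mean(axis=1), p)
        np.testing.assert_allclose(h, state.h, rtol=1e-12)

    def test_flatten_mode_input_size(self, rng):
        fm = rng.normal(size=(3, 4, 5))
        assert reduce_rows(fm, "flatten").shape == (3, 20)
        assert reduce_rows(fm, "channel_mean").shape == (3, 4)

    def test_perfect_memory_depends_only_on_first_step(self, rng):
        p = GateParams.random(2, 3, rng=np.random.default_rng(3))
        p.b_f[:] = 60.0
        p.b_i[:] = -60.0
        row = rng.normal(size=(1, 2, 1))
        fm2 = np.concatenate([row, rng.normal(size=(3, 2, 1))])
        fm3 = np.concatenate([row, rng.normal(size=(3, 2, 1))])
        # cell state frozen after step 1; only o_t varies, bounded by tanh(c_1)
        state1 = lstm_cell_step(LSTMState(h=np.zeros(3), c=np.zeros(3)), row[0].mean(axis=1), p)
        for fm in (fm2, fm3):
            h = temporal_forward(fm, p)
            assert np.all(np.abs(h) <= np.abs(np.tanh(state1.c)) + 1e-12)


class TestClassify:
    def test_zero_parameters_uniform_probabilities(self):
        probs = classify(np.zeros(64), np.zeros((12, 64)), np.zeros(12))
        np.testing.assert_allclose(probs, np.full(12, 1 / 12))

    def test_probabilities_sum_to_one(self, rng):
        probs = classify(rng.normal(size=8), rng.normal(size=(5, 8)), rng.normal(size=5))
        assert probs.sum() == pytest.approx(1.0)
        assert np.all(probs > 0)

    def test_argmax_invariant_under_logit_shift(self, rng):
        h = rng.normal(size=6)
        w = rng.normal(size=(4, 6))
        b = rng.normal(size=4)
        base = classify(h, w, b)
        shifted = softmax(w @ h + b + 100.0)
        assert base.argmax() == shifted.argmax()
        np.testing.assert_allclose(base, shifted, rtol=1e-9)

    def test_fc_parameter_count(self):
        w, b = np.zeros((12, 64)), np.zeros(12)
        assert w.size + b.size == 780
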