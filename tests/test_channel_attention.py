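import numpy as np
import pytest
from hypothesis import given, strategies as st

from harnet._nn import _sigmoid
from harnet.channel_attention import (ImprovedECA, eca_kernel_size, eca_weights,
                                      global_avg_pool, improved_eca_forward,
                                      rank_channels, selection_count)
from harnet.inception_block import count_parameters


class TestGlobalAvgPool:
    def test_constant_channel(self):
        fm = np.full((3, 4, 2), 3.0)
        np.testing.assert_allclose(global_avg_pool(fm), [3.0, 3.0])

    def test_small_example(self):
        fm = np.array([[1.0, 2.0], [3.0, 4.0]])[:, :, None]
        assert global_avg_pool(fm)[0] == pytest.approx(2.5)

    def test_matches_direct_summation(self, rng):
        fm = rng.normal(size=(5, 4, 7))
        expected = [fm[:, :, c].sum() / 20.0 for c in range(7)]
        np.testing.assert_allclose(global_avg_pool(fm), expected, rtol=1e-12)


class TestAdaptiveKernelSize:
    def test_reference_384_channels(self):
        assert eca_kernel_size(384) == 5

    def test_two_channels(self):
        assert eca_kernel_size(2) == 1  # t = 0.5 + 0.5 = 1

    def test_64_channels_half_tie_rounds_down(self):
        assert eca_kernel_size(64) == 3  # t = 3.5, tie -> lower odd

    def test_too_few_channels_error(self):
        with pytest.raises(ValueError):
            eca_kernel_size(1)

    @given(C=st.integers(2, 4096))
    def test_always_odd_positive(self, C):
        k = eca_kernel_size(C)
        assert k >= 1 and k % 2 == 1


class TestEcaWeights:
    def test_zero_vector_all_one_taps_gives_half(self):
        omega = eca_weights(np.zeros(8), np.ones(3))
        np.testing.assert_allclose(omega, 0.5)

    def test_k1_is_elementwise_sigmoid(self, rng):
        pooled = rng.normal(size=6)
        w = 1.7
        np.testing.assert_allclose(eca_weights(pooled, np.array([w])), _sigmoid(w * pooled))

    def test_k3_matches_sliding_sum_oracle(self, rng):
        pooled = rng.normal(size=6)
        ker = rng.normal(size=3)
        padded = np.concatenate([[0.0], pooled, [0.0]])
        expected = [_sigmoid(sum(ker[j] * padded[i + j] for j in range(3))) for i in range(6)]
        np.testing.assert_allclose(eca_weights(pooled, ker), expected, rtol=1e-12)

    def test_even_kernel_rejected(self):
        with pytest.raises(ValueError, match="odd"):
            eca_weights(np.zeros(6), np.ones(2))

    @given(seed=st.integers(0, 1000))
    def test_weights_in_open_unit_interval(self, seed):
        rng = np.random.default_rng(seed)
        omega = eca_weights(rng.normal(scale=5, size=16), rng.normal(size=5))
        assert np.all(omega > 0) and np.all(omega < 1)


class TestSelectionCount:
    @pytest.mark.parametrize("C,k,expected", [
        (4, 1, 2),     # 1 + 1 = 2
        (256, 5, 10),  # 5 + 4 = 9, even tie -> upper
        (384, 5, 10),  # 9.2925 -> 10
    ])
    def test_examples(self, C, k, expected):
        assert selection_count(C, k) == expected

    def test_clamped_to_channel_count(self):
        assert selection_count(2, 9) <= 2

    @given(k=st.integers(1, 9))
    def test_monotone_in_channels(self, k):
        values = [selection_count(C, k) for C in range(2, 600)]
        assert all(b >= a for a, b in zip(values, values[1:]))


class TestImprovedEcaForward:
    def test_select_everything_keeps_full_weighted_map(self, rng):
        fm = rng.normal(size=(3, 2, 2))
        res = improved_eca_forward(fm, n_override=2, kernel=np.array([1.0]))
        assert res.n == 2 and res.output.shape == (3, 2, 2)
        order = np.argsort(-np.abs(res.omega), kind="stable")
        np.testing.assert_array_equal(res.selected, order)
        for j, c in enumerate(res.selected):
            np.testing.assert_allclose(res.output[:, :, j], fm[:, :, c] * res.omega[c])

    def test_high_mean_channel_is_selected(self, rng):
        fm = np.zeros((4, 4, 16))
        fm[:, :, 5] = 3.0  # one channel with a distinct pooled value
        res = improved_eca_forward(fm, kernel=np.array([0.0, 2.0, 0.0]))
        # with only the center tap active, omega tracks each channel's own pooled value
        assert 5 in res.selected
        oracle = np.argsort(-np.abs(res.omega), kind="stable")[: res.n]
        np.testing.assert_array_equal(res.selected, oracle)

    def test_reference_configuration_shapes(self, rng):
        fm = rng.normal(size=(4, 3, 384))
        res = improved_eca_forward(fm, n_override=9, rng=rng)
        assert res.k == 5
        assert res.output.shape == (4, 3, 9)
        assert count_parameters((9, 384, 1, 1), bias=True) == 3465

    def test_n_override_beyond_channels_rejected(self, rng):
        with pytest.raises(ValueError, match="n_override"):
            improved_eca_forward(rng.normal(size=(2, 2, 4)), n_override=5)

    @given(seed=st.integers(0, 200))
    def test_selected_are_largest_by_magnitude(self, seed):
        rng = np.random.default_rng(seed)
        fm = rng.normal(scale=2, size=(3, 3, 12))
        res = improved_eca_forward(fm, rng=rng)
        mags = np.abs(res.omega)
        not_selected = np.setdiff1d(np.arange(12), res.selected)
        if len(not_selected):
            assert mags[res.selected].min() >= mags[not_selected].max()

    def test_n_equal_c_recovers_original_eca_up_to_permutation(self, rng):
        fm = rng.normal(size=(3, 2, 16))
        kernel = rng.normal(size=3)  # adaptive size for 16 channels
        res = improved_eca_forward(fm, n_override=16, kernel=kernel)
        pooled = global_avg_pool(fm)
        omega = eca_weights(pooled, kernel)
        original = fm * omega  # unimproved ECA output
        restored = np.empty_like(original)
        for j, c in enumerate(res.selected):
            restored[:, :, c] = res.output[:, :, j]
        np.testing.assert_allclose(restored, original, rtol=1e-12)


class TestImprovedEcaLayer:
    def test_conv1x1_reduce_has_learned_parameters(self):
        eca = ImprovedECA(384, n_override=9, channel_reduce="conv1x1")
        assert eca.reduce_conv.n_parameters() == 3465

    def test_gather_reduce_has_only_kernel_parameters(self):
        eca = ImprovedECA(384, n_override=9)
        assert eca.n_parameters() == eca.k == 5

    def test_batched_forward_matches_single_map_function(self, rng):
        eca = ImprovedECA(8, rng=np.random.default_rng(3))
        maps = rng.normal(size=(4, 8, 3, 2))
        out = eca.forward(maps)
        for i in range(4):
            single = improved_eca_forward(maps[i].transpose(1, 2, 0),
                                          kernel=eca.kernel.value)
            np.testing.assert_allclose(out[i].transpose(1, 2, 0), single.output, rtol=1e-12)

    def test_rank_channels_stable_tie_break(self):
        omega = np.array([0.4, 0.6, 0.6, 0.2])
        np.testing.assert_array_equal(rank_channels(omega), [1, 2, 0, 3])
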