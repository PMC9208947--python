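import numpy as np
import pytest
from hypothesis import given, strategies as st

from harnet.io_formats import ChannelMeta, SensorRecording
from harnet.preprocessing import (InterpolationError, interpolate_missing,
                                  segment_windows, split_train_test,
                                  windows_to_arrays)


def make_recording(samples, labels=None, timestamps=None, rate=1.0):
    samples = np.atleast_2d(np.asarray(samples, float))
    if samples.shape[0] == 1:
        samples = samples.T
    T, D = samples.shape
    meta = [ChannelMeta("s", "acc", f"a{j}") for j in range(D)]
    return SensorRecording(
        timestamps=np.arange(T, dtype=float) if timestamps is None else np.asarray(timestamps, float),
        samples=samples,
        channel_meta=meta,
        labels=np.zeros(T, int) if labels is None else np.asarray(labels, int),
        rate_hz=rate,
    )


class TestInterpolation:
    def test_exact_linear_gap(self):
        y = np.full(11, np.nan)
        y[0], y[10] = 0.0, 10.0
        y[[1, 2, 3, 5, 6, 7, 8, 9]] = np.arange(11.0)[[1, 2, 3, 5, 6, 7, 8, 9]]
        y[4] = np.nan
        rec = interpolate_missing(make_recording(y))
        assert rec.samples[4, 0] == pytest.approx(4.0)

    def test_straight_line_reconstructed_to_machine_precision(self, rng):
        T = 100
        x = np.arange(T, dtype=float)
        line = 3.7 * x - 12.1
        y = line.copy()
        interior = rng.choice(np.arange(1, T - 1), size=30, replace=False)
        y[interior] = np.nan
        rec = interpolate_missing(make_recording(y))
        np.testing.assert_allclose(rec.samples[:, 0], line, rtol=0, atol=1e-12)

    def test_gap_of_three_matches_line_oracle(self):
        # anchors (x=2, y=1) and (x=6, y=9): slope 2, so y(3,4,5) = 3, 5, 7
        y = np.array([0.0, 0.5, 1.0, np.nan, np.nan, np.nan, 9.0])
        rec = interpolate_missing(make_recording(y))
        slope = (9.0 - 1.0) / (6.0 - 2.0)
        expected = [1.0 + slope * (xi - 2.0) for xi in (3, 4, 5)]
        np.testing.assert_allclose(rec.samples[3:6, 0], expected)

    def test_uses_timestamps_not_indices(self):
        ts = np.array([0.0, 1.0, 4.0])
        y = np.array([0.0, np.nan, 8.0])
        rec = interpolate_missing(make_recording(y, timestamps=ts))
        assert rec.samples[1, 0] == pytest.approx(2.0)  # 0 + 8/4 * 1

    def test_idempotent_on_complete_recording(self, rng):
        rec = make_recording(rng.normal(size=(20, 3)))
        out = interpolate_missing(rec)
        np.testing.assert_array_equal(out.samples, rec.samples)

    def test_boundary_gap_is_error(self):
        with pytest.raises(InterpolationError, match="boundary"):
            interpolate_missing(make_recording([np.nan, 1.0, 2.0]))

    def test_fully_missing_channel_is_error(self):
        with pytest.raises(InterpolationError, match="fully missing"):
            interpolate_missing(make_recording([np.nan, np.nan, np.nan]))


class TestSegmentation:
    def test_non_overlapping_uniform_label(self):
        rec = make_recording(np.arange(10.0))
        ws = segment_windows(rec, 5, 5)
        assert [w.origin[1] for w in ws] == [0, 5]
        assert all(w.label == 0 for w in ws)

    def test_window_count_arithmetic(self):
        rec = make_recording(np.arange(10.0))
        assert len(segment_windows(rec, 5, 2)) == (10 - 5) // 2 + 1 == 3

    def test_majority_label_from_enumeration(self):
        labels = [0] * 6 + [1] * 4
        rec = make_recording(np.arange(10.0), labels=labels)
        ws = segment_windows(rec, 5, 5)
        assert [w.label for w in ws] == [0, 1]  # window at 5: one 0, four 1s

    def test_tie_window_discarded(self):
        labels = [0] * 3 + [1] * 3
        rec = make_recording(np.arange(6.0), labels=labels)
        ws = segment_windows(rec, 6, 6)
        assert ws == []

    def test_short_recording_warns_and_returns_empty(self, caplog):
        rec = make_recording(np.arange(3.0))
        with caplog.at_level("WARNING"):
            assert segment_windows(rec, 5) == []
        assert any("shorter" in r.message for r in caplog.records)

    def test_sentinel_in_samples_rejected(self):
        rec = make_recording([0.0, np.nan, 2.0, 3.0])
        with pytest.raises(ValueError, match="missing"):
            segment_windows(rec, 2)

    @given(T=st.integers(5, 60), K=st.integers(1, 10), stride=st.integers(1, 10),
           seed=st.integers(0, 100))
    def test_conserves_source_data_exactly(self, T, K, stride, seed):
        rng = np.random.default_rng(seed)
        rec = make_recording(rng.normal(size=(T, 2)))
        for w in segment_windows(rec, K, stride):
            start = w.origin[1]
            np.testing.assert_array_equal(w.data, rec.samples[start : start + K])
            assert w.data.shape == (K, 2)

    @pytest.mark.parametrize("K", [50, 100])
    def test_window_length_is_pure_configuration(self, K):
        rec = make_recording(np.arange(250.0))
        ws = segment_windows(rec, K)
        assert len(ws) == 250 // K
        assert all(w.data.shape == (K, 1) for w in ws)


class TestSplit:
    def _windows(self, n):
        rec = make_recording(np.arange(float(n)))
        return segment_windows(rec, 1, 1)

    def test_seven_three_on_ten(self):
        s = split_train_test(self._windows(10), seed=0)
        assert (len(s.train), len(s.test)) == (7, 3)

    def test_rounding_on_101(self):
        s = split_train_test(self._windows(101), seed=0)
        assert (len(s.train), len(s.test)) == (71, 30)

    def test_same_seed_identical_partition(self):
        ws = self._windows(20)
        a = split_train_test(ws, seed=5)
        b = split_train_test(ws, seed=5)
        assert [w.origin for w in a.train] == [w.origin for w in b.train]
        assert [w.origin for w in a.test] == [w.origin for w in b.test]

    def test_disjoint_by_origin(self):
        s = split_train_test(self._windows(30), seed=2)
        assert not ({w.origin for w in s.train} & {w.origin for w in s.test})

    def test_too_few_windows_is_error(self):
        with pytest.raises(ValueError, match="at least 2"):
            split_train_test(self._windows(1), seed=0)


def test_windows_to_arrays_shapes():
    rec = make_recording(np.arange(12.0), labels=[0] * 6 + [1] * 6)
    X, y = windows_to_arrays(segment_windows(rec, 3, 3))
    assert X.shape == (4, 3, 1)
    assert y.tolist() == [0, 0, 1, 1]
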