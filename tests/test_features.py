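import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from depspeech.audio_io import AudioSignal
from depspeech.features import (Feature3D, FeatureConfig, compute_padding_length,
                                delta, fbank, mfcc39, pad_or_split, stack_3d)

from conftest import make_tone


class TestFbank:
    def test_frame_count_and_dimension(self):
        out = fbank(make_tone(300, 1.0))
        # floor((16000 - 400)/160) + 1 = 98 frames of 40 bands
        assert out.shape == (98, 40)

    def test_white_noise_is_finite(self):
        rng = np.random.default_rng(0)
        sig = AudioSignal(rng.uniform(-0.5, 0.5, 16_000), 16_000)
        out = fbank(sig)
        assert np.all(np.isfinite(out))

    def test_digital_silence_hits_log_floor_not_nan(self):
        out = fbank(AudioSignal(np.zeros(8000), 16_000))
        assert np.all(np.isfinite(out))

    def test_too_short_signal_rejected(self):
        with pytest.raises(ValueError):
            fbank(AudioSignal(np.zeros(100), 16_000))


class TestMfcc39:
    def test_dimension(self):
        out = mfcc39(make_tone(300, 1.0))
        assert out.shape[1] == 39

    def test_delta_columns_by_construction(self):
        out = mfcc39(make_tone(300, 1.0))
        np.testing.assert_allclose(out[:, 13:26], delta(out[:, :13]), atol=1e-12)
        np.testing.assert_allclose(out[:, 26:39], delta(out[:, 13:26]), atol=1e-12)

    def test_stationary_tone_has_near_zero_interior_deltas(self):
        out = mfcc39(make_tone(300, 2.0))
        static_rms = np.sqrt(np.mean(out[:, :13] ** 2))
        interior = out[10:-10, 13:26]
        assert np.abs(interior).max() < 1e-2 * static_rms


class TestDelta:
    def test_constant_sequence_difference_is_zero(self):
        out = delta(np.full((7, 3), 4.2), N=2, sign="difference")
        np.testing.assert_allclose(out, 0.0, atol=1e-12)

    def test_hand_evaluated_impulse(self):
        # m=[0,0,1,0,0], N=2, edge replication:
        # index 1: [1*(m2-m0) + 2*(m3-m0)]/(2*(1+4)) = 1/10
        out = delta(np.array([0.0, 0.0, 1.0, 0.0, 0.0]), N=2)
        np.testing.assert_allclose(out, [0.2, 0.1, 0.0, -0.1, -0.2], atol=1e-12)

    def test_printed_sum_on_constant(self):
        # sum convention on constant c gives c * (sum n)/(sum n^2) = 0.6 c at N=2
        c = 2.5
        out = delta(np.full(6, c), N=2, sign="printed_sum")
        np.testing.assert_allclose(out, 0.6 * c, atol=1e-12)

    def test_invalid_window(self):
        with pytest.raises(ValueError):
            delta(np.zeros(5), N=0)

    @settings(derandomize=True, max_examples=25, deadline=None)
    @given(st.integers(min_value=1, max_value=10), st.floats(-3, 3), st.floats(-3, 3))
    def test_linearity(self, T, a, b):
        rng = np.random.default_rng(T)
        m = rng.normal(size=(T, 4))
        k = rng.normal(size=(T, 4))
        lhs = delta(a * m + b * k)
        rhs = a * delta(m) + b * delta(k)
        np.testing.assert_allclose(lhs, rhs, atol=1e-9)


class TestStack3D:
    def test_shape_and_channel_invariants(self):
        static = fbank(make_tone(250, 1.0))
        feat = stack_3d(static)
        assert feat.values.shape == (98, 40, 3)
        np.testing.assert_allclose(feat.values[:, :, 1], delta(feat.values[:, :, 0]))
        np.testing.assert_allclose(feat.values[:, :, 2], delta(feat.values[:, :, 1]))

    def test_zero_static_gives_zero_channels(self):
        feat = stack_3d(np.zeros((12, 40)))
        np.testing.assert_allclose(feat.values, 0.0)

    def test_wrong_width_rejected(self):
        with pytest.raises(ValueError):
            stack_3d(np.zeros((12, 39)))


class TestPaddingLength:
    def test_unique_mode(self):
        assert compute_padding_length([10, 10, 25]) == 10

    def test_tie_breaks_to_smaller(self):
        assert compute_padding_length([10, 20]) == 10

    def test_singleton(self):
        assert compute_padding_length([7]) == 7

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            compute_padding_length([])


class TestPadOrSplit:
    def test_split_with_padded_tail(self):
        chunks, masks = pad_or_split(np.arange(25 * 2, dtype=float).reshape(25, 2), 10)
        assert len(chunks) == 3
        assert all(c.shape == (10, 2) for c in chunks)
        assert [m.sum() for m in masks] == [10, 10, 5]
        assert np.all(chunks[2][5:] == 0.0)

    def test_exact_fit_full_mask(self):
        chunks, masks = pad_or_split(np.ones((10, 2)), 10)
        assert len(chunks) == 1
        assert masks[0].all()

    def test_single_frame_kept_at_discard_boundary(self):
        # 1 frame with L=10: 1 >= 0.1*10, so the chunk is kept and padded
        chunks, masks = pad_or_split(np.ones((1, 2)), 10)
        assert len(chunks) == 1
        assert masks[0].sum() == 1

    def test_tiny_remainder_discarded(self):
        # 105 frames with L=100: second chunk has 5 < 0.1*100 real frames
        chunks, masks = pad_or_split(np.ones((105, 2)), 100)
        assert len(chunks) == 1

    @settings(derandomize=True, max_examples=30, deadline=None)
    @given(T=st.integers(min_value=1, max_value=120),
           L=st.integers(min_value=1, max_value=40))
    def test_frame_conservation(self, T, L):
        chunks, masks = pad_or_split(np.ones((T, 3)), L)
        kept = sum(int(m.sum()) for m in masks)
        discarded = T - kept
        # every discarded chunk was strictly below the 10% floor
        assert discarded == 0 or discarded < 0.1 * L
        assert kept <= T
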