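"""Codec behaviour: exact bit-plane round trips, latency-code lossiness,
tanh readout bounds, and the tensor mode product against a loop oracle."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from vtsnn import (CodecConfig, GrayImage, SpikePlaneStack, mpd_decode,
                   n_mode_product, ttfs_encode, uwd_decode, uwe_encode)


class TestNModeProduct:
    def test_identity_matrix_leaves_tensor_unchanged(self, rng):
        t = rng.normal(size=(3, 4, 5))
        for mode in range(3):
            eye = np.eye(t.shape[mode])
            assert np.allclose(n_mode_product(t, eye, mode), t)

    def test_ones_row_sums_along_mode(self):
        t = np.ones((2, 2, 2))
        out = n_mode_product(t, np.ones((1, 2)), mode=1)
        assert out.shape == (2, 1, 2)
        assert np.all(out == 2.0)

    def test_matches_triple_loop_oracle(self, rng):
        p = rng.integers(-5, 6, size=(3, 4, 5)).astype(float)
        b = rng.integers(-5, 6, size=(2, 5)).astype(float)
        got = n_mode_product(p, b, mode=2)
        expected = np.zeros((3, 4, 2))
        for i in range(3):
            for l in range(4):
                for j in range(2):
                    expected[i, l, j] = sum(b[j, k] * p[i, l, k] for k in range(5))
        assert np.allclose(got, expected)

    def test_dimension_mismatch_raises(self):
        with pytest.raises(ValueError, match="mismatch"):
            n_mode_product(np.ones((3, 4)), np.ones((2, 5)), mode=1)


class TestUWE:
    @pytest.mark.parametrize("value,bits", [
        (0, [0] * 8),
        (255, [1] * 8),
        (146, [1, 0, 0, 1, 0, 0, 1, 0]),  # 146 = 128 + 16 + 2
    ])
    def test_single_pixel_bit_planes(self, value, bits):
        stack = uwe_encode(np.array([[value]]))
        assert stack.planes[:, 0, 0].tolist() == bits

    def test_weighted_sum_identity(self, rng):
        img = rng.integers(0, 256, size=(14, 14))
        stack = uwe_encode(img)
        recon = (stack.plane_weights[:, None, None] * stack.planes).sum(axis=0)
        assert np.array_equal(recon, img)

    @pytest.mark.parametrize("bad", [256, -1])
    def test_out_of_range_pixel_rejected_not_clipped(self, bad):
        with pytest.raises(ValueError, match="range"):
            uwe_encode(np.array([[bad]]))

    def test_planes_msb_first(self):
        stack = uwe_encode(np.array([[128]]))
        assert stack.order_convention == "msb_first"
        assert stack.planes[0, 0, 0] == 1 and stack.planes[1:].sum() == 0


class TestUWDRoundTrip:
    def test_all_ones_stack_decodes_to_255(self):
        img = uwd_decode(np.ones((8, 2, 2), dtype=np.uint8))
        assert np.all(img.pixels == 255)

    def test_inverse_of_encode_example(self):
        planes = np.array([1, 0, 0, 1, 0, 0, 1, 0]).reshape(8, 1, 1)
        assert uwd_decode(planes).pixels[0, 0] == 146

    def test_exhaustive_roundtrip_all_256_values(self):
        values = np.arange(256).reshape(16, 16)
        assert np.array_equal(uwd_decode(uwe_encode(values)).pixels, values)

    def test_non_binary_input_rejected(self):
        bad = np.full((8, 1, 1), 0.5)
        with pytest.raises(ValueError, match="binary"):
            uwd_decode(bad)

    def test_decoded_values_are_integers(self, rng):
        img = rng.integers(0, 256, size=(6, 6))
        out = uwd_decode(uwe_encode(img))
        assert np.issubdtype(out.pixels.dtype, np.integer)

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(st.integers(0, 255), st.integers(0, 255))
    def test_roundtrip_property(self, a, b):
        img = np.array([[a, b]])
        assert np.array_equal(uwd_decode(uwe_encode(img)).pixels, img)


class TestTTFS:
    def test_brightest_pixel_spikes_at_time_zero(self):
        stack = ttfs_encode(np.array([[255, 10]]), T=8)
        assert stack.planes[0, 0, 0] == 1
        assert stack.planes[1:, 0, 0].sum() == 0

    def test_zero_pixel_is_outside_window(self):
        stack = ttfs_encode(np.array([[255, 0]]), T=8)
        assert stack.planes[:, 0, 1].sum() == 0  # t = T, no spike

    def test_half_max_spikes_at_t4_with_floor(self):
        stack = ttfs_encode(np.array([[100, 50]]), T=8)
        assert np.argmax(stack.planes[:, 0, 1]) == 4

    def test_at_most_one_spike_per_pixel(self, rng):
        img = rng.integers(0, 256, size=(10, 10))
        stack = ttfs_encode(img, T=8)
        assert np.all(stack.planes.sum(axis=0) <= 1)

    def test_brighter_never_later(self, rng):
        img = rng.integers(1, 256, size=(12, 12))
        stack = ttfs_encode(img, T=8)
        t_of = np.where(stack.planes.sum(axis=0) > 0,
                        np.argmax(stack.planes, axis=0), 8)
        order = np.argsort(img.ravel())  # ascending intensity
        assert np.all(np.diff(t_of.ravel()[order]) <= 0)

    def test_all_zero_image_warns_and_emits_nothing(self):
        with pytest.warns(UserWarning, match="no spikes"):
            stack = ttfs_encode(np.zeros((3, 3), dtype=int), T=8)
        assert stack.planes.sum() == 0

    def test_lossy_collision_exists_at_T8(self):
        # two distinct intensities, one latency code: the latency code
        # cannot separate 256 levels into 8 bins
        img = np.array([[255, 1, 2]])
        stack = ttfs_encode(img, T=8)
        assert np.array_equal(stack.planes[:, 0, 1], stack.planes[:, 0, 2])


class TestMPD:
    def test_all_zero_stack_maps_to_zero(self):
        assert np.all(mpd_decode(np.zeros((8, 2, 2), dtype=np.uint8)) == 0.0)

    def test_single_msb_spike_is_tanh_one(self):
        planes = np.zeros((8, 1, 1), dtype=np.uint8)
        planes[0] = 1
        assert mpd_decode(planes)[0, 0] == pytest.approx(np.tanh(1.0), abs=1e-12)

    def test_output_strictly_inside_unit_interval(self):
        out = mpd_decode(np.ones((8, 3, 3), dtype=np.uint8))
        assert np.all(out > -1) and np.all(out < 1)

    def test_adding_a_spike_never_decreases_output(self, rng):
        planes = (rng.random((8, 4, 4)) < 0.3).astype(np.uint8)
        base = mpd_decode(planes)
        zeros = np.argwhere(planes == 0)
        t, i, j = zeros[0]
        planes[t, i, j] = 1
        assert mpd_decode(planes)[i, j] >= base[i, j]


def test_codec_config_validation():
    with pytest.raises(ValueError):
        CodecConfig(mpd_theta=1.0)
    cfg = CodecConfig()
    assert cfg.decode_matrix.tolist() == [[128, 64, 32, 16, 8, 4, 2, 1]]


def test_spike_plane_stack_invariants():
    with pytest.raises(ValueError, match="binary"):
        SpikePlaneStack(np.full((2, 1, 1), 2))
    with pytest.raises(ValueError, match="decreasing"):
        SpikePlaneStack(np.zeros((2, 1, 1), dtype=np.uint8), plane_weights=[1, 2])
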