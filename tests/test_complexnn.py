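"""Complex convolution, split activation and complex L1 loss."""

import numpy as np
import pytest

from fourierpd.complexnn import (
    complex_activation,
    complex_conv2d,
    complex_l1_loss,
)


def conv_oracle(x, w):
    """Direct complex multiply-accumulate: s(t) = sum_a x(t+a) w(a) (valid region)."""
    n, cin, h, wid = x.shape
    cout, _, kh, kw = w.shape
    ho, wo = h - kh + 1, wid - kw + 1
    out = np.zeros((n, cout, ho, wo), dtype=complex)
    for b in range(n):
        for o in range(cout):
            for i in range(ho):
                for j in range(wo):
                    acc = 0.0 + 0.0j
                    for c in range(cin):
                        for u in range(kh):
                            for v in range(kw):
                                acc += x[b, c, i + u, j + v] * w[o, c, u, v]
                    out[b, o, i, j] = acc
    return out


def matrix_form(x, w):
    """2x2 real block-matrix evaluation: [[w_r, -w_i], [w_i, w_r]] applied to (x_r, x_i)."""
    from scipy.signal import correlate2d

    n, cin, h, wid = x.shape
    cout, _, kh, kw = w.shape
    out_r = np.zeros((n, cout, h - kh + 1, wid - kw + 1))
    out_i = np.zeros_like(out_r)
    for b in range(n):
        for o in range(cout):
            for c in range(cin):
                rr = correlate2d(x[b, c].real, w[o, c].real, mode="valid")
                ii = correlate2d(x[b, c].imag, w[o, c].imag, mode="valid")
                ri = correlate2d(x[b, c].real, w[o, c].imag, mode="valid")
                ir = correlate2d(x[b, c].imag, w[o, c].real, mode="valid")
                out_r[b, o] += rr - ii
                out_i[b, o] += ri + ir
    return out_r + 1j * out_i


class TestComplexConv:
    def test_identity_kernel(self, rng):
        x = (rng.standard_normal((1, 1, 8, 8)) + 1j * rng.standard_normal((1, 1, 8, 8)))
        w = np.zeros((1, 1, 3, 3), dtype=complex)
        w[0, 0, 1, 1] = 1.0 + 0.0j
        out = complex_conv2d(x, w, padding=1)
        assert np.allclose(out, x, atol=1e-12)

    def test_imaginary_impulse_multiplies_by_i(self, rng):
        x = (rng.standard_normal((1, 1, 8, 8)) + 1j * rng.standard_normal((1, 1, 8, 8)))
        w = np.zeros((1, 1, 3, 3), dtype=complex)
        w[0, 0, 1, 1] = 1j
        out = complex_conv2d(x, w, padding=1)
        assert np.allclose(out.real, -x.imag, atol=1e-12)
        assert np.allclose(out.imag, x.real, atol=1e-12)

    def test_matches_direct_complex_mac_oracle(self, rng):
        x = rng.standard_normal((1, 1, 4, 4)) + 1j * rng.standard_normal((1, 1, 4, 4))
        w = rng.standard_normal((1, 1, 3, 3)) + 1j * rng.standard_normal((1, 1, 3, 3))
        assert np.abs(complex_conv2d(x, w) - conv_oracle(x, w)).max() < 1e-6

    def test_matches_oracle_multichannel(self, rng):
        x = rng.standard_normal((2, 3, 6, 5)) + 1j * rng.standard_normal((2, 3, 6, 5))
        w = rng.standard_normal((4, 3, 3, 3)) + 1j * rng.standard_normal((4, 3, 3, 3))
        assert np.abs(complex_conv2d(x, w) - conv_oracle(x, w)).max() < 1e-6

    def test_component_form_equals_matrix_form(self, rng):
        x = rng.standard_normal((1, 2, 7, 7)) + 1j * rng.standard_normal((1, 2, 7, 7))
        w = rng.standard_normal((3, 2, 3, 3)) + 1j * rng.standard_normal((3, 2, 3, 3))
        assert np.abs(complex_conv2d(x, w) - matrix_form(x, w)).max() < 1e-7

    def test_linearity_in_input_and_kernel(self, rng):
        x1 = rng.standard_normal((1, 1, 6, 6)) + 1j * rng.standard_normal((1, 1, 6, 6))
        x2 = rng.standard_normal((1, 1, 6, 6)) + 1j * rng.standard_normal((1, 1, 6, 6))
        w1 = rng.standard_normal((1, 1, 3, 3)) + 1j * rng.standard_normal((1, 1, 3, 3))
        w2 = rng.standard_normal((1, 1, 3, 3)) + 1j * rng.standard_normal((1, 1, 3, 3))
        lhs = complex_conv2d(x1 + x2, w1)
        rhs = complex_conv2d(x1, w1) + complex_conv2d(x2, w1)
        assert np.allclose(lhs, rhs, atol=1e-10)
        lhs = complex_conv2d(x1, w1 + w2)
        rhs = complex_conv2d(x1, w1) + complex_conv2d(x1, w2)
        assert np.allclose(lhs, rhs, atol=1e-10)

    def test_channel_mismatch_raises(self, rng):
        with pytest.raises(ValueError):
            complex_conv2d(np.ones((1, 2, 4, 4), complex), np.ones((1, 3, 3, 3), complex))

    def test_complex_bias_added_per_channel(self, rng):
        x = rng.standard_normal((1, 1, 4, 4)) + 0j
        w = np.zeros((2, 1, 1, 1), complex)
        out = complex_conv2d(x, w, bias=np.array([1 + 2j, -3j]))
        assert np.allclose(out[0, 0], 1 + 2j)
        assert np.allclose(out[0, 1], -3j)


class TestSplitActivation:
    def test_nonnegative_input_unchanged(self):
        x = np.array([[1.0 + 2.0j, 0.5 + 0.0j]])
        assert np.array_equal(complex_activation(x), x)

    def test_negative_parts_clipped(self):
        assert complex_activation(np.array(-1.0 - 1.0j)) == 0.0 + 0.0j
        assert complex_activation(np.array(-1.0 + 2.0j)) == 0.0 + 2.0j

    def test_idempotent(self, rng):
        x = rng.standard_normal((5, 5)) + 1j * rng.standard_normal((5, 5))
        once = complex_activation(x)
        assert np.array_equal(complex_activation(once), once)


class TestComplexL1Loss:
    def test_zero_iff_equal(self, rng):
        y = rng.standard_normal((2, 4, 4)) + 1j * rng.standard_normal((2, 4, 4))
        assert complex_l1_loss(y, y) == 0.0
        assert complex_l1_loss(y + 1e-3, y) > 0.0

    def test_hand_values(self):
        assert complex_l1_loss(np.array([0.0 + 0.0j]), np.array([1.0 + 1.0j])) == pytest.approx(2.0)
        assert complex_l1_loss(
            np.array([0.0 + 0.0j, 0.0 + 0.0j]), np.array([3.0 + 4.0j, -1.0 + 0.0j])
        ) == pytest.approx(4.0)

    def test_translation_invariance(self, rng):
        y = rng.standard_normal((3, 3)) + 1j * rng.standard_normal((3, 3))
        yh = rng.standard_normal((3, 3)) + 1j * rng.standard_normal((3, 3))
        c = 0.7 - 1.3j
        assert complex_l1_loss(yh + c, y + c) == pytest.approx(complex_l1_loss(yh, y), rel=1e-12)

    def test_shape_mismatch_raises(self):
        with pytest.raises(ValueError):
            complex_l1_loss(np.ones(3, complex), np.ones(4, complex))
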