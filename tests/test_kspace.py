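"""Fourier conventions and variable-density mask conformance."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from fourierpd.kspace import (
    fft2c,
    ifft2c,
    make_varden1d_mask,
    make_varden2d_mask,
    theoretical_acceleration,
    undersample,
)


class TestCenteredFFT:
    def test_inverse_pair(self, rng):
        x = rng.standard_normal((32, 32)) + 1j * rng.standard_normal((32, 32))
        assert np.abs(ifft2c(fft2c(x)) - x).max() < 1e-10 * np.abs(x).max()

    def test_parseval(self, rng):
        x = rng.standard_normal((48, 48)) + 1j * rng.standard_normal((48, 48))
        e_img = np.sum(np.abs(x) ** 2)
        e_k = np.sum(np.abs(fft2c(x)) ** 2)
        assert abs(e_img - e_k) < 1e-10 * e_img

    def test_centre_impulse_gives_flat_spectrum(self):
        n = 256
        x = np.zeros((n, n), dtype=complex)
        x[n // 2, n // 2] = 1.0  # DC location of the centered convention
        k = fft2c(x)
        assert np.allclose(np.abs(k), 1.0 / n, atol=1e-12)

    def test_rejects_non_2d(self):
        with pytest.raises(ValueError):
            fft2c(np.ones(5))


class TestVarden1D:
    def test_line_count_and_centre_block(self):
        m = make_varden1d_mask((256, 256), 0.25, seed=0)
        line_sampled = m.grid.all(axis=1)
        partial = m.grid.any(axis=1) & ~line_sampled
        assert not partial.any()  # full readout lines only
        assert line_sampled.sum() == 64  # round(0.25 * 256)
        centre = np.arange(124, 132)  # 8 contiguous lines around row 128
        assert line_sampled[centre].all()
        assert m.n_sampled == 64 * 256

    def test_full_fraction_is_all_ones(self):
        m = make_varden1d_mask((64, 64), 1.0, seed=5)
        assert m.grid.all()

    @given(st.integers(0, 10_000), st.sampled_from([0.1, 0.25, 0.5]))
    @settings(max_examples=25, deadline=None, derandomize=True)
    def test_exact_count_any_seed(self, seed, fraction):
        rows = 64
        m = make_varden1d_mask((rows, rows), fraction, centre_lines=4, seed=seed)
        expected = int(np.floor(fraction * rows + 0.5))
        assert m.grid.all(axis=1).sum() == expected

    def test_density_decreases_from_centre(self):
        """Line-selection frequency falls off monotonically (binomial error)."""
        rows = 64
        counts = np.zeros(rows)
        n_draws = 2000
        for seed in range(n_draws):
            m = make_varden1d_mask((rows, 16), 0.25, centre_lines=4, seed=seed)
            counts += m.grid[:, 0]
        # compare coarse bands on one side of the centre, outside the fixed block
        near = counts[36:44].mean()
        mid = counts[44:52].mean()
        far = counts[52:60].mean()
        se = np.sqrt(n_draws * 0.25)  # generous binomial scale
        assert near > mid - 3 * se and mid > far - 3 * se
        assert near > far + 3 * se  # clear overall decay

    def test_reproducible_from_seed(self):
        a = make_varden1d_mask((128, 128), 0.25, seed=11)
        b = make_varden1d_mask((128, 128), 0.25, seed=11)
        assert np.array_equal(a.grid, b.grid)

    def test_rejects_bad_parameters(self):
        with pytest.raises(ValueError):
            make_varden1d_mask((64, 64), 0.0)
        with pytest.raises(ValueError):
            make_varden1d_mask((64, 64), 1.5)
        with pytest.raises(ValueError):
            make_varden1d_mask((64, 64), 0.1, centre_lines=32)


class TestVarden2D:
    def test_exact_point_count(self):
        m = make_varden2d_mask((256, 256), 0.25, seed=1)
        assert m.n_sampled == 16384  # round(0.25 * 65536)

    def test_dense_centre_fully_sampled(self):
        m = make_varden2d_mask((256, 256), 0.25, seed=2)
        n_centre = round(0.025 * 256 * 256)
        r = np.arange(256) - 128
        rr, cc = np.meshgrid(r, r, indexing="ij")
        dist2 = (rr**2 + cc**2).ravel()
        inner = np.sort(dist2)[n_centre - 1]
        strictly_inside = dist2.reshape(256, 256) < inner
        assert m.grid[strictly_inside].all()
        assert strictly_inside.sum() <= n_centre <= m.n_sampled

    def test_full_fraction_is_all_ones(self):
        assert make_varden2d_mask((32, 32), 1.0, seed=0).grid.all()

    def test_centre_fraction_bounds(self):
        with pytest.raises(ValueError):
            make_varden2d_mask((64, 64), 0.02, centre_fraction=0.025)


class TestUndersample:
    def test_identity_and_annihilation(self, rng):
        k = rng.standard_normal((32, 32)) + 1j * rng.standard_normal((32, 32))
        ones = make_varden1d_mask((32, 32), 1.0, seed=0)
        assert np.array_equal(undersample(k, ones), k)
        zero_grid = np.zeros((32, 32))
        assert not undersample(k, zero_grid).any()

    def test_support_bounded_by_mask(self, rng, mask64):
        k = rng.standard_normal((64, 64)) + 1j * rng.standard_normal((64, 64))
        ku = undersample(k, mask64)
        assert (np.abs(ku) > 0).sum() <= mask64.n_sampled
        assert np.abs(ku[mask64.grid == 0]).max() == 0.0

    def test_shape_mismatch(self, rng, mask64):
        with pytest.raises(ValueError):
            undersample(np.ones((32, 32), complex), mask64)

    def test_fully_sampled_roundtrip(self, phantom64):
        ones = make_varden1d_mask((64, 64), 1.0, seed=0)
        rec = ifft2c(undersample(fft2c(phantom64), ones))
        assert np.abs(rec - phantom64).max() < 1e-10


@pytest.mark.parametrize(
    "fraction,accel", [(0.25, 4.0), (0.10, 10.0), (1.0, 1.0)]
)
def test_theoretical_acceleration(fraction, accel):
    m = make_varden1d_mask((64, 64), fraction, centre_lines=4, seed=0)
    assert theoretical_acceleration(m) == pytest.approx(accel)
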