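"""Centred FFT diffraction, windowed profiles, pupil autocorrelation."""

import numpy as np
import pytest

from spikyoptics.aperture_models import ApertureSpec, PupilMask, make_circular, make_spiky
from spikyoptics.analytic_psf import airy
from spikyoptics.numeric_psf import (
    PSFImage,
    WindowProfile,
    diffract,
    line_profile,
    peak_position,
    pupil_autocorrelation,
)


def wrap_mask(a: np.ndarray) -> PupilMask:
    spec = ApertureSpec(grid_size=a.shape[0], inner_radius=1)
    return PupilMask(amplitude=np.asarray(a, dtype=float), spec=spec)


class TestDiffract:
    def test_constant_mask_gives_central_delta(self):
        img = diffract(wrap_mask(np.ones((64, 64))))
        assert img.intensity[32, 32] == 1.0
        off = img.intensity.copy()
        off[32, 32] = 0.0
        assert np.all(np.abs(off) < 1e-20)

    def test_parseval_identity(self):
        rng = np.random.default_rng(0)
        a = (rng.random((128, 128)) > 0.7).astype(float)
        field = np.fft.fftshift(np.fft.fft2(np.fft.ifftshift(a)))
        assert np.sum(np.abs(a) ** 2) == pytest.approx(
            np.sum(np.abs(field) ** 2) / a.size, rel=1e-9
        )
        # and the packaged transform retains that field
        img = diffract(wrap_mask(a))
        assert np.allclose(np.abs(img.amplitude), np.abs(field), atol=1e-9)

    def test_first_dark_ring_radius(self):
        # 900-px diameter pupil in 2048: first Airy zero at 1.22*N/D = 2.78 px
        img = diffract(make_circular(2048, 450))
        row = img.intensity[1024, 1024:1024 + 8]
        minima = [i for i in range(1, 7) if row[i] < row[i - 1] and row[i] <= row[i + 1]]
        assert minima[0] in (2, 3)

    def test_matches_sampled_airy_in_main_lobes(self):
        n, radius = 1024, 256
        img = diffract(make_circular(n, radius))
        c = n // 2
        v, u = np.ogrid[:n, :n]
        warg = 2 * np.pi * radius * np.hypot(u - c, v - c) / n
        sel = warg <= 13.3237  # out to the third dark ring
        expected = airy(warg[sel]) ** 2
        err = np.linalg.norm(img.intensity[sel] - expected) / np.linalg.norm(expected)
        assert err < 0.02

    def test_centered_symmetric_pupil_gives_symmetric_intensity(self):
        img = diffract(make_circular(256, 60))
        a = img.intensity
        flipped = np.roll(np.flip(a), (1, 1), axis=(0, 1))  # point reflection about (N/2, N/2)
        assert np.allclose(a, flipped, atol=1e-9)

    def test_peak_always_at_center_for_nonnegative_pupils(self):
        for seed in (0, 5):
            spec = ApertureSpec(
                grid_size=256, inner_radius=60, spike_length=12, n_spikes=7,
                spike_mode="irregular", seed=seed,
            )
            img = diffract(make_spiky(spec))
            assert np.unravel_index(np.argmax(img.intensity), img.intensity.shape) == (128, 128)

    def test_fwhm_shrinks_with_aperture_diameter(self):
        def central_fwhm(diameter):
            img = diffract(make_circular(2048, diameter // 2))
            row = img.intensity[1024]
            return np.sum(row >= 0.5)

        widths = [central_fwhm(d) for d in (256, 512, 900, 1360)]
        assert all(a >= b for a, b in zip(widths, widths[1:]))

    def test_zero_mask_rejected(self):
        with pytest.raises(ValueError):
            diffract(wrap_mask(np.zeros((32, 32))))

    def test_padding_refines_sampling(self):
        img = diffract(make_circular(256, 60), pad=2)
        assert img.intensity.shape == (512, 512)
        assert img.intensity[256, 256] == 1.0


class TestLineProfile:
    def make_image(self, n=64):
        return diffract(make_circular(n, 16))

    def test_center_lands_at_documented_window_position(self):
        img = self.make_image(64)
        prof = line_profile(img, "row", 33, 20, 50)
        # centre pixel 1-based 33 -> position 33 - 20 + 1 = 14
        assert peak_position(prof) == 14

    def test_column_and_row_agree_for_symmetric_psf(self):
        img = self.make_image(64)
        r = line_profile(img, "row", 33, 10, 56)
        c = line_profile(img, "column", 33, 10, 56)
        assert np.allclose(r.values, c.values, atol=1e-9)

    def test_window_renormalized_to_unit_max(self):
        img = self.make_image(64)
        prof = line_profile(img, "row", 33, 40, 60)  # off-centre window
        assert prof.values.max() == pytest.approx(1.0)

    def test_out_of_bounds_window_rejected(self):
        img = self.make_image(64)
        with pytest.raises(IndexError):
            line_profile(img, "row", 33, 0, 10)
        with pytest.raises(IndexError):
            line_profile(img, "row", 33, 60, 70)
        with pytest.raises(IndexError):
            line_profile(img, "row", 65, 10, 20)


class TestPeakPosition:
    def test_simple_and_tie_cases(self):
        assert peak_position(WindowProfile(np.array([0.0, 1.0, 0.0]), 5, 7, 1)) == 2
        assert peak_position(WindowProfile(np.array([1.0, 1.0, 0.0]), 5, 7, 1)) == 1

    def test_window_conventions_from_reference_geometries(self):
        # 2048-frame: centre 1-based 1025 -> position 36 in [990, 1058]
        img = PSFImage(intensity=np.zeros((2048, 2048)))
        intensity = img.intensity
        intensity[1024, 1024] = 1.0
        prof = line_profile(PSFImage(intensity=intensity), "row", 1025, 990, 1058)
        assert peak_position(prof) == 36
        # 512-frame: centre 1-based 257 -> position 22 in [236, 296]
        i2 = np.zeros((512, 512))
        i2[256, 256] = 1.0
        prof2 = line_profile(PSFImage(intensity=i2), "row", 257, 236, 296)
        assert peak_position(prof2) == 22


class TestAutocorrelation:
    def test_zero_lag_counts_on_pixels(self):
        rng = np.random.default_rng(1)
        a = (rng.random((32, 32)) > 0.5).astype(float)
        corr = pupil_autocorrelation(wrap_mask(a), normalized=False)
        assert corr[31, 31] == pytest.approx(a.sum(), rel=1e-12)

    def test_support_bounded_by_twice_mask_support(self):
        mask = make_circular(64, 10)
        corr = pupil_autocorrelation(mask)
        c = corr.shape[0] // 2
        v, u = np.ogrid[: corr.shape[0], : corr.shape[1]]
        rho = np.hypot(u - c, v - c)
        assert np.all(corr[rho > 2 * 10 + 2] < 1e-9)

    def test_matches_brute_force_sliding_dot_product(self):
        rng = np.random.default_rng(2)
        a = (rng.random((16, 16)) > 0.5).astype(float)
        corr = pupil_autocorrelation(wrap_mask(a), normalized=False)
        n = 16
        brute = np.zeros((2 * n - 1, 2 * n - 1))
        for di in range(-(n - 1), n):
            for dj in range(-(n - 1), n):
                s = 0.0
                for i in range(n):
                    for j in range(n):
                        i2, j2 = i + di, j + dj
                        if 0 <= i2 < n and 0 <= j2 < n:
                            s += a[i, j] * a[i2, j2]
                brute[di + n - 1, dj + n - 1] = s
        assert np.allclose(corr, brute, atol=1e-9)

    def test_point_reflection_symmetry(self):
        spec = ApertureSpec(
            grid_size=64, inner_radius=12, spike_length=4, n_spikes=5,
            spike_mode="irregular", seed=9,
        )
        corr = pupil_autocorrelation(make_spiky(spec))
        assert np.allclose(corr, corr[::-1, ::-1], atol=1e-9)

    def test_zero_mask_rejected(self):
        with pytest.raises(ValueError):
            pupil_autocorrelation(wrap_mask(np.zeros((16, 16))))
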