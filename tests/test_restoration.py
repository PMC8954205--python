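"""Restoration: PSF closed forms, TV-l1 objective/descent, MMWF oracle."""

import numpy as np
import pytest
from skimage.metrics import peak_signal_noise_ratio as psnr

from limbicnet.restoration import (MMWFConfig, RestorationConfig,
                                   TVDeblurConfig, blur_slice, make_psf,
                                   mmwf_denoise, mmwf_window_stats,
                                   restore_volume, tv_l1_deblur, tv_objective)
from limbicnet.volume import Volume


def piecewise_slice(n=32, rng=None):
    """Piecewise-constant test slice: background 0, disc 1, inner square 1.6."""
    s = np.zeros((n, n))
    yy, xx = np.mgrid[:n, :n]
    s[(yy - n / 2) ** 2 + (xx - n / 2) ** 2 < (0.4 * n) ** 2] = 1.0
    s[n // 2 - n // 8: n // 2 + n // 8, n // 2 - n // 8: n // 2 + n // 8] = 1.6
    if rng is not None:
        s *= 1.0 + 0.0 * rng.normal()  # keep signature symmetric
    return s


class TestMakePsf:
    def test_gaussian_ratio_closed_form(self):
        k = make_psf(2.0, half_width=5)
        c = k.half_width
        assert k.kernel[c + 1, c] / k.kernel[c, c] == pytest.approx(
            np.exp(-1.0 / 8.0), rel=1e-12)

    def test_unit_sum_and_center_max(self):
        for sigma in (0.5, 1.0, 2.0, 3.7):
            k = make_psf(sigma)
            assert k.kernel.sum() == pytest.approx(1.0, abs=1e-12)
            assert k.kernel.max() == k.kernel[k.half_width, k.half_width]

    def test_radial_symmetry(self):
        k = make_psf(2.0, half_width=5)
        c = k.half_width
        assert k.kernel[c + 3, c + 4] == k.kernel[c + 4, c + 3]
        assert k.kernel[c + 3, c + 4] == k.kernel[c - 3, c - 4]

    def test_default_half_width_is_3_sigma(self):
        assert make_psf(2.0).half_width == 6
        assert make_psf(1.1).half_width == 4

    def test_nonpositive_sigma_rejected(self):
        with pytest.raises(ValueError):
            make_psf(0.0)


class TestTvObjective:
    def test_exact_fit_constant_slice_is_zero(self):
        g = np.full((8, 8), 3.0)
        assert tv_objective(g, g, make_psf(1.5), 0.01) == pytest.approx(0.0)

    def test_constant_offset_closed_form(self):
        f = np.full((8, 8), 2.0)
        g = np.full((8, 8), 2.5)
        assert tv_objective(f, g, make_psf(1.0), 0.1) == pytest.approx(
            0.5 * 64, rel=1e-12)

    def test_step_edge_hand_computed(self):
        """4x4 slice with a unit step between columns 1 and 2, identity psf,
        f = g: fidelity 0, penalty = lambda x 4 unit jumps."""
        g = np.zeros((4, 4))
        g[:, 2:] = 1.0
        ident = make_psf(0.05, half_width=1)  # effectively a delta kernel
        obj = tv_objective(g, g, ident, 0.01)
        assert obj == pytest.approx(0.01 * 4, abs=1e-6)

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            tv_objective(np.zeros((4, 4)), np.zeros((5, 4)), make_psf(1.0), 0.01)


class TestTvDeblur:
    def test_constant_slice_is_fixed_point(self):
        g = np.full((16, 16), 2.0)
        f = tv_l1_deblur(g, make_psf(1.5))
        np.testing.assert_allclose(f, g, atol=1e-8)

    @pytest.mark.parametrize("sigma", [1.0, 2.0])
    def test_objective_descent_on_blurred_phantom(self, sigma):
        clean = piecewise_slice()
        psf = make_psf(sigma)
        g = blur_slice(clean, psf)
        cfg = TVDeblurConfig()
        f, trace = tv_l1_deblur(g, psf, cfg, return_trace=True)
        assert tv_objective(f, g, psf, cfg.lambda_) < tv_objective(
            g, g, psf, cfg.lambda_)
        assert all(b <= a + 1e-12 for a, b in zip(trace, trace[1:]))

    @pytest.mark.parametrize("sigma", [1.0, 2.0])
    def test_psnr_gain_on_noiseless_blur(self, sigma):
        clean = piecewise_slice()
        psf = make_psf(sigma)
        g = blur_slice(clean, psf)
        f = tv_l1_deblur(g, psf)
        dr = clean.max()
        assert psnr(clean, f, data_range=dr) > psnr(clean, g, data_range=dr)

    def test_nonnegative_output(self):
        rng = np.random.default_rng(0)
        g = np.clip(rng.normal(0.2, 0.3, (24, 24)), 0, None)
        f = tv_l1_deblur(g, make_psf(1.0))
        assert (f >= 0).all()

    def test_nonfinite_input_rejected(self):
        g = np.full((8, 8), np.nan)
        with pytest.raises(ValueError):
            tv_l1_deblur(g, make_psf(1.0))

    def test_shift_equivariance_away_from_boundary(self):
        """Circularly shifting a centered object commutes with deblurring
        when a zero band keeps the content off the boundary."""
        clean = np.zeros((40, 40))
        clean[14:26, 14:26] = 1.0
        clean[18:22, 18:22] = 1.8
        psf = make_psf(1.0)
        g = blur_slice(clean, psf)
        shift = (3, 2)
        g_shift = np.roll(g, shift, axis=(0, 1))
        f = tv_l1_deblur(g, psf)
        f_shift = tv_l1_deblur(g_shift, psf)
        # tiny float asymmetries in the FFT solves can flip the monotone
        # accept/reject decision on ties, so equality is approximate
        np.testing.assert_allclose(np.roll(f, shift, axis=(0, 1)), f_shift,
                                   atol=5e-4)


def mmwf_bruteforce(g, window, gamma_sq=None):
    """Independent per-pixel loop oracle for the MMWF."""
    h = window // 2
    gp = np.pad(g, h, mode="symmetric")
    H, W = g.shape
    mus = np.zeros_like(g, dtype=float)
    variances = np.zeros_like(g, dtype=float)
    for i in range(H):
        for j in range(W):
            win = gp[i:i + window, j:j + window].ravel()
            mus[i, j] = np.median(win)
            variances[i, j] = np.var(win)
    if gamma_sq is None:
        gamma_sq = variances.mean()
    out = np.zeros_like(g, dtype=float)
    for i in range(H):
        for j in range(W):
            s2 = variances[i, j]
            gain = max(s2 - gamma_sq, 0.0) / s2 if s2 > 0 else 0.0
            out[i, j] = mus[i, j] + gain * (g[i, j] - mus[i, j])
    return out


class TestMmwfWindowStats:
    def test_constant_window(self):
        st = mmwf_window_stats(np.full(9, 4.0))
        assert st.mu_bar == 4.0 and st.sigma_n_sq == 0.0

    def test_single_spike_hand_computed(self):
        w = np.array([0, 0, 0, 0, 10, 0, 0, 0, 0], dtype=float)
        st = mmwf_window_stats(w)
        assert st.mu_bar == 0.0
        assert st.sigma_n_sq == pytest.approx(800.0 / 81.0, rel=1e-12)

    def test_even_count_median(self):
        st = mmwf_window_stats(np.array([1.0, 2.0, 3.0, 4.0]))
        assert st.mu_bar == 2.5


class TestMmwfDenoise:
    def test_matches_bruteforce_oracle(self, rng):
        for _ in range(5):
            g = rng.normal(1.0, 0.3, (16, 16))
            for window in (3, 5):
                got = mmwf_denoise(g, MMWFConfig(window=window))
                want = mmwf_bruteforce(g, window)
                np.testing.assert_allclose(got, want, atol=1e-9)

    def test_zero_gamma_is_identity(self, rng):
        g = rng.normal(1.0, 0.3, (12, 12))
        cfg = MMWFConfig(window=3, gamma_sq_rule="fixed", gamma_sq_fixed=0.0)
        np.testing.assert_allclose(mmwf_denoise(g, cfg), g, atol=1e-12)

    def test_gamma_equals_variance_gives_median_filter(self):
        """On a constant-variance image, gamma^2 = sigma_n^2 everywhere
        reduces the filter to the local-median map."""
        from scipy.ndimage import median_filter
        g = np.tile(np.array([[0.0, 1.0], [1.0, 0.0]]), (6, 6))
        st = mmwf_window_stats(np.pad(g, 1, mode="symmetric")[:3, :3])
        cfg = MMWFConfig(window=3, gamma_sq_rule="fixed",
                         gamma_sq_fixed=st.sigma_n_sq)
        out = mmwf_denoise(g, cfg)
        want = median_filter(g, size=3, mode="reflect")
        np.testing.assert_allclose(out, want, atol=1e-12)

    def test_spike_center_hand_computed(self):
        """5x5 zero slice with center 10, window 3, fixed gamma^2=2:
        center output = (1 - 2/(800/81)) x 10."""
        g = np.zeros((5, 5))
        g[2, 2] = 10.0
        cfg = MMWFConfig(window=3, gamma_sq_rule="fixed", gamma_sq_fixed=2.0)
        out = mmwf_denoise(g, cfg)
        expected = (1.0 - 2.0 / (800.0 / 81.0)) * 10.0
        assert out[2, 2] == pytest.approx(expected, rel=1e-9)

    def test_psnr_gain_on_noise_only(self):
        """MMWF increases PSNR vs truth averaged over >= 10 noisy slices."""
        rng = np.random.default_rng(42)
        gains = []
        for _ in range(10):
            clean = piecewise_slice()
            noisy = np.clip(clean + rng.normal(0, 0.12, clean.shape), 0, None)
            den = mmwf_denoise(noisy, MMWFConfig(window=5))
            dr = clean.max()
            gains.append(psnr(clean, den, data_range=dr)
                         - psnr(clean, noisy, data_range=dr))
        assert np.mean(gains) > 0
        assert np.all(np.array(gains) > 0)

    def test_shift_equivariance_with_fixed_gamma(self):
        rng = np.random.default_rng(9)
        g = np.zeros((24, 24))
        g[8:16, 8:16] = rng.normal(1.0, 0.2, (8, 8))
        cfg = MMWFConfig(window=3, gamma_sq_rule="fixed", gamma_sq_fixed=0.01)
        out = mmwf_denoise(g, cfg)
        out_shift = mmwf_denoise(np.roll(g, (2, 3), axis=(0, 1)), cfg)
        np.testing.assert_allclose(np.roll(out, (2, 3), axis=(0, 1)),
                                   out_shift, atol=1e-12)


class TestRestoreVolume:
    def test_none_is_identity(self, rng):
        vol = Volume(np.abs(rng.normal(1, 0.2, (8, 8, 5))))
        out = restore_volume(vol, RestorationConfig(method="none"))
        np.testing.assert_array_equal(out.data, vol.data)

    def test_deblur_on_zero_volume(self):
        vol = Volume(np.zeros((8, 8, 4)))
        out = restore_volume(vol, RestorationConfig(method="deblur", sigma_b=1.0))
        np.testing.assert_allclose(out.data, 0.0, atol=1e-12)

    def test_denoise_composes_slicewise(self, rng):
        vol = Volume(np.abs(rng.normal(1, 0.2, (12, 12, 4))))
        cfg = RestorationConfig(method="denoise", mmwf=MMWFConfig(window=3))
        out = restore_volume(vol, cfg)
        for z in range(vol.n_slices):
            np.testing.assert_allclose(
                out.data[:, :, z],
                np.clip(mmwf_denoise(vol.data[:, :, z], cfg.mmwf), 0, None))

    def test_unknown_method_rejected(self):
        with pytest.raises(ValueError, match="allowed"):
            RestorationConfig(method="sharpen")
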