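"""Unit and property tests for the raster correlation module."""

from __future__ import annotations

import numpy as np
import pytest

from cytodyn.core import (GAMMA_2D, ImageSeries, RasterScanConfig, RegionMask,
                          default_confocal_scan)
from cytodyn.rics import (CorrelationSurface, arbitrary_region_acf,
                          compare_regions, fit_rics, highpass_detrend,
                          rics_model)
from conftest import brute_force_acf


# ---------------------------------------------------------------- model

class TestRICSModel:
    @pytest.mark.parametrize("D", [0.0, 0.1, 1.0, 50.0])
    def test_zero_lag_amplitude_is_gamma(self, small_scan, D):
        assert rics_model(0, 0, D, 1.0, small_scan) == pytest.approx(
            2 ** (-1.5), abs=1e-12)

    def test_amplitude_scales_inverse_n(self, small_scan):
        assert rics_model(0, 0, 1.0, 4.0, small_scan) == pytest.approx(
            GAMMA_2D / 4.0, abs=1e-12)

    def test_static_limit_gaussian(self):
        # D=0: pure PSF Gaussian, delta_r=50, omega_r=250, xi=5 -> gamma*exp(-1)
        scan = RasterScanConfig(delta_r=50, tau_p=8.19, tau_l=4.92,
                                tau_frame=1.26, omega_r=250, image_size=(64, 64))
        val = rics_model(5, 0, 0.0, 1.0, scan)
        assert val == pytest.approx(GAMMA_2D * np.exp(-1.0), rel=1e-12)

    def test_strictly_decreasing_along_fast_axis(self, small_scan):
        for D in (0.0, 0.5, 5.0):
            xi = np.arange(0, 30)
            g = rics_model(xi, 0, D, 1.0, small_scan)
            assert np.all(np.diff(g) < 0)

    def test_rejects_nonpositive_n(self, small_scan):
        with pytest.raises(ValueError, match="N"):
            rics_model(0, 0, 1.0, 0.0, small_scan)

    def test_finite_everywhere(self, small_scan):
        xi, psi = np.meshgrid(np.arange(-40, 41), np.arange(-40, 41))
        g = rics_model(xi, psi, 123.4, 0.01, small_scan)
        assert np.all(np.isfinite(g))


# ---------------------------------------------------------------- detrend

class TestHighpassDetrend:
    def test_constant_series_unchanged(self):
        s = ImageSeries(data=np.full((20, 8, 8), 7.0))
        out = highpass_detrend(s, 5)
        np.testing.assert_allclose(out.data, s.data, atol=1e-12)

    def test_window_equal_t_subtracts_temporal_mean(self, rng):
        data = rng.uniform(1, 3, size=(16, 6, 6))
        s = ImageSeries(data=data)
        out = highpass_detrend(s, 16)
        expect = data - data.mean(axis=0) + data.mean()
        np.testing.assert_allclose(out.data, expect, atol=1e-10)

    def test_mean_preserved(self, rng):
        data = rng.uniform(0, 10, size=(30, 8, 8))
        out = highpass_detrend(ImageSeries(data=data), 10)
        assert out.data.mean() == pytest.approx(data.mean(), abs=1e-10)

    def test_linear_ramp_suppressed_10x(self, rng):
        T = 200
        ramp = np.linspace(0.0, 100.0, T)[:, None, None] * np.ones((1, 8, 8))
        data = ramp + rng.normal(0, 1, (T, 8, 8))
        out = highpass_detrend(ImageSeries(data=data), 10)

        def trend_amplitude(x):
            t = np.arange(T) - (T - 1) / 2
            px = x.reshape(T, -1).mean(axis=1)
            slope = (t * (px - px.mean())).sum() / (t**2).sum()
            return abs(slope) * T

        assert trend_amplitude(data) / trend_amplitude(out.data) >= 10.0

    def test_rejects_bad_window(self):
        s = ImageSeries(data=np.zeros((5, 4, 4)))
        with pytest.raises(ValueError):
            highpass_detrend(s, 6)
        with pytest.raises(ValueError):
            highpass_detrend(s, 1)


# ---------------------------------------------------------------- ACF

class TestArbitraryRegionACF:
    def test_constant_image_zero_acf(self):
        s = ImageSeries(data=np.full((3, 8, 8), 5.0))
        surf = arbitrary_region_acf(s, RegionMask(np.ones((8, 8), bool)))
        np.testing.assert_allclose(surf.G[np.isfinite(surf.G)], 0.0, atol=1e-14)

    def test_matches_quadruple_loop_oracle(self, rng):
        data = rng.uniform(1, 2, size=(3, 8, 8))
        mask = rng.random((8, 8)) > 0.3
        surf = arbitrary_region_acf(ImageSeries(data=data), RegionMask(mask),
                                    max_lag_xi=4, max_lag_psi=4)
        oracle = brute_force_acf(data, mask, 4, 4)
        both = np.isfinite(surf.G) & np.isfinite(oracle)
        assert np.abs(surf.G[both] - oracle[both]).max() < 1e-12
        np.testing.assert_array_equal(np.isfinite(surf.G), np.isfinite(oracle))

    def test_symmetry_exact(self, rng):
        data = rng.uniform(1, 2, size=(2, 12, 12))
        mask = rng.random((12, 12)) > 0.4
        surf = arbitrary_region_acf(ImageSeries(data=data), RegionMask(mask))
        G = surf.G
        np.testing.assert_array_equal(G, G[::-1, ::-1])

    def test_poisson_noise_zero_lag(self, rng):
        # independent Poisson, mean mu: G(0,0) ~ 1/mu, off-lags ~ 0
        mu = 20.0
        data = rng.poisson(mu, size=(200, 32, 32)).astype(float)
        surf = arbitrary_region_acf(ImageSeries(data=data),
                                    RegionMask(np.ones((32, 32), bool)))
        assert surf.value(0, 0) == pytest.approx(1.0 / mu, rel=0.1)
        assert abs(surf.value(3, 0)) < 5e-4
        assert abs(surf.value(0, 2)) < 5e-4

    def test_full_frame_equals_unmasked_fft(self, rng):
        data = rng.uniform(1, 4, size=(2, 16, 16))
        surf = arbitrary_region_acf(ImageSeries(data=data),
                                    RegionMask(np.ones((16, 16), bool)))
        # independent unmasked route: zero-padded np.fft autocorrelation
        T, ny, nx = data.shape
        acc = np.zeros((2 * ny - 1, 2 * nx - 1))
        counts = np.outer(ny - np.abs(np.arange(-(ny - 1), ny)),
                          nx - np.abs(np.arange(-(nx - 1), nx)))
        for frame in data:
            mu = frame.mean()
            d = frame - mu
            F = np.fft.rfft2(d, s=(2 * ny - 1, 2 * nx - 1))
            corr = np.fft.irfft2(F * np.conj(F), s=(2 * ny - 1, 2 * nx - 1))
            corr = np.fft.fftshift(corr)
            acc += corr / counts / mu**2
        ref = acc / T
        ci, cj = nx - 1, ny - 1
        sub = ref[cj - surf.max_psi:cj + surf.max_psi + 1,
                  ci - surf.max_xi:ci + surf.max_xi + 1]
        np.testing.assert_allclose(surf.G, sub, atol=1e-10)

    def test_rejects_nonpositive_masked_mean(self):
        data = np.zeros((2, 8, 8))
        with pytest.raises(ValueError, match="mean"):
            arbitrary_region_acf(ImageSeries(data=data),
                                 RegionMask(np.ones((8, 8), bool)))


# ---------------------------------------------------------------- fitting

def _model_surface(scan, D, N, max_xi=16, max_psi=4):
    xi = np.arange(-max_xi, max_xi + 1)
    psi = np.arange(-max_psi, max_psi + 1)
    XI, PSI = np.meshgrid(xi, psi)
    G = rics_model(XI, PSI, D, N, scan)
    return CorrelationSurface(G=G, xi_lags=xi, psi_lags=psi,
                              n_pairs=np.ones_like(G, dtype=int))


class TestFitRICS:
    def test_self_consistency(self, small_scan):
        surf = _model_surface(small_scan, D=0.5, N=10.0)
        fit = fit_rics(surf, small_scan)
        assert fit.converged
        assert fit.D == pytest.approx(0.5, rel=1e-6)
        assert fit.N == pytest.approx(10.0, rel=1e-6)
        assert abs(fit.offset) < 1e-9

    def test_explicit_init_honored(self, small_scan):
        surf = _model_surface(small_scan, D=2.0, N=3.0)
        fit = fit_rics(surf, small_scan, init=(1.0, 1.0))
        assert fit.D == pytest.approx(2.0, rel=1e-6)

    def test_zero_lag_model_identity(self, small_scan):
        # G_model(0,0) + offset == gamma/N + offset by construction
        fit = fit_rics(_model_surface(small_scan, 1.0, 5.0), small_scan)
        g00 = rics_model(0, 0, fit.D, fit.N, small_scan) + fit.offset
        assert g00 == pytest.approx(GAMMA_2D / fit.N + fit.offset, abs=1e-12)

    def test_all_zero_surface_rejected(self, small_scan):
        surf = _model_surface(small_scan, 1.0, 5.0)
        surf.G[:] = 0.0
        with pytest.raises(ValueError):
            fit_rics(surf, small_scan)

    def test_narrow_surface_rejected(self, small_scan):
        xi = np.arange(-4, 5)
        psi = np.arange(-2, 3)
        G = np.ones((5, 9))
        surf = CorrelationSurface(G=G, xi_lags=xi, psi_lags=psi,
                                  n_pairs=np.ones_like(G))
        with pytest.raises(ValueError, match="8 px"):
            fit_rics(surf, small_scan)

    def test_ordering_preserved(self, small_scan):
        from cytodyn.simgen import DiffusionSimSpec, simulate_diffusion_raster
        fits = []
        for D in (0.2, 2.0):
            spec = DiffusionSimSpec(D_true=D, particle_density=1.0,
                                    brightness=5.0, scan=small_scan,
                                    n_frames=30, seed=7)
            series = simulate_diffusion_raster(spec)
            det = highpass_detrend(series, 10)
            surf = arbitrary_region_acf(det, RegionMask(np.ones((64, 64), bool)))
            fits.append(fit_rics(surf, small_scan))
        assert fits[0].D < fits[1].D


class TestRecoveryScaling:
    def test_error_shrinks_with_more_frames(self, small_scan):
        # scaled-down version of the frame-doubling invariant: median
        # relative error over seeds improves when the frame count doubles
        from cytodyn.simgen import DiffusionSimSpec, simulate_diffusion_raster
        mask = RegionMask(np.ones((64, 64), bool))

        def median_err(n_frames):
            errs = []
            for seed in range(8):
                spec = DiffusionSimSpec(D_true=1.0, particle_density=1.0,
                                        brightness=5.0, scan=small_scan,
                                        n_frames=n_frames, seed=seed)
                det = highpass_detrend(simulate_diffusion_raster(spec), 10)
                fit = fit_rics(arbitrary_region_acf(det, mask), small_scan)
                errs.append(abs(fit.D - 1.0))
            return float(np.median(errs))

        e_short = median_err(20)
        e_long = median_err(40)
        assert e_long <= 0.20          # median error within tolerance
        assert e_long <= e_short * 1.2  # no degradation; typically shrinks


class TestCompareRegions:
    def test_single_mask_matches_fit_rics(self, small_scan):
        from cytodyn.simgen import DiffusionSimSpec, simulate_diffusion_raster
        spec = DiffusionSimSpec(D_true=1.0, particle_density=1.0,
                                brightness=5.0, scan=small_scan,
                                n_frames=20, seed=3)
        series = simulate_diffusion_raster(spec)
        mask = RegionMask(np.ones((64, 64), bool), label="full")
        table = compare_regions(series, [mask])
        det = highpass_detrend(series, 10)
        direct = fit_rics(arbitrary_region_acf(det, mask), small_scan)
        assert table.loc[0, "D_um2_per_s"] == pytest.approx(direct.D, rel=1e-9)

    def test_two_masks_homogeneous_consistent(self, small_scan):
        from cytodyn.simgen import DiffusionSimSpec, simulate_diffusion_raster
        spec = DiffusionSimSpec(D_true=1.0, particle_density=1.5,
                                brightness=6.0, scan=small_scan,
                                n_frames=40, seed=11)
        series = simulate_diffusion_raster(spec)
        left = np.zeros((64, 64), bool)
        left[:, :32] = True
        masks = [RegionMask(left, "left"), RegionMask(~left, "right")]
        table = compare_regions(series, masks)
        d = table["D_um2_per_s"].to_numpy()
        assert np.all(d > 0)
        assert abs(d[0] - d[1]) / d.mean() < 1.0   # same ground truth

    def test_empty_mask_list_rejected(self, small_scan):
        s = ImageSeries(data=np.ones((3, 64, 64)), scan=small_scan)
        with pytest.raises(ValueError):
            compare_regions(s, [])

    def test_small_mask_rejected(self, small_scan):
        s = ImageSeries(data=np.ones((3, 64, 64)), scan=small_scan)
        tiny = np.zeros((64, 64), bool)
        tiny[0, :10] = True
        with pytest.raises(ValueError, match="64"):
            compare_regions(s, [RegionMask(tiny)])
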