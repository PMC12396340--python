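"""Tests for the synthetic-data generators."""

from __future__ import annotations

import numpy as np
import pytest

from cytodyn.core import default_confocal_scan
from cytodyn.simgen import (DiffusionSimSpec, DisplacementSpec,
                            PlantedPunctaSpec, expected_mean_intensity,
                            make_shifted_pair, make_star_skeleton,
                            make_translating_mask_series, plant_engulfment,
                            plant_puncta, simulate_diffusion_raster)


class TestDiffusionSim:
    def test_determinism(self, small_scan):
        spec = DiffusionSimSpec(D_true=0.5, particle_density=1.0,
                                brightness=5.0, scan=small_scan,
                                n_frames=5, seed=42)
        a = simulate_diffusion_raster(spec)
        b = simulate_diffusion_raster(spec)
        np.testing.assert_array_equal(a.data, b.data)

    def test_photon_counts_nonnegative_integer(self, small_scan):
        spec = DiffusionSimSpec(D_true=1.0, particle_density=0.5,
                                brightness=3.0, scan=small_scan,
                                n_frames=3, seed=0)
        s = simulate_diffusion_raster(spec)
        assert np.issubdtype(s.data.dtype, np.integer)
        assert (s.data >= 0).all()

    def test_mean_matches_closed_form(self, small_scan):
        spec = DiffusionSimSpec(D_true=1.0, particle_density=2.0,
                                brightness=10.0, scan=small_scan,
                                n_frames=50, seed=5)
        s = simulate_diffusion_raster(spec)
        expect = expected_mean_intensity(spec)
        # standard error over all pixels of all frames (conservative bound:
        # particle-number fluctuations dominate, use 3 sigma of frame means)
        frame_means = s.data.reshape(s.n_frames, -1).mean(axis=1)
        se = frame_means.std(ddof=1) / np.sqrt(s.n_frames)
        assert abs(frame_means.mean() - expect) < 3 * max(se, 1e-3)

    def test_frozen_particles_pure_shot_noise(self, small_scan):
        spec = DiffusionSimSpec(D_true=0.0, particle_density=1.0,
                                brightness=20.0, scan=small_scan,
                                n_frames=60, seed=9)
        s = simulate_diffusion_raster(spec).data.astype(float)
        # Fano factor of the temporal fluctuations ~ 1 (Poisson only)
        mean_px = s.mean(axis=0)
        var_px = s.var(axis=0, ddof=1)
        bright = mean_px > 0.5
        fano = (var_px[bright] / mean_px[bright]).mean()
        assert fano == pytest.approx(1.0, abs=0.1)

    def test_invalid_parameters_named(self, small_scan):
        with pytest.raises(ValueError, match="D_true"):
            DiffusionSimSpec(D_true=-1.0, particle_density=1.0, brightness=1.0,
                             scan=small_scan)
        with pytest.raises(ValueError, match="particle_density"):
            DiffusionSimSpec(D_true=1.0, particle_density=0.0, brightness=1.0,
                             scan=small_scan)
        with pytest.raises(ValueError, match="brightness"):
            DiffusionSimSpec(D_true=1.0, particle_density=1.0, brightness=float("nan"),
                             scan=small_scan)
        with pytest.raises(ValueError, match="n_frames"):
            DiffusionSimSpec(D_true=1.0, particle_density=1.0, brightness=1.0,
                             scan=small_scan, n_frames=1)


class TestShiftedPair:
    def test_zero_shift_identical(self):
        a, b = make_shifted_pair(0, DisplacementSpec(shift=(0, 0)))
        np.testing.assert_array_equal(a, b)

    def test_integer_shift_is_exact_roll(self):
        a, b = make_shifted_pair(1, DisplacementSpec(shift=(3, 2)))
        np.testing.assert_array_equal(b, np.roll(a, (2, 3), axis=(0, 1)))

    def test_fractional_shift_periodic_consistency(self):
        # two quarter-pixel shifts compose to one half-pixel shift
        a, b_half = make_shifted_pair(2, DisplacementSpec(shift=(0.5, 0)))
        _, b_q = make_shifted_pair(2, DisplacementSpec(shift=(0.25, 0)))
        import scipy.ndimage as ndi
        b_qq = np.fft.ifftn(ndi.fourier_shift(np.fft.fftn(b_q), (0, 0.25))).real
        # taking .real between shifts breaks Hermitian symmetry at the
        # Nyquist bin, so composition is only approximate there
        np.testing.assert_allclose(b_half, b_qq, atol=1e-4)

    def test_determinism_with_noise(self):
        spec = DisplacementSpec(shift=(1.5, -0.5), noise_sd=0.1, seed=7)
        a1, b1 = make_shifted_pair(3, spec)
        a2, b2 = make_shifted_pair(3, spec)
        np.testing.assert_array_equal(a1, a2)
        np.testing.assert_array_equal(b1, b2)

    def test_oversize_shift_rejected(self):
        with pytest.raises(ValueError):
            make_shifted_pair(0, DisplacementSpec(shift=(100, 0)), shape=(64, 64))


class TestTranslatingMasks:
    def test_square_step_geometry(self, square_mask):
        s = make_translating_mask_series(square_mask, (2, 0), 6, field=(12, 40))
        for k in range(5):
            sym = (s.data[k] ^ s.data[k + 1]).sum()
            add = (s.data[k + 1] & ~s.data[k]).sum()
            assert sym == 40
            assert add == 20

    def test_zero_step_all_identical(self, square_mask):
        s = make_translating_mask_series(square_mask, (0, 0), 4)
        for k in range(1, 4):
            np.testing.assert_array_equal(s.data[k], s.data[0])

    def test_step_equal_width_disjoint(self, square_mask):
        s = make_translating_mask_series(square_mask, (10, 0), 3, field=(11, 40))
        assert not (s.data[0] & s.data[1]).any()
        assert (s.data[0] ^ s.data[1]).sum() == 200

    def test_leaving_field_rejected(self, square_mask):
        with pytest.raises(ValueError, match="field"):
            make_translating_mask_series(square_mask, (5, 0), 10, field=(12, 20))


class TestStarSkeleton:
    def test_analytic_branch_length(self):
        from cytodyn.morpho import total_branch_length
        sk = make_star_skeleton(6, 20.0)
        assert total_branch_length(sk) == pytest.approx(120.0, abs=1e-9)

    def test_single_branch(self):
        from cytodyn.morpho import sholl
        sk = make_star_skeleton(1, 10.0)
        prof = sholl(sk, step=2.0, max_radius=10.0)
        assert list(prof.intersections[:4]) == [1, 1, 1, 1]

    def test_bifurcation_doubles_crossings(self):
        from cytodyn.morpho import sholl
        sk = make_star_skeleton(4, 20.0, bifurcate_at=10.0)
        prof = sholl(sk, step=1.0, max_radius=20.0)
        by_r = dict(zip(prof.radii, prof.intersections))
        assert by_r[5.0] == 4
        assert by_r[15.0] == 8

    def test_invalid_bifurcation_rejected(self):
        with pytest.raises(ValueError):
            make_star_skeleton(3, 10.0, bifurcate_at=10.0)
        with pytest.raises(ValueError):
            make_star_skeleton(0, 10.0)


class TestPlantPuncta:
    def test_pair_distances_exact(self):
        spec = PlantedPunctaSpec(n_pairs=7, pair_distance=30.0,
                                 n_singles_a=5, n_singles_b=5, seed=1)
        pa, pb, img = plant_puncta(spec)
        assert len(pa) == 12 and len(pb) == 12
        d = np.linalg.norm(pa.centroids[:7] - pb.centroids[:7], axis=1)
        np.testing.assert_allclose(d, 30.0, atol=1e-9)

    def test_singles_respect_guard_distance(self):
        spec = PlantedPunctaSpec(n_pairs=3, pair_distance=40.0,
                                 n_singles_a=4, n_singles_b=4, seed=2)
        pa, pb, _ = plant_puncta(spec)
        from scipy.spatial.distance import cdist
        d = cdist(pa.centroids[3:], pb.centroids)
        assert d.min() >= 4 * spec.pair_distance - 1e-9

    def test_zero_pairs(self):
        from cytodyn.synapse import colocalize
        pa, pb, _ = plant_puncta(PlantedPunctaSpec(n_pairs=0, pair_distance=30,
                                                   n_singles_a=3, n_singles_b=3,
                                                   seed=3))
        assert colocalize(pa, pb).count == 0

    def test_determinism(self):
        spec = PlantedPunctaSpec(n_pairs=4, pair_distance=25.0, seed=9)
        a1, b1, i1 = plant_puncta(spec)
        a2, b2, i2 = plant_puncta(spec)
        np.testing.assert_array_equal(a1.centroids, a2.centroids)
        np.testing.assert_array_equal(i1, i2)

    def test_infeasible_packing_rejected(self):
        spec = PlantedPunctaSpec(n_pairs=500, pair_distance=2000.0,
                                 field_size=2.0, seed=0)
        with pytest.raises(ValueError, match="[Ii]nfeasible|field"):
            plant_puncta(spec)


class TestPlantEngulfment:
    @pytest.fixture
    def cell(self):
        m = np.zeros((120, 120), bool)
        m[30:90, 30:90] = True
        return m

    def test_planted_counts(self, cell):
        img, pset, labels = plant_engulfment(cell, 4, 2, 3, seed=1)
        assert list(labels).count("inside") == 4
        assert list(labels).count("partial") == 2
        assert list(labels).count("outside") == 3
        flat = cell.ravel()
        for fp, lab in zip(pset.footprints, labels):
            frac = flat[fp].mean()
            if lab == "inside":
                assert frac == 1.0
            elif lab == "outside":
                assert frac == 0.0
            else:
                assert 0.0 < frac < 1.0

    def test_zero_inside(self, cell):
        from cytodyn.synapse import engulfment
        _, pset, _ = plant_engulfment(cell, 0, 2, 2, seed=4)
        assert engulfment(pset, cell) == {1: 0}

    def test_empty_mask_rejected(self):
        with pytest.raises(ValueError):
            plant_engulfment(np.zeros((50, 50), bool), 1, 0, 0)
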