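"""Synthetic-stack generator: PSF, background, placement, metrics."""

import numpy as np
import pytest
from scipy.spatial.distance import cdist

from spotcount import (
    BackgroundParams,
    GroundTruth,
    ImageStack,
    SimulationConfig,
    generate_background,
    generate_psf,
    place_point_sources,
    signal_intensity_metric,
    simulate_stack,
    spot_density_metric,
    synthesize_stack,
)
from spotcount.simulate import DensityInfeasibleError
from spotcount.stacks import ValidationError


class TestPSF:
    def test_normalized_and_odd(self):
        k = generate_psf(1.0, 1.0, truncate_radius=3.0)
        assert abs(k.sum() - 1.0) < 1e-12
        assert all(s % 2 == 1 for s in k.shape)

    def test_center_maximal_and_symmetric(self):
        k = generate_psf(1.3, 2.0)
        center = tuple(s // 2 for s in k.shape)
        assert k[center] == k.max()
        for ax in range(3):
            assert np.allclose(k, np.flip(k, axis=ax))

    def test_matches_product_of_gaussians_formula(self):
        # Oracle: evaluate the separable Gaussian product directly, renormalize.
        sxy, sz = 1.3, 2.0
        k = generate_psf(sxy, sz)
        rz, rxy = k.shape[0] // 2, k.shape[1] // 2
        zz, yy, xx = np.meshgrid(
            np.arange(-rz, rz + 1),
            np.arange(-rxy, rxy + 1),
            np.arange(-rxy, rxy + 1),
            indexing="ij",
        )
        expected = np.exp(
            -(zz**2) / (2 * sz**2) - (yy**2 + xx**2) / (2 * sxy**2)
        )
        expected /= expected.sum()
        assert np.allclose(k, expected, atol=1e-14)

    @pytest.mark.parametrize("sxy,sz", [(0, 1), (1, -2)])
    def test_rejects_bad_sigma(self, sxy, sz):
        with pytest.raises(ValidationError):
            generate_psf(sxy, sz)


class TestBackground:
    def test_degenerate_is_constant(self):
        p = BackgroundParams(baseline=100, gradient_amplitude=0, n_blobs=0)
        bg = generate_background((4, 32, 32), p, seed=3)
        assert np.allclose(bg.voxels, 100.0)

    def test_deterministic(self):
        p = BackgroundParams()
        a = generate_background((4, 40, 40), p, seed=9)
        b = generate_background((4, 40, 40), p, seed=9)
        assert np.array_equal(a.voxels, b.voxels)

    def test_bounds_by_construction(self):
        p = BackgroundParams(
            baseline=100, gradient_amplitude=20, n_blobs=5, blob_amplitude=50
        )
        bg = generate_background((6, 48, 48), p, seed=1)
        assert bg.voxels.min() >= 100.0 - 1e-9
        assert bg.voxels.max() <= 100.0 + 5 * 50 + 20 + 1e-9


class TestPlacement:
    def test_zero_spots(self):
        cfg = SimulationConfig(shape=(5, 32, 32), n_spots=0)
        assert place_point_sources(cfg).sources == []

    def test_min_separation_enforced(self):
        cfg = SimulationConfig(
            shape=(20, 128, 128), n_spots=50, min_separation=5, seed=2
        )
        truth = place_point_sources(cfg)
        coords = truth.coordinates().astype(float)
        d = cdist(coords, coords)
        np.fill_diagonal(d, np.inf)
        assert d.min() >= 5.0

    def test_zero_cv_gives_constant_magnitude(self):
        cfg = SimulationConfig(
            shape=(5, 48, 48), n_spots=10, magnitude_cv=0.0, magnitude_mean=500
        )
        assert np.allclose(place_point_sources(cfg).magnitudes(), 500.0)

    def test_infeasible_density_raises(self):
        cfg = SimulationConfig(shape=(1, 32, 32), n_spots=200, min_separation=10)
        with pytest.raises(DensityInfeasibleError):
            place_point_sources(cfg)

    def test_deterministic(self):
        cfg = SimulationConfig(shape=(8, 64, 64), n_spots=20, seed=7)
        assert place_point_sources(cfg).sources == place_point_sources(cfg).sources


class TestSynthesize:
    def test_no_sources_no_noise_equals_blurred_background(self):
        from scipy.ndimage import gaussian_filter

        cfg = SimulationConfig(shape=(4, 32, 32), n_spots=0, noise_sd=0.0)
        bg = generate_background(cfg.shape, cfg.background_params, seed=1)
        out = synthesize_stack(GroundTruth([], "s"), bg, cfg)
        expected = gaussian_filter(bg.voxels, cfg.post_blur_sigma)
        assert np.allclose(out.voxels, expected)

    def test_intensity_conservation_for_interior_sources(self):
        # Normalized PSF and blur kernels conserve total added intensity.
        cfg = SimulationConfig(shape=(15, 64, 64), n_spots=0, noise_sd=0.0)
        bg = generate_background(
            cfg.shape, BackgroundParams(baseline=200, gradient_amplitude=0, n_blobs=0)
        )
        truth = GroundTruth([(7, 30, 30, 900.0), (7, 40, 22, 500.0)], "s")
        out = synthesize_stack(truth, bg, cfg)
        added = out.voxels.sum() - 200.0 * np.prod(cfg.shape)
        assert abs(added - 1400.0) / 1400.0 < 1e-6

    def test_shape_mismatch_rejected(self):
        cfg = SimulationConfig(shape=(4, 32, 32))
        bg = generate_background((4, 32, 32))
        bad = GroundTruth([(10, 5, 5, 10.0)], "s")
        with pytest.raises(ValidationError):
            synthesize_stack(bad, bg, cfg)

    def test_full_simulation_deterministic(self):
        cfg = SimulationConfig(shape=(6, 48, 48), n_spots=8, seed=11)
        s1, t1 = simulate_stack(cfg)
        s2, t2 = simulate_stack(cfg)
        assert np.array_equal(s1.voxels, s2.voxels)
        assert t1.sources == t2.sources


class TestSignalIntensityMetric:
    def test_source_at_image_mean_gives_zero(self):
        v = np.zeros((1, 32, 32))
        v[0, :, :16] = 10.0  # mean 5, sd 5
        stack = ImageStack(voxels=v, stack_id="s")
        truth = GroundTruth([(0, 0, 20, 1.0), (0, 0, 2, 1.0)], "s")
        # one source at 0, one at 10: mean at sources == image mean
        assert abs(signal_intensity_metric(stack, truth)) < 1e-12

    def test_constant_image_is_degenerate(self, flat_stack):
        with pytest.raises(ValidationError):
            signal_intensity_metric(flat_stack, GroundTruth([(0, 1, 1, 1.0)], "flat"))

    def test_empty_truth_is_error(self, flat_stack):
        with pytest.raises(ValidationError):
            signal_intensity_metric(flat_stack, GroundTruth([], "flat"))

    def test_hand_computed_zscore(self):
        rng = np.random.default_rng(5)
        v = rng.uniform(10, 20, size=(2, 32, 32))
        stack = ImageStack(voxels=v, stack_id="s")
        truth = GroundTruth([(1, 10, 12, 1.0), (0, 3, 30, 1.0)], "s")
        got = signal_intensity_metric(stack, truth)
        expected = (np.mean([v[1, 10, 12], v[0, 3, 30]]) - v.mean()) / v.std()
        assert abs(got - expected) < 1e-12

    def test_monotone_in_magnitude(self):
        vals = []
        for mag in (2000.0, 6000.0, 12000.0):
            cfg = SimulationConfig(
                shape=(8, 64, 64), n_spots=10, magnitude_mean=mag, seed=3
            )
            stack, truth = simulate_stack(cfg)
            vals.append(signal_intensity_metric(stack, truth))
        assert vals[0] < vals[1] < vals[2]


class TestSpotDensityMetric:
    def test_source_everywhere_gives_zero(self):
        v = np.ones((1, 32, 32))
        stack = ImageStack(voxels=v, stack_id="s")
        sources = [(0, y, x, 1.0) for y in range(32) for x in range(32)]
        assert spot_density_metric(stack, GroundTruth(sources, "s")) == 0.0

    def test_matches_brute_force(self):
        rng = np.random.default_rng(8)
        stack = ImageStack(voxels=rng.uniform(0, 1, (4, 32, 32)), stack_id="s")
        coords = [(int(z), int(y), int(x)) for z, y, x in
                  zip(rng.integers(0, 4, 5), rng.integers(0, 32, 5), rng.integers(0, 32, 5))]
        coords = list(dict.fromkeys(coords))
        truth = GroundTruth([(z, y, x, 1.0) for z, y, x in coords], "s")
        got = spot_density_metric(stack, truth)
        # Brute force: all-voxel x all-source minimum distance.
        zz, yy, xx = np.meshgrid(
            np.arange(4), np.arange(32), np.arange(32), indexing="ij"
        )
        vox = np.column_stack([zz.ravel(), yy.ravel(), xx.ravel()]).astype(float)
        d = cdist(vox, np.array(coords, dtype=float)).min(axis=1)
        assert abs(got - d.mean()) < 1e-9

    def test_empty_truth_is_error(self, flat_stack):
        with pytest.raises(ValidationError):
            spot_density_metric(flat_stack, GroundTruth([], "flat"))
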