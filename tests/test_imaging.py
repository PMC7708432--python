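"""Image formation: emitters, PSF, rendering, SBR, noise, deconvolution."""

import numpy as np
import pytest

from biofilm3d.arrangement import CellArrangement, GridSpec, rasterize_instances
from biofilm3d.geometry import Spherocylinder
from biofilm3d.imaging import (
    ImageVolume,
    NoiseModel,
    PSFModel,
    add_noise,
    calibrate_sbr,
    place_fluorophores,
    render_noiseless,
    richardson_lucy,
    sbr_masks,
    subtract_background,
    surrogate_confidence,
    synthesize_psf,
)
from biofilm3d.evaluate import estimate_sbr


def _delta_psf(voxel_size=(0.1, 0.1, 0.1)) -> PSFModel:
    k = np.zeros((3, 3, 3))
    k[1, 1, 1] = 1.0
    return PSFModel(kernel=k, voxel_size=voxel_size)


class TestEmitters:
    def test_counts_within_range(self, colony_sparse):
        arr, _, _ = colony_sparse
        em = place_fluorophores(arr, "interior", (500, 1000), seed=1)
        counts = np.bincount(em.cell_ids)[1:]
        counts = counts[counts > 0]
        assert counts.min() >= 500 and counts.max() <= 1000
        assert len(counts) == len(arr)

    def test_interior_emitters_inside_cells(self, colony_sparse):
        arr, _, _ = colony_sparse
        em = place_fluorophores(arr, "interior", (100, 200), seed=2)
        by_id = {c.cell_id: c for c in arr.cells}
        for cid in np.unique(em.cell_ids):
            pts = em.positions[em.cell_ids == cid]
            assert by_id[int(cid)].contains(pts).all()

    def test_membrane_emitters_on_surface(self, colony_sparse):
        arr, _, _ = colony_sparse
        em = place_fluorophores(arr, "membrane", (100, 200), seed=3)
        by_id = {c.cell_id: c for c in arr.cells}
        worst = 0.0
        for cid in np.unique(em.cell_ids):
            pts = em.positions[em.cell_ids == cid]
            worst = max(worst, np.abs(by_id[int(cid)].surface_distance(pts)).max())
        assert worst < 1e-6

    def test_both_mode_places_interior_and_membrane(self):
        cell = Spherocylinder(1, (2.0, 2.0, 2.0), (0, 0, 1), 2.0, 1.0)
        arr = CellArrangement([cell])
        em = place_fluorophores(arr, "both", (100, 100), seed=4)
        dist = np.abs(cell.surface_distance(em.positions))
        assert (dist < 1e-6).sum() >= 100  # the membrane half
        assert (dist > 0.05).sum() > 50  # a deep-interior population


class TestPSF:
    def test_normalization_and_odd_extent(self):
        psf = synthesize_psf()
        assert psf.kernel.sum() == pytest.approx(1.0, abs=1e-6)
        assert all(s % 2 == 1 for s in psf.kernel.shape)

    def test_fwhm_matches_request(self):
        psf = synthesize_psf(0.23, 0.57, (0.1, 0.1, 0.1))
        k = psf.kernel

        def fwhm(profile, step):
            profile = profile / profile.max()
            above = np.flatnonzero(profile >= 0.5)
            # linear interpolation at the half-maximum crossings
            lo, hi = above[0], above[-1]
            f = lambda i, j: i + (0.5 - profile[i]) / (profile[j] - profile[i]) * (j - i)
            left = f(lo - 1, lo) if lo > 0 else lo
            right = f(hi, hi + 1) if hi < len(profile) - 1 else hi
            return (right - left) * step

        c = tuple(s // 2 for s in k.shape)
        assert fwhm(k[:, c[1], c[2]], 0.1) == pytest.approx(0.57, abs=0.05)
        assert fwhm(k[c[0], c[1], :], 0.1) == pytest.approx(0.23, abs=0.05)

    def test_negative_fwhm_rejected(self):
        with pytest.raises(ValueError):
            synthesize_psf(-0.1, 0.5)

    def test_psf_model_validation(self):
        with pytest.raises(ValueError, match="odd"):
            PSFModel(kernel=np.ones((2, 3, 3)), voxel_size=(0.1, 0.1, 0.1))
        with pytest.raises(ValueError):
            PSFModel(kernel=np.zeros((3, 3, 3)), voxel_size=(0.1, 0.1, 0.1))


class TestRender:
    def test_zero_emitters_gives_zero_volume(self):
        from biofilm3d.imaging import EmitterSet

        grid = GridSpec((8, 8, 8))
        em = EmitterSet(np.zeros((0, 3)), np.zeros(0, dtype=np.int32))
        img = render_noiseless(em, _delta_psf(), grid)
        assert img.voxels.sum() == 0

    def test_single_emitter_delta_psf(self):
        from biofilm3d.imaging import EmitterSet

        grid = GridSpec((8, 8, 8))
        em = EmitterSet(np.array([[0.35, 0.35, 0.35]]), np.array([1], dtype=np.int32))
        img = render_noiseless(em, _delta_psf(), grid, photons_per_emitter=7.0)
        assert img.voxels[3, 3, 3] == pytest.approx(7.0)
        assert img.voxels.sum() == pytest.approx(7.0)

    def test_flux_conservation_interior_emitters(self):
        from biofilm3d.imaging import EmitterSet

        rng = np.random.default_rng(5)
        grid = GridSpec((64, 64, 64))
        pts = rng.uniform(2.2, 4.2, (1000, 3))  # deep interior
        em = EmitterSet(pts, np.ones(1000, dtype=np.int32))
        psf = synthesize_psf(voxel_size=grid.voxel_size)
        img = render_noiseless(em, psf, grid, photons_per_emitter=3.0)
        assert img.voxels.sum() == pytest.approx(3000.0, rel=1e-3)

    def test_flux_linearity_exact(self):
        from biofilm3d.imaging import EmitterSet

        rng = np.random.default_rng(6)
        grid = GridSpec((32, 32, 32))
        em = EmitterSet(rng.uniform(1, 2, (100, 3)), np.ones(100, dtype=np.int32))
        psf = synthesize_psf(voxel_size=grid.voxel_size)
        one = render_noiseless(em, psf, grid, photons_per_emitter=1.0)
        three = render_noiseless(em, psf, grid, photons_per_emitter=3.0)
        np.testing.assert_allclose(
            three.voxels, 3.0 * one.voxels, rtol=1e-9, atol=1e-9
        )

    def test_mismatched_psf_voxel_size_rejected(self):
        from biofilm3d.imaging import EmitterSet

        grid = GridSpec((8, 8, 8), (0.1, 0.1, 0.1))
        em = EmitterSet(np.zeros((0, 3)), np.zeros(0, dtype=np.int32))
        with pytest.raises(ValueError, match="voxel size"):
            render_noiseless(em, _delta_psf(voxel_size=(0.2, 0.2, 0.2)), grid)


@pytest.fixture(scope="module")
def rendered_scene(colony_sparse):
    arr, grid, inst = colony_sparse
    em = place_fluorophores(arr, "interior", (500, 1000), seed=21)
    psf = synthesize_psf(voxel_size=grid.voxel_size)
    noiseless = render_noiseless(em, psf, grid)
    return arr, grid, inst, noiseless, psf


class TestSBR:
    def test_calibration_round_trip(self, rendered_scene):
        _, grid, inst, noiseless, _ = rendered_scene
        noise = NoiseModel(background=200.0, read_noise_sd=3.04, seed=8)
        scale = calibrate_sbr(noiseless, inst, noise, target_sbr=1.34)
        noisy = add_noise(ImageVolume(noiseless.voxels * scale, grid), noise)
        sig, bg = sbr_masks(noiseless, inst)
        assert estimate_sbr(noisy, sig, bg) == pytest.approx(1.34, abs=0.05)

    def test_vanishing_signal_gives_unit_sbr(self, rendered_scene):
        _, grid, inst, noiseless, _ = rendered_scene
        noise = NoiseModel(background=200.0, read_noise_sd=3.04, seed=9)
        noisy = add_noise(ImageVolume(noiseless.voxels * 0.0, grid), noise)
        sig, bg = sbr_masks(noiseless, inst)
        assert estimate_sbr(noisy, sig, bg) == pytest.approx(1.0, abs=0.02)

    def test_doubling_background_halves_excess(self, rendered_scene):
        """(SBR − 1) ∝ 1/background at fixed signal scale."""
        _, grid, inst, noiseless, _ = rendered_scene
        sig, bg_mask = sbr_masks(noiseless, inst)
        scaled = ImageVolume(noiseless.voxels * 300.0, grid)
        excess = []
        for bg_level, seed in [(100.0, 10), (200.0, 11)]:
            noisy = add_noise(scaled, NoiseModel(bg_level, 0.0, seed))
            excess.append(estimate_sbr(noisy, sig, bg_mask) - 1.0)
        assert excess[0] / excess[1] == pytest.approx(2.0, rel=0.05)

    def test_target_at_most_one_rejected(self, rendered_scene):
        _, _, inst, noiseless, _ = rendered_scene
        with pytest.raises(ValueError):
            calibrate_sbr(noiseless, inst, NoiseModel(), target_sbr=1.0)


class TestNoise:
    def test_fixed_seed_reproducible(self):
        img = ImageVolume(np.full((20, 20, 20), 50.0), GridSpec((20, 20, 20)))
        noise = NoiseModel(background=100.0, read_noise_sd=3.0, seed=12)
        np.testing.assert_array_equal(
            add_noise(img, noise).voxels, add_noise(img, noise).voxels
        )

    def test_read_noise_sd_recovered(self):
        """Dark-frame calibration: SD over 10⁶ voxels ≈ 3.04 within 2%."""
        img = ImageVolume(np.zeros((100, 100, 100)), GridSpec((100, 100, 100)))
        out = add_noise(img, NoiseModel(0.0, 3.04, seed=13), clip=False)
        assert out.voxels.std() == pytest.approx(3.04, rel=0.02)

    def test_poisson_variance_equals_mean(self):
        """Var = µ + background for Poisson-dominated pixels, no read noise."""
        img = ImageVolume(np.full((60, 60, 60), 70.0), GridSpec((60, 60, 60)))
        out = add_noise(img, NoiseModel(background=30.0, read_noise_sd=0.0, seed=14))
        assert out.voxels.mean() == pytest.approx(100.0, rel=0.01)
        assert out.voxels.var() == pytest.approx(100.0, rel=0.03)

    def test_total_variance_includes_read_noise(self):
        img = ImageVolume(np.full((60, 60, 60), 50.0), GridSpec((60, 60, 60)))
        out = add_noise(img, NoiseModel(background=50.0, read_noise_sd=5.0, seed=15))
        assert out.voxels.var() == pytest.approx(100.0 + 25.0, rel=0.05)


class TestRichardsonLucy:
    def test_delta_kernel_identity(self):
        rng = np.random.default_rng(16)
        img = ImageVolume(rng.uniform(1, 10, (16, 16, 16)), GridSpec((16, 16, 16)))
        out = richardson_lucy(img, _delta_psf(), iterations=5)
        np.testing.assert_allclose(out.voxels, img.voxels, rtol=1e-9)

    def test_flux_conserved_within_one_percent(self):
        rng = np.random.default_rng(17)
        grid = GridSpec((48, 48, 48))
        img = np.zeros(grid.shape)
        img[16:32, 16:32, 16:32] = rng.uniform(50, 150, (16, 16, 16))
        psf = synthesize_psf(voxel_size=grid.voxel_size)
        from scipy.signal import fftconvolve

        blurred = ImageVolume(np.clip(fftconvolve(img, psf.kernel, "same"), 0, None), grid)
        out = richardson_lucy(blurred, psf, iterations=10)
        assert out.voxels.sum() == pytest.approx(blurred.voxels.sum(), rel=0.01)
        assert out.voxels.min() >= 0

    def test_two_point_contrast_increases_monotonically(self):
        grid = GridSpec((32, 32, 64))
        img = np.zeros(grid.shape)
        img[16, 16, 28] = 1000.0
        img[16, 16, 36] = 1000.0
        psf = synthesize_psf(0.4, 0.6, grid.voxel_size)
        from scipy.signal import fftconvolve

        blurred = ImageVolume(np.clip(fftconvolve(img, psf.kernel, "same"), 0, None), grid)
        contrasts = []
        for it in range(1, 11):
            out = richardson_lucy(blurred, psf, iterations=it)
            peak = max(out.voxels[16, 16, 28], out.voxels[16, 16, 36])
            valley = out.voxels[16, 16, 32]
            contrasts.append((peak - valley) / (peak + valley))
        assert all(b > a for a, b in zip(contrasts, contrasts[1:]))

    def test_invalid_iterations(self):
        img = ImageVolume(np.ones((8, 8, 8)), GridSpec((8, 8, 8)))
        with pytest.raises(ValueError):
            richardson_lucy(img, _delta_psf(), iterations=0)


class TestBackgroundSubtraction:
    def test_uniform_image_with_itself_dark_goes_to_zero(self):
        img = ImageVolume(np.full((10, 10, 10), 37.0), GridSpec((10, 10, 10)))
        out = subtract_background(img, dark_mask=np.ones((10, 10, 10), bool))
        assert np.all(out.voxels == 0)

    def test_recovers_constant_background(self):
        rng = np.random.default_rng(18)
        grid = GridSpec((40, 40, 40))
        signal = np.zeros(grid.shape)
        signal[10:30, 10:30, 10:30] = 500.0
        noisy = rng.poisson(signal + 200.0).astype(float)
        dark = signal == 0
        out = subtract_background(ImageVolume(noisy, grid), dark_mask=dark)
        se = np.sqrt(200.0 / dark.sum())
        assert out.meta["background_estimate"] == pytest.approx(200.0, abs=5 * se)
        assert out.voxels.min() >= 0

    def test_percentile_rule(self):
        grid = GridSpec((20, 20, 20))
        img = np.full(grid.shape, 100.0)
        img[10:, :, :] = 300.0
        out = subtract_background(ImageVolume(img, grid), percentile=40)
        assert out.voxels.min() == 0


class TestSurrogateConfidence:
    def test_degenerate_parameters_reproduce_one_hot(self, colony_sparse):
        _, _, inst = colony_sparse
        conf = surrogate_confidence(inst, blur_sd=0.0, flip_noise=0.0)
        from biofilm3d.arrangement import instances_to_classmap

        cm = instances_to_classmap(inst)
        assert np.all(conf.interior(1)[cm.classes == 1] == 1.0)
        assert np.all(conf.values[0][cm.classes == 0] == 1.0)

    def test_class_sums_equal_one(self, colony_sparse):
        _, _, inst = colony_sparse
        conf = surrogate_confidence(inst, blur_sd=1.5, flip_noise=0.05, seed=3)
        sums = conf.values.sum(axis=0)
        assert np.abs(sums - 1.0).max() < 1e-3

    def test_thresholding_recovers_true_cell_count(self, colony_sparse):
        from biofilm3d.postprocess import threshold_and_label

        _, _, inst = colony_sparse
        conf = surrogate_confidence(inst, blur_sd=1.0, flip_noise=0.0, seed=1)
        labeled = threshold_and_label(conf, tau=0.94)
        assert labeled.n_objects == inst.n_objects
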