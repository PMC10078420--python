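"""Reconstruction chain: windowing, zero-fill, averaging, segmentation, fits."""

import numpy as np
import pytest
from scipy.ndimage import binary_erosion
from skimage.transform import resize

import lltherm as L
from lltherm.recon import fit_recovery_curve


class TestHamming:
    def test_zero_input(self):
        assert np.all(L.hamming_apodize(np.zeros((8, 8), complex)) == 0)

    def test_symmetry_and_energy(self, rng):
        k = rng.standard_normal((16, 12)) + 1j * rng.standard_normal((16, 12))
        out = L.hamming_apodize(k)
        w = out / np.where(k == 0, 1, k)
        np.testing.assert_allclose(w.real, w.real[::-1, :][:, ::-1], atol=1e-12)
        assert np.sum(np.abs(out) ** 2) <= np.sum(np.abs(k) ** 2)
        assert np.abs(w).max() == pytest.approx(1.0, abs=1e-12)


class TestZeroFill:
    def test_output_dims(self, rng):
        k = rng.standard_normal((64, 35)) + 0j
        assert L.zero_fill(k, (128, 69)).shape == (128, 69)

    def test_identity_and_shrink(self, rng):
        k = rng.standard_normal((8, 6)) + 0j
        np.testing.assert_array_equal(L.zero_fill(k, (8, 6)), k)
        with pytest.raises(ValueError):
            L.zero_fill(k, (4, 6))

    def test_point_source_location_scales(self):
        img = np.zeros((64, 35))
        img[20, 10] = 1.0
        ks = np.fft.fftshift(np.fft.fft2(img))
        big = np.abs(np.fft.ifft2(np.fft.ifftshift(L.zero_fill(ks, (128, 69)))))
        px, py = np.unravel_index(np.argmax(big), big.shape)
        assert abs(px - 20 * 128 / 64) <= 1 and abs(py - 10 * 69 / 35) <= 1


class TestReconstructSeries:
    def test_constant_schedule_is_plain_mean(self, five_vial_phantom, b1_map, seq_1slice):
        ks = L.simulate_acquisition(
            five_vial_phantom, b1_map, L.constant_schedule(5, 4), seq_1slice,
            noise_sd=1.0, seed=3,
        )
        series = L.reconstruct_series(ks)
        mags = np.abs(np.fft.ifft2(np.fft.ifftshift(ks.data[0], axes=(-2, -1)), axes=(-2, -1)))
        np.testing.assert_allclose(series.images, mags.mean(axis=1), rtol=1e-12)

    def test_na_normalization_exact_when_noise_free(
        self, five_vial_phantom, b1_map, seq_1slice, variable_schedule
    ):
        ks_var = L.simulate_acquisition(
            five_vial_phantom, b1_map, variable_schedule, seq_1slice)
        ks_one = L.simulate_acquisition(
            five_vial_phantom, b1_map, L.constant_schedule(79, 1), seq_1slice)
        np.testing.assert_allclose(
            L.reconstruct_series(ks_var).images,
            L.reconstruct_series(ks_one).images,
            rtol=1e-9, atol=1e-12,
        )

    def test_three_slices_79_points_gives_237_images(self, five_vial_phantom, b1_map, seq):
        ks = L.simulate_acquisition(
            five_vial_phantom, b1_map, L.constant_schedule(79, 1), seq)
        series = L.reconstruct_series(ks)
        assert series.images.shape[0] * series.images.shape[1] == 237


class TestBackgroundSubtract:
    def test_constant_offset_removed(self, rng):
        images = np.abs(rng.standard_normal((1, 4, 16, 16))) + 5.0
        series = L.ImageSeries(images=images, times=np.arange(1, 5.0), na=np.ones(4))
        roi = np.zeros((16, 16), bool)
        roi[:4, :4] = True
        out = L.background_subtract(series, roi, clip_negative=False)
        np.testing.assert_allclose(out.images[..., roi].mean(axis=-1), 0.0, atol=1e-12)

    def test_rician_background_centered_after_subtraction(self, seq_1slice, b1_map):
        ph = L.make_vial_phantom([100.0], geometry=L.default_geometry(1))
        ks = L.simulate_acquisition(
            ph, b1_map, L.constant_schedule(20, 3), seq_1slice, noise_sd=2.0, seed=11)
        roi = ph.label_grid == 0
        series = L.reconstruct_series(ks)
        out = L.background_subtract(series, roi, clip_negative=False)
        resid = out.images[..., roi]
        sigma_img = 2.0 / np.sqrt(64 * 35)
        se = sigma_img / np.sqrt(resid.size)
        assert abs(resid.mean()) < 3 * se

    def test_empty_roi_rejected(self):
        series = L.ImageSeries(
            images=np.ones((1, 3, 8, 8)), times=np.arange(1, 4.0), na=np.ones(3))
        with pytest.raises(ValueError):
            L.background_subtract(series, np.zeros((8, 8), bool))


class TestSegmentVials:
    def test_recovers_discs(self, five_vial_phantom):
        truth = five_vial_phantom.label_grid
        img = five_vial_phantom.m0_grid() + 0.05 * (truth >= 2)
        seeds = []
        for lab in five_vial_phantom.vial_labels():
            xs, ys = np.nonzero(truth == lab)
            seeds.append((int(xs.mean()), int(ys.mean())))
        labels = L.segment_vials(img, seeds, tolerance=0.02)
        from scipy.ndimage import binary_dilation

        for i, lab in enumerate(five_vial_phantom.vial_labels(), start=1):
            got = labels == i
            want = truth == lab
            band = binary_dilation(want, iterations=1) & ~binary_erosion(want, iterations=1)
            assert not np.any((got ^ want) & ~band)

    def test_tiny_tolerance_keeps_seed_only(self, rng):
        img = rng.uniform(1.0, 2.0, (16, 16))
        labels = L.segment_vials(img, [(8, 8)], tolerance=1e-9, background_threshold=0.0)
        assert labels.sum() == 1 and labels[8, 8] == 1

    def test_two_seeds_one_region_merge(self):
        img = np.zeros((16, 16))
        img[4:12, 4:12] = 1.0
        labels = L.segment_vials(img, [(5, 5), (10, 10)], tolerance=0.5)
        assert set(np.unique(labels)) == {0, 1}
        with pytest.raises(ValueError):
            L.segment_vials(img, [(5, 5), (10, 10)], tolerance=0.5, merge_overlaps=False)

    def test_background_seed_rejected(self):
        img = np.zeros((16, 16))
        img[4:12, 4:12] = 1.0
        with pytest.raises(ValueError, match="background"):
            L.segment_vials(img, [(0, 0)], tolerance=0.5)


class TestFitT1Star:
    def _series(self, ts, amp, shape=(4, 4), n_t=40, noise=None, rng=None):
        t = L.sample_times(n_t, 25.0)
        clean = amp * (1 - np.exp(-t / ts))
        images = np.tile(clean[None, :, None, None], (1, 1) + shape)
        if noise:
            images = np.abs(
                images + noise * (rng.standard_normal(images.shape)
                                  + 1j * rng.standard_normal(images.shape))
            )
        return L.ImageSeries(images=images, times=t, na=np.ones(n_t))

    def test_noise_free_exact(self, seq):
        series = self._series(120.0, 1.0)
        out = L.fit_t1star(series, seq)
        assert np.all(out.valid)
        np.testing.assert_allclose(out.t1star[out.valid], 120.0, rtol=1e-6)
        np.testing.assert_allclose(out.amplitude[out.valid], 1.0, rtol=1e-6)

    def test_flat_signal_pins_at_bound(self, seq):
        n_t = 20
        images = np.ones((1, n_t, 2, 2))
        series = L.ImageSeries(
            images=images, times=L.sample_times(n_t, 25.0), na=np.ones(n_t))
        out = L.fit_t1star(series, seq)
        assert not np.any(out.valid)

    def test_all_zero_pixel_invalid_not_error(self, seq):
        series = self._series(120.0, 1.0)
        series.images[..., 0, 0] = 0.0
        out = L.fit_t1star(series, seq)
        assert not out.valid[0, 0, 0]

    def test_rician_noise_median_within_5pct(self, seq):
        rng = np.random.default_rng(2024)
        series = self._series(200.0, 1.0, shape=(32, 32), n_t=79, noise=0.05, rng=rng)
        out = L.fit_t1star(series, seq)
        med = np.median(out.t1star[out.valid])
        assert med == pytest.approx(200.0, rel=0.05)

    def test_confidence_intervals_cover_noise_free(self, seq):
        series = self._series(150.0, 2.0)
        out = L.fit_t1star(series, seq, compute_ci=True)
        assert np.all(out.t1star_ci95[out.valid] < 1.0)  # essentially exact fit


class TestFitRecoveryCurve:
    def test_matches_map_fit(self, seq):
        t = L.sample_times(79, 25.0)
        y = 0.8 * (1 - np.exp(-t / 300.0))
        amp, ts = fit_recovery_curve(t, y, alpha=5.0, TR_alpha=25.0)
        assert ts == pytest.approx(300.0, rel=1e-6)
        assert amp == pytest.approx(0.8, rel=1e-6)


class TestT1Map:
    def test_uniform_alpha_equals_scalar_conversion(self, seq):
        ts = np.full((1, 8, 8), 120.0)
        tsmap = L.T1StarMap(
            t1star=ts, amplitude=np.ones_like(ts), valid=np.ones_like(ts, bool),
            residual_norm=np.zeros_like(ts), at_bound=np.zeros_like(ts, bool))
        b1 = L.FlipAngleMap(angles=np.full((8, 8), 5.0))
        out = L.t1_map(tsmap, b1, 25.0)
        np.testing.assert_allclose(out.t1[out.valid], L.true_t1(120.0, 5.0, 25.0))

    def test_seven_pct_angle_error_below_one_pct(self):
        assert L.flip_angle_error_bound(relative_error=0.07) < 1.0

    def test_pole_pixels_flagged(self, seq):
        bound = L.t1star_max(5.0, 25.0)
        ts = np.array([[[bound * 1.01, 100.0]]])
        tsmap = L.T1StarMap(
            t1star=ts, amplitude=np.ones_like(ts), valid=np.ones_like(ts, bool),
            residual_norm=np.zeros_like(ts), at_bound=np.zeros_like(ts, bool))
        b1 = L.FlipAngleMap(angles=np.full((1, 2), 5.0))
        out = L.t1_map(tsmap, b1, 25.0)
        assert not out.valid[0, 0, 0] and out.valid[0, 0, 1]


class TestEndToEnd:
    def test_noise_free_full_sampling_within_1pct(
        self, five_vial_phantom, b1_map, seq_1slice, variable_schedule
    ):
        ph = five_vial_phantom
        ks = L.simulate_acquisition(ph, b1_map, variable_schedule, seq_1slice)
        series = L.reconstruct_series(ks)
        tsmap = L.fit_t1star(series, seq_1slice, mask=ph.label_grid >= 2)
        tmap = L.t1_map(tsmap, b1_map, seq_1slice.TR_alpha)
        for lab in ph.vial_labels():
            sel = binary_erosion(ph.label_grid == lab, iterations=1)[None] & tmap.valid
            est = tmap.t1[sel].mean()
            assert est == pytest.approx(ph.vial_params[lab].T1, rel=0.01)

    def test_noise_free_undersampled_hamming_within_2pct(
        self, five_vial_phantom, b1_map, seq_1slice, variable_schedule
    ):
        ph = five_vial_phantom
        mask = L.gaussian_line_mask(35, 24, seed=7)
        ks = L.simulate_acquisition(ph, b1_map, variable_schedule, seq_1slice, mask=mask)
        series = L.reconstruct_series(ks, out_shape=(128, 69), apodize=True)
        tsmap = L.fit_t1star(series, seq_1slice)
        b1_zf = L.FlipAngleMap(angles=resize(b1_map.angles, (128, 69), order=1, mode="edge"))
        tmap = L.t1_map(tsmap, b1_zf, seq_1slice.TR_alpha)
        labels_zf = resize(
            ph.label_grid.astype(float), (128, 69), order=0, preserve_range=True
        ).astype(int)
        for lab in ph.vial_labels():
            sel = binary_erosion(labels_zf == lab, iterations=4)[None] & tmap.valid
            est = tmap.t1[sel].mean()
            assert est == pytest.approx(ph.vial_params[lab].T1, rel=0.02)
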