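"""Preprocessing chain: skull stripping, noise/PSNR, denoisers, cropping.

Phantom ground-truth masks act as the oracle for the morphological steps.
"""

import numpy as np
import pytest

import ncctscreen as ncs
from ncctscreen.ctio import GraySlice
from ncctscreen.preprocess import (BBox, EmptyImageError, NoiseSpec, SkullStripParams,
                                   add_gaussian_noise, crop_brain, denoise, psnr,
                                   strip_skull)


class TestStripSkull:
    def test_removes_skull_and_keeps_brain(self, phantom_slice):
        _, hu, truth = phantom_slice
        g = ncs.apply_window(hu)
        stripped, skull_mask, brain_mask = strip_skull(g)
        skull_removed = (stripped.pixels[truth.skull_mask] == 0).mean()
        brain_kept = (
            stripped.pixels[truth.brain_mask] == g.pixels[truth.brain_mask]
        ).mean()
        assert skull_removed >= 0.99
        assert brain_kept >= 0.95
        assert stripped.stage == "skull_stripped"

    def test_falx_calcification_removed(self):
        spec = ncs.PhantomSpec(image_size=256, skull_outer_radius=110.0,
                               skull_thickness=8.0, falx_calcification=True, seed=21)
        hu, truth = ncs.generate_phantom(spec)
        g = ncs.apply_window(hu)
        stripped, _, _ = strip_skull(g)
        falx = truth.skull_mask & (np.hypot(*np.mgrid[:256, :256] - 128.0) < 102)
        assert falx.any()
        assert np.all(stripped.pixels[falx] == 0)

    def test_never_increases_pixels(self, phantom_slice):
        _, hu, _ = phantom_slice
        g = ncs.apply_window(hu)
        stripped, _, _ = strip_skull(g)
        assert np.all(stripped.pixels <= g.pixels)

    def test_empty_image_rejected(self):
        sl = GraySlice(np.zeros((512, 512), dtype=np.uint8))
        with pytest.raises(EmptyImageError):
            strip_skull(sl)

    def test_no_skull_degrades_to_foreground_mask(self):
        img = np.zeros((64, 64), dtype=np.uint8)
        img[20:40, 20:40] = 100  # nothing reaches the bone threshold
        sl = GraySlice(img)
        stripped, skull_mask, brain_mask = strip_skull(sl)
        assert not skull_mask.any()
        assert np.array_equal(brain_mask, img > 0)
        assert np.array_equal(stripped.pixels, img)

    def test_invalid_params_rejected(self):
        with pytest.raises(ValueError):
            SkullStripParams(skull_threshold=300)
        with pytest.raises(ValueError):
            SkullStripParams(erosion_radius=0)


class TestGaussianNoise:
    def _flat(self, value=128, n=512):
        return GraySlice(np.full((n, n), value, dtype=np.uint8), stage="skull_stripped")

    def test_zero_variance_is_identity(self):
        sl = self._flat()
        out = add_gaussian_noise(sl, NoiseSpec(variance=0.0))
        assert np.array_equal(out.pixels, sl.pixels)
        assert out.stage == "noisy"

    def test_sample_variance_matches_spec(self):
        sl = self._flat()
        out = add_gaussian_noise(sl, NoiseSpec(variance=0.001, seed=5))
        diff = (out.pixels.astype(float) - sl.pixels.astype(float)) / 255.0
        assert diff.var() == pytest.approx(0.001, rel=0.10)

    def test_seed_determinism(self):
        sl = self._flat()
        a = add_gaussian_noise(sl, NoiseSpec(variance=0.001, seed=9))
        b = add_gaussian_noise(sl, NoiseSpec(variance=0.001, seed=9))
        assert np.array_equal(a.pixels, b.pixels)

    def test_negative_variance_rejected(self):
        with pytest.raises(ValueError):
            NoiseSpec(variance=-0.1)


class TestPSNR:
    def test_identical_images_flagged(self):
        a = np.full((8, 8), 7, dtype=np.uint8)
        rep = psnr(a, a.copy())
        assert rep.identical and rep.psnr_db == np.inf

    def test_unit_mse_closed_form(self):
        a = np.zeros((16, 16), dtype=np.uint8)
        rep = psnr(a, a + 1)
        assert rep.mse == 1.0
        assert rep.psnr_db == pytest.approx(48.13, abs=0.01)

    def test_full_scale_difference_is_zero_db(self):
        a = np.zeros((8, 8), dtype=np.uint8)
        b = np.full((8, 8), 255, dtype=np.uint8)
        assert psnr(a, b).psnr_db == pytest.approx(0.0, abs=1e-12)

    def test_symmetry(self):
        rng = np.random.default_rng(2)
        a = rng.integers(0, 256, (32, 32)).astype(np.uint8)
        b = rng.integers(0, 256, (32, 32)).astype(np.uint8)
        assert psnr(a, b).psnr_db == pytest.approx(psnr(b, a).psnr_db)

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError, match="shape"):
            psnr(np.zeros((4, 4)), np.zeros((5, 5)))


class TestDenoisers:
    def test_median_removes_salt_noise_from_constant(self):
        img = np.full((64, 64), 100, dtype=np.uint8)
        img[10, 10] = img[30, 40] = 255
        sl = GraySlice(img, stage="noisy")
        out = denoise(sl, "median")
        assert np.all(out.pixels == 100)
        assert out.stage == "denoised"

    def test_unknown_method_rejected(self):
        sl = GraySlice(np.zeros((8, 8), dtype=np.uint8), stage="noisy")
        with pytest.raises(ValueError, match="unknown denoise method"):
            denoise(sl, "wiener")

    def test_untrained_dncnn_rejected(self):
        sl = GraySlice(np.zeros((8, 8), dtype=np.uint8), stage="noisy")
        with pytest.raises(ValueError, match="untrained"):
            denoise(sl, "dncnn")

    def test_every_method_improves_psnr_on_phantoms(self, stripped_phantoms, trained_dncnn):
        """Each denoiser strictly increases PSNR vs the noisy input, per slice."""
        for i, (clean, _) in enumerate(stripped_phantoms[8:]):
            noisy = add_gaussian_noise(clean, NoiseSpec(variance=0.001, seed=500 + i))
            base = psnr(clean, noisy).psnr_db
            for method in ("median", "gaussian", "bilateral", "dncnn"):
                restored = denoise(noisy, method, dncnn=trained_dncnn)
                assert psnr(clean, restored).psnr_db > base, (method, i)

    def test_trained_dncnn_beats_median_on_average(self, stripped_phantoms, trained_dncnn):
        """On ≥20 held-out slices the learned denoiser outperforms the median filter."""
        dncnn_db, median_db = [], []
        held_out = stripped_phantoms[8:]
        assert len(held_out) >= 20
        for i, (clean, _) in enumerate(held_out):
            noisy = add_gaussian_noise(clean, NoiseSpec(variance=0.001, seed=500 + i))
            dncnn_db.append(psnr(clean, denoise(noisy, "dncnn", dncnn=trained_dncnn)).psnr_db)
            median_db.append(psnr(clean, denoise(noisy, "median")).psnr_db)
        assert np.mean(dncnn_db) >= np.mean(median_db)


class TestCropBrain:
    def test_single_pixel_box(self):
        img = np.zeros((512, 512), dtype=np.uint8)
        img[100, 200] = 50
        out, box = crop_brain(GraySlice(img, stage="skull_stripped"))
        assert box == BBox(100, 100, 200, 200)
        assert out.pixels.shape == (1, 1)

    def test_block_dimensions_inclusive(self):
        img = np.zeros((512, 512), dtype=np.uint8)
        img[50:150, 60:220] = 80
        out, box = crop_brain(GraySlice(img, stage="skull_stripped"))
        assert out.pixels.shape == (100, 160)
        assert (box.xmin, box.xmax, box.ymin, box.ymax) == (50, 149, 60, 219)

    def test_idempotent(self, phantom_slice):
        _, hu, _ = phantom_slice
        stripped, _, _ = strip_skull(ncs.apply_window(hu))
        once, _ = crop_brain(stripped)
        twice, _ = crop_brain(once)
        assert np.array_equal(once.pixels, twice.pixels)

    def test_conserves_all_nonzero_pixels(self, phantom_slice):
        _, hu, _ = phantom_slice
        stripped, _, _ = strip_skull(ncs.apply_window(hu))
        cropped, _ = crop_brain(stripped)
        assert (cropped.pixels > 0).sum() == (stripped.pixels > 0).sum()
        assert cropped.pixels.sum() == stripped.pixels.sum()

    def test_all_zero_rejected(self):
        with pytest.raises(EmptyImageError):
            crop_brain(GraySlice(np.zeros((16, 16), dtype=np.uint8)))
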