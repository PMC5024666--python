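"""Mondrian generation, flat rendering, LMS conversion, display prep."""

import numpy as np
import pytest

from illumdisc import colorimetry as cm
from illumdisc import scene as sc
from illumdisc.colorimetry import CANONICAL_GRID, ChromaticityXY, Spectrum


def _uniform_reflectance_set(value=1.0):
    s = Spectrum(CANONICAL_GRID, np.full(31, value), role="reflectance")
    return sc.ReflectanceSet(surfaces=(s,) * 16, labels=tuple(str(i) for i in range(16)))


class TestGenerateMondrian:
    def test_full_coverage(self, small_scene):
        assert (small_scene.surface_map() >= 0).all()

    def test_all_surfaces_present_under_uniform_bias(self):
        scene = sc.generate_mondrian((128, 128), 2000, rng=1)
        assert (scene.pixel_shares() > 0).all()

    def test_same_seed_reproduces_rect_list(self):
        a = sc.generate_mondrian((48, 48), 300, rng=5)
        b = sc.generate_mondrian((48, 48), 300, rng=5)
        assert a.rects == b.rects

    def test_bad_bias_rejected(self):
        with pytest.raises(ValueError):
            sc.generate_mondrian((32, 32), 100, bias=np.zeros(16), rng=0)

    def test_bias_shifts_pixel_shares(self):
        bias = np.ones(16)
        bias[0] = 50.0
        scene = sc.generate_mondrian((64, 64), 800, bias=bias, rng=7)
        shares = scene.pixel_shares()
        assert shares[0] > 0.3


class TestRenderFlat:
    def test_zero_illuminant_gives_black_image(self, small_scene):
        img = sc.render_flat(small_scene, Spectrum(CANONICAL_GRID, np.zeros(31)))
        assert img.data.max() == 0.0

    def test_perfect_reflector_shows_illuminant_chromaticity(self):
        scene = sc.generate_mondrian(
            (16, 16), 100, reflectances=_uniform_reflectance_set(), rng=2
        )
        illum = cm.daylight_spectrum(6500.0)
        img = sc.render_flat(scene, illum)
        xy_img = sc.mean_chromaticity(img)
        xy_il = cm.xyz_to_xy(cm.spectrum_to_xyz(illum))
        assert xy_img.x == pytest.approx(xy_il.x, abs=1e-12)
        assert xy_img.y == pytest.approx(xy_il.y, abs=1e-12)

    def test_linear_in_illuminant(self, small_scene, target_spectrum):
        a = sc.render_flat(small_scene, target_spectrum)
        b = sc.render_flat(small_scene, target_spectrum.scaled(2.0))
        assert np.allclose(b.data, 2.0 * a.data)

    def test_repaint_changes_only_that_rectangle(self, small_scene, target_spectrum):
        base = sc.render_flat(small_scene, target_spectrum)
        idx = len(small_scene.rects) - 1  # topmost rectangle is fully visible
        x0, y0, w, h, old = small_scene.rects[idx]
        repainted = small_scene.with_surface(idx, (old + 1) % 16)
        img2 = sc.render_flat(repainted, target_spectrum)
        diff = np.any(base.data != img2.data, axis=2)
        ys, xs = np.nonzero(diff)
        assert diff.any()
        assert xs.min() >= max(x0, 0) and xs.max() < x0 + w
        assert ys.min() >= max(y0, 0) and ys.max() < y0 + h


class TestMeanChromaticity:
    def test_uniform_image(self, target_spectrum):
        data = np.tile(target_spectrum.values, (4, 4, 1))
        xy = sc.mean_chromaticity(sc.MultispectralImage(data))
        ref = cm.xyz_to_xy(cm.spectrum_to_xyz(target_spectrum))
        assert xy.x == pytest.approx(ref.x)

    def test_intensity_scale_invariance(self, small_scene, target_spectrum):
        img = sc.render_flat(small_scene, target_spectrum)
        a = sc.mean_chromaticity(img)
        b = sc.mean_chromaticity(sc.MultispectralImage(img.data * 7.0))
        assert (a.x, a.y) == (pytest.approx(b.x), pytest.approx(b.y))

    def test_half_and_half_matches_hand_computed_average(self):
        s1 = np.zeros(31); s1[5] = 1.0
        s2 = np.zeros(31); s2[20] = 1.0
        data = np.zeros((2, 2, 31))
        data[0, :, :] = s1
        data[1, :, :] = s2
        xy = sc.mean_chromaticity(sc.MultispectralImage(data))
        cmfs = cm.load_cmfs()
        xyz = 0.5 * cmfs[5] + 0.5 * cmfs[20]
        assert xy.x == pytest.approx(xyz[0] / xyz.sum())
        assert xy.y == pytest.approx(xyz[1] / xyz.sum())

    def test_black_image_rejected(self):
        with pytest.raises(ValueError):
            sc.mean_chromaticity(sc.MultispectralImage(np.zeros((2, 2, 31))))

    def test_neutral_ensemble_near_reference_chromaticity(self, target_spectrum):
        scene = sc.generate_mondrian((128, 128), 2000, rng=0)
        xy = sc.mean_chromaticity(sc.render_flat(scene, target_spectrum))
        assert np.hypot(xy.x - 0.323, xy.y - 0.357) < 0.02


class TestSelectScene:
    def test_single_candidate(self, small_scene, target_spectrum):
        got = sc.select_scene([small_scene], ChromaticityXY(0.3, 0.3), target_spectrum)
        assert got is small_scene

    def test_matches_exhaustive_oracle(self, target_spectrum):
        candidates = [sc.generate_mondrian((32, 32), 300, rng=k) for k in range(5)]
        target_xy = ChromaticityXY(0.33, 0.35)
        dists = []
        for cand in candidates:
            xy = sc.mean_chromaticity(sc.render_flat(cand, target_spectrum))
            dists.append(np.hypot(xy.x - target_xy.x, xy.y - target_xy.y))
        oracle = candidates[int(np.argmin(dists))]
        assert sc.select_scene(candidates, target_xy, target_spectrum) is oracle

    def test_empty_rejected(self, target_spectrum):
        with pytest.raises(ValueError):
            sc.select_scene([], ChromaticityXY(0.3, 0.3), target_spectrum)


class TestToLMS:
    def test_zero_image(self):
        lms = sc.to_lms(sc.MultispectralImage(np.zeros((2, 2, 31))))
        assert lms.max() == 0.0

    def test_linearity(self, small_scene, target_spectrum):
        img = sc.render_flat(small_scene, target_spectrum)
        assert np.allclose(
            sc.to_lms(sc.MultispectralImage(img.data * 3.0)), 3.0 * sc.to_lms(img)
        )

    def test_single_band_ratio_reads_off_fundamentals(self):
        i = int(np.where(CANONICAL_GRID == 560)[0][0])
        data = np.zeros((1, 1, 31))
        data[0, 0, i] = 1.0
        lms = sc.to_lms(sc.MultispectralImage(data))[0, 0]
        assert np.allclose(lms, cm.load_cone_fundamentals()[i])

    def test_grid_mismatch_rejected(self):
        with pytest.raises(ValueError, match="grid"):
            sc.to_lms(sc.MultispectralImage(np.zeros((2, 2, 31))), np.zeros((10, 3)))


class TestDisplayPrep:
    def test_gamut_scale_factor_and_ratios(self, small_scene, target_spectrum):
        imgs = [
            sc.render_flat(small_scene, target_spectrum),
            sc.render_flat(small_scene, target_spectrum.scaled(0.5)),
        ]
        scaled = sc.scale_to_gamut(imgs)
        ratio = scaled[0].data[3, 3, 10] / scaled[1].data[3, 3, 10]
        assert ratio == pytest.approx(2.0, rel=1e-9)
        peak = max(
            ((im.data @ cm.load_cmfs()) @ sc._XYZ_TO_SRGB.T).max() for im in scaled
        )
        assert peak == pytest.approx(1.0, rel=1e-9)

    def test_tone_map_truncates_constructed_pixels(self, target_spectrum):
        data = np.tile(target_spectrum.values, (6, 6, 1)) * 0.1
        bright = data.copy()
        ys, xs = np.unravel_index([1, 5, 9, 13, 22, 30, 35], (6, 6))
        for y, x in zip(ys, xs):
            bright[y, x] *= 100.0  # 7 pixels far above the cap
        imgs = [sc.MultispectralImage(data), sc.MultispectralImage(bright)]
        cap = 4.0 * (imgs[0].data @ cm.load_cmfs()[:, 1]).mean()
        lum = imgs[1].data @ cm.load_cmfs()[:, 1]
        assert (lum > cap).sum() == 7
        out = sc.tone_map_for_display(imgs, reference_index=0)
        assert out[1].dtype == np.uint8
        # the 7 capped pixels end up equal to each other (same spectrum shape)
        capped = np.unique(out[1][lum > cap].reshape(7, 3), axis=0)
        assert len(capped) == 1

    def test_tone_map_preserves_chromaticity_below_cap(self, target_spectrum):
        data = np.tile(target_spectrum.values, (4, 4, 1)) * 0.05
        out = sc.tone_map_for_display([sc.MultispectralImage(data)])[0]
        assert len(np.unique(out.reshape(-1, 3), axis=0)) == 1

    def test_empty_collection_rejected(self):
        with pytest.raises(ValueError):
            sc.scale_to_gamut([])
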