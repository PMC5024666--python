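"""Colorimetric primitives: conversions, locus geometry, ΔE, JND scale."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as hs

from illumdisc import colorimetry as cm
from illumdisc.colorimetry import (
    CANONICAL_GRID,
    ChromaticityXY,
    Spectrum,
    UCSuv,
    XYZ,
)


class TestSpectrumToXYZ:
    def test_zero_spectrum_maps_to_zero(self):
        xyz = cm.spectrum_to_xyz(Spectrum(CANONICAL_GRID, np.zeros(31)))
        assert (xyz.X, xyz.Y, xyz.Z) == (0.0, 0.0, 0.0)

    def test_equal_energy_is_illuminant_e(self):
        xy = cm.xyz_to_xy(cm.spectrum_to_xyz(Spectrum(CANONICAL_GRID, np.ones(31))))
        assert xy.x == pytest.approx(1 / 3, abs=1e-3)
        assert xy.y == pytest.approx(1 / 3, abs=1e-3)

    def test_single_band_reads_off_cmf_row(self):
        v = np.zeros(31)
        i = int(np.where(CANONICAL_GRID == 550)[0][0])
        v[i] = 2.5
        xyz = cm.spectrum_to_xyz(Spectrum(CANONICAL_GRID, v))
        row = cm.load_cmfs()[i]
        assert np.allclose([xyz.X, xyz.Y, xyz.Z], 2.5 * row)

    def test_linearity(self, rng):
        a = Spectrum(CANONICAL_GRID, rng.random(31))
        b = Spectrum(CANONICAL_GRID, rng.random(31))
        lhs = cm.spectrum_to_xyz(
            Spectrum(CANONICAL_GRID, 2.0 * a.values + 0.5 * b.values)
        ).as_array()
        rhs = 2.0 * cm.spectrum_to_xyz(a).as_array() + 0.5 * cm.spectrum_to_xyz(b).as_array()
        assert np.allclose(lhs, rhs)

    def test_grid_mismatch_names_both_grids(self):
        s = Spectrum(np.arange(400, 700, 20, dtype=float), np.ones(15))
        with pytest.raises(ValueError, match="grid mismatch"):
            cm.spectrum_to_xyz(s)


class TestChromaticity:
    def test_unit_xyz(self):
        xy = cm.xyz_to_xy(XYZ(1, 1, 1))
        assert (xy.x, xy.y) == (pytest.approx(1 / 3), pytest.approx(1 / 3))

    def test_scale_invariance(self):
        a = cm.xyz_to_xy(XYZ(0.4, 0.7, 0.2))
        b = cm.xyz_to_xy(XYZ(4.0, 7.0, 2.0))
        assert (a.x, a.y) == (pytest.approx(b.x), pytest.approx(b.y))

    def test_d65_whitepoint(self):
        xy = cm.xyz_to_xy(XYZ(0.95047, 1.0, 1.08883))
        assert xy.x == pytest.approx(0.3127, abs=2e-4)
        assert xy.y == pytest.approx(0.3290, abs=2e-4)

    def test_zero_sum_rejected(self):
        with pytest.raises(ValueError):
            cm.xyz_to_xy(XYZ(0, 0, 0))

    def test_uv1960_of_equal_energy(self):
        uv = cm.xy_to_uv1960(ChromaticityXY(1 / 3, 1 / 3))
        assert uv.u == pytest.approx(4 / 19, abs=1e-12)
        assert uv.v == pytest.approx(6 / 19, abs=1e-12)

    def test_uv1960_of_d65(self):
        uv = cm.xy_to_uv1960(ChromaticityXY(0.3127, 0.3290))
        # brute-force evaluation of the projective map
        d = -2 * 0.3127 + 12 * 0.3290 + 3
        assert uv.u == pytest.approx(4 * 0.3127 / d)
        assert uv.v == pytest.approx(6 * 0.3290 / d)
        assert uv.u == pytest.approx(0.1978, abs=2e-4)
        assert uv.v == pytest.approx(0.3122, abs=2e-4)

    @given(
        hs.floats(0.05, 0.6),
        hs.floats(0.05, 0.6),
    )
    @settings(derandomize=True, max_examples=50)
    def test_uv_xy_round_trip(self, x, y):
        if x + y >= 1.0:
            return
        uv = cm.xy_to_uv1960(ChromaticityXY(x, y))
        back = cm.uv1960_to_xy(uv)
        assert back.x == pytest.approx(x, abs=1e-12)
        assert back.y == pytest.approx(y, abs=1e-12)


class TestCIELUV:
    WHITE = XYZ(0.95047, 1.0, 1.08883)

    def test_self_difference_is_zero(self):
        p = cm.xyz_to_luv(XYZ(0.3, 0.4, 0.2), self.WHITE)
        assert cm.delta_e_luv(p, p) == 0.0

    def test_white_maps_to_origin(self):
        w = cm.xyz_to_luv(self.WHITE, self.WHITE)
        assert w.Lstar == pytest.approx(100.0, abs=1e-9)
        assert w.ustar == pytest.approx(0.0, abs=1e-9)
        assert w.vstar == pytest.approx(0.0, abs=1e-9)

    def test_against_step_by_step_oracle(self):
        # independent spreadsheet-style evaluation of the CIELUV formulas
        def oracle_luv(c, w):
            def uprime(X, Y, Z):
                d = X + 15 * Y + 3 * Z
                return 4 * X / d, 9 * Y / d

            yr = c.Y / w.Y
            L = 116 * yr ** (1 / 3) - 16 if yr > (6 / 29) ** 3 else (29 / 3) ** 3 * yr
            up, vp = uprime(c.X, c.Y, c.Z)
            un, vn = uprime(w.X, w.Y, w.Z)
            return np.array([L, 13 * L * (up - un), 13 * L * (vp - vn)])

        a, b = XYZ(0.42, 0.51, 0.30), XYZ(0.18, 0.22, 0.40)
        expected = float(
            np.sqrt(np.sum((oracle_luv(a, self.WHITE) - oracle_luv(b, self.WHITE)) ** 2))
        )
        got = cm.delta_e_luv(
            cm.xyz_to_luv(a, self.WHITE), cm.xyz_to_luv(b, self.WHITE)
        )
        assert got == pytest.approx(expected, rel=1e-12)

    def test_mismatched_whites_rejected(self):
        a = cm.xyz_to_luv(XYZ(0.3, 0.4, 0.2), self.WHITE)
        b = cm.xyz_to_luv(XYZ(0.3, 0.4, 0.2), XYZ(1.0, 1.0, 1.0))
        with pytest.raises(ValueError, match="white"):
            cm.delta_e_luv(a, b)

    def test_metric_properties_on_random_triples(self, rng):
        for _ in range(50):
            pts = [
                cm.xyz_to_luv(XYZ(*(0.05 + rng.random(3))), self.WHITE)
                for _ in range(3)
            ]
            ab = cm.delta_e_luv(pts[0], pts[1])
            ba = cm.delta_e_luv(pts[1], pts[0])
            bc = cm.delta_e_luv(pts[1], pts[2])
            ac = cm.delta_e_luv(pts[0], pts[2])
            assert ab >= 0 and ab == pytest.approx(ba)
            assert ac <= ab + bc + 1e-9


class TestPlanckianLocus:
    def test_u_monotone_decreasing_in_temperature(self):
        Ts = np.linspace(2000, 20000, 40)
        us = [cm.planckian_uv(T).u for T in Ts]
        assert np.all(np.diff(us) < 0)

    def test_against_1nm_brute_force_oracle(self):
        # direct 1 nm Planck integration, written independently
        from scipy.interpolate import PchipInterpolator

        wl = np.arange(400.0, 700.0 + 1e-9, 1.0)
        cmfs10 = cm.load_cmfs()
        cmfs = np.column_stack(
            [PchipInterpolator(CANONICAL_GRID, cmfs10[:, i])(wl) for i in range(3)]
        )
        lam = wl * 1e-9
        T = 6700.0
        planck = lam ** -5 / (np.exp(1.4388e-2 / (lam * T)) - 1.0)
        X, Y, Z = planck @ cmfs
        d = -2 * (X / (X + Y + Z)) + 12 * (Y / (X + Y + Z)) + 3
        u_oracle = 4 * (X / (X + Y + Z)) / d
        v_oracle = 6 * (Y / (X + Y + Z)) / d
        uv = cm.planckian_uv(T)
        assert uv.u == pytest.approx(u_oracle, abs=1e-9)
        assert uv.v == pytest.approx(v_oracle, abs=1e-9)

    @pytest.mark.parametrize("T", [3000.0, 6700.0, 10000.0])
    def test_cct_round_trip(self, T):
        assert cm.cct_of_uv(cm.planckian_uv(T)) == pytest.approx(T, abs=1.0)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            cm.planckian_uv(500.0)


class TestCCT:
    def test_perpendicular_displacement_preserves_cct(self):
        base = cm.planckian_uv(6700.0)
        n = cm.iso_cct_direction(6700.0)
        p = UCSuv(*(base.as_array() + 0.01 * n))
        assert cm.cct_of_uv(p) == pytest.approx(6700.0, abs=20.0)

    def test_matches_exhaustive_grid_search(self, rng):
        # independent oracle: exhaustive 1 K nearest-point search
        Ts = np.arange(2000.0, 15000.0, 1.0)
        locus = np.array([cm.planckian_uv(T).as_array() for T in Ts[::50]])
        for _ in range(5):
            T0 = float(rng.uniform(2500, 12000))
            n = cm.iso_cct_direction(T0)
            p = cm.planckian_uv(T0).as_array() + float(rng.uniform(-0.01, 0.01)) * n
            # coarse oracle bracket, then 1 K scan
            d = np.linalg.norm(locus - p, axis=1)
            Tc = Ts[::50][int(np.argmin(d))]
            scan = np.arange(max(Tc - 100, 1000), Tc + 100, 1.0)
            pts = np.array([cm.planckian_uv(t).as_array() for t in scan])
            T_oracle = scan[int(np.argmin(np.linalg.norm(pts - p, axis=1)))]
            assert cm.cct_of_uv(UCSuv(*p)) == pytest.approx(T_oracle, abs=2.0)

    def test_far_point_rejected(self):
        with pytest.raises(ValueError, match="not near"):
            cm.cct_of_uv(UCSuv(0.4, 0.1))


class TestDaylight:
    def test_d65_chromaticity(self):
        xy = cm.xyz_to_xy(cm.spectrum_to_xyz(cm.daylight_spectrum(6500.0)))
        assert np.hypot(xy.x - 0.3127, xy.y - 0.3290) < 0.002

    def test_scaling_preserves_chromaticity(self):
        s = cm.daylight_spectrum(6700.0)
        xyz = cm.spectrum_to_xyz(s)
        xy1 = cm.xyz_to_xy(xyz)
        xy2 = cm.xyz_to_xy(cm.spectrum_to_xyz(s.scaled(1.0 / xyz.Y)))
        assert xy1.x == pytest.approx(xy2.x, abs=1e-12)

    def test_d67_close_to_planckian_locus(self):
        uv = cm.xy_to_uv1960(cm.xyz_to_xy(cm.spectrum_to_xyz(cm.daylight_spectrum(6700.0))))
        assert np.linalg.norm(uv.as_array() - cm.planckian_uv(6700.0).as_array()) < 0.01

    @pytest.mark.parametrize("cct", np.linspace(4000, 10000, 7))
    def test_daylight_locus_tracks_planckian(self, cct):
        uv = cm.xy_to_uv1960(cm.xyz_to_xy(cm.spectrum_to_xyz(cm.daylight_spectrum(cct))))
        nearest = cm.planckian_uv(cm.cct_of_uv(uv))
        assert np.linalg.norm(uv.as_array() - nearest.as_array()) < 0.012

    def test_domain_error(self):
        with pytest.raises(ValueError):
            cm.daylight_spectrum(3000.0)


class TestIsoCCTDirection:
    def test_orthogonal_to_tangent(self):
        n = cm.iso_cct_direction(6700.0)
        t = (
            cm.planckian_uv(6710.0).as_array() - cm.planckian_uv(6690.0).as_array()
        )
        t /= np.linalg.norm(t)
        assert abs(float(n @ t)) < 1e-6

    def test_unit_norm(self):
        assert np.linalg.norm(cm.iso_cct_direction(6700.0)) == pytest.approx(1.0, abs=1e-12)

    def test_matches_local_quadratic_oracle(self):
        # independent oracle: fit a quadratic to the locus around 6700 K
        # and take the normal of its tangent
        Ts = np.linspace(6500, 6900, 9)
        pts = np.array([cm.planckian_uv(T).as_array() for T in Ts])
        # parametrize by u, fit v(u) quadratically
        cu = np.polyfit(pts[:, 0], pts[:, 1], 2)
        u0 = cm.planckian_uv(6700.0).u
        slope = 2 * cu[0] * u0 + cu[1]
        tangent = np.array([1.0, slope])
        tangent /= np.linalg.norm(tangent)
        normal = np.array([-tangent[1], tangent[0]])
        if normal[1] < 0:
            normal = -normal
        got = cm.iso_cct_direction(6700.0)
        assert np.allclose(got, normal, atol=1e-3)


class TestJND:
    def test_zero_scale_gives_zero(self):
        assert cm.jnd_in_delta_e(k_sd=0.0) == 0.0

    def test_linear_in_k(self):
        one = cm.jnd_in_delta_e(k_sd=1.0)
        two = cm.jnd_in_delta_e(k_sd=2.0)
        assert two == pytest.approx(2.0 * one, rel=0.01)

    def test_empty_set_rejected(self):
        with pytest.raises(ValueError):
            cm.jnd_in_delta_e(ellipses=[])

    def test_ellipse_count(self):
        assert len(cm.load_macadam_ellipses()) == 25
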