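"""Spectral and colorimetric primitives shared by the whole package.

Everything downstream — LED metamer synthesis, scene rendering, the
psychophysical parametrization of illumination change — is expressed in
terms of the objects defined here: tabulated spectra on a canonical
400–700 nm grid, CIE 1931 tristimulus values, CIE 1960 uniform
chromaticities (in which the Planckian locus and iso-CCT lines are
defined), CIELUV color differences, the CIE daylight model, and the
MacAdam (1942) chromaticity-discrimination ellipses used to calibrate
CIELUV ΔE against just-noticeable differences.

Reference data (CIE 1931 2° color-matching functions, CIE daylight
components S0/S1/S2, Stockman–Sharpe-type 2° cone fundamentals and the
25 MacAdam ellipses) ship as packaged CSV tables, already on the
canonical 10 nm grid.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from importlib import resources

import numpy as np
from scipy.interpolate import PchipInterpolator
from scipy.optimize import minimize_scalar

__all__ = [
    "CANONICAL_GRID",
    "Spectrum",
    "XYZ",
    "ChromaticityXY",
    "UCSuv",
    "LuvColor",
    "MacAdamEllipse",
    "load_cmfs",
    "load_cone_fundamentals",
    "load_daylight_components",
    "load_macadam_ellipses",
    "spectrum_to_xyz",
    "xyz_to_xy",
    "xy_to_XYZ",
    "xy_to_uv1960",
    "uv1960_to_xy",
    "uv1960_to_uvprime",
    "xyz_to_luv",
    "delta_e_luv",
    "planckian_uv",
    "cct_of_uv",
    "daylight_chromaticity",
    "daylight_spectrum",
    "iso_cct_direction",
    "jnd_in_delta_e",
    "ILLUMINANT_C_XY",
]

#: Canonical wavelength grid: 400–700 nm, 10 nm spacing, 31 bands.
CANONICAL_GRID = np.arange(400, 701, 10, dtype=float)

#: CIE illuminant C chromaticity — the adapting field of the original
#: MacAdam ellipse measurements.
ILLUMINANT_C_XY = (0.31006, 0.31616)

_NEG_CLIP_WARN = 1e-6


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Spectrum:
    """A wavelength-tabulated power or reflectance function.

    Parameters
    ----------
    wavelengths_nm : array, ascending uniform grid (canonically
        :data:`CANONICAL_GRID`).
    values : array, nonnegative power per band for illuminants/channels,
        or unitless in [0, 1] for reflectances.
    role : one of ``"illuminant"``, ``"reflectance"``, ``"channel"``.
    """

    wavelengths_nm: np.ndarray
    values: np.ndarray
    role: str = "illuminant"

    def __post_init__(self):
        wl = np.asarray(self.wavelengths_nm, dtype=float)
        v = np.asarray(self.values, dtype=float)
        if wl.ndim != 1 or v.shape != wl.shape:
            raise ValueError("wavelengths and values must be 1-D and congruent")
        if wl.size >= 2 and not np.all(np.diff(wl) > 0):
            raise ValueError("wavelength grid must be strictly ascending")
        if self.role == "reflectance":
            if np.any(v < 0) or np.any(v > 1):
                raise ValueError("reflectance values must lie in [0, 1]")
        else:
            if np.any(v < 0):
                small = -v.min() <= _NEG_CLIP_WARN * max(abs(v).max(), 1e-300)
                if small:
                    v = np.clip(v, 0.0, None)
                else:
                    raise ValueError(f"{self.role} values must be nonnegative")
        object.__setattr__(self, "wavelengths_nm", wl)
        object.__setattr__(self, "values", v)

    def assert_same_grid(self, other: "Spectrum | np.ndarray", what: str = "operand"):
        grid = other.wavelengths_nm if isinstance(other, Spectrum) else np.asarray(other)
        if self.wavelengths_nm.shape != grid.shape or not np.allclose(
            self.wavelengths_nm, grid
        ):
            raise ValueError(
                f"grid mismatch: spectrum grid "
                f"[{self.wavelengths_nm[0]}..{self.wavelengths_nm[-1]} "
                f"n={self.wavelengths_nm.size}] vs {what} grid "
                f"[{grid[0]}..{grid[-1]} n={grid.size}]"
            )

    def scaled(self, k: float) -> "Spectrum":
        return Spectrum(self.wavelengths_nm, self.values * k, self.role)


@dataclass(frozen=True)
class XYZ:
    X: float
    Y: float
    Z: float

    def as_array(self) -> np.ndarray:
        return np.array([self.X, self.Y, self.Z], dtype=float)


@dataclass(frozen=True)
class ChromaticityXY:
    x: float
    y: float


@dataclass(frozen=True)
class UCSuv:
    """CIE 1960 uniform-chromaticity-scale coordinates (v = (2/3)·v′)."""

    u: float
    v: float

    def as_array(self) -> np.ndarray:
        return np.array([self.u, self.v], dtype=float)


@dataclass(frozen=True)
class LuvColor:
    Lstar: float
    ustar: float
    vstar: float
    white: XYZ = field(compare=False, default=None)


@dataclass(frozen=True)
class MacAdamEllipse:
    """One 1942 chromaticity-discrimination ellipse, axes at 1 SD in xy."""

    center: ChromaticityXY
    semi_axes: tuple  # (a, b), a >= b > 0, xy units
    angle_deg: float

    def boundary(self, k_sd: float = 1.0, n: int = 64) -> np.ndarray:
        """(n, 2) xy points on the k_sd-scaled ellipse boundary."""
        t = np.linspace(0.0, 2 * np.pi, n, endpoint=False)
        a, b = self.semi_axes
        th = np.deg2rad(self.angle_deg)
        ex = k_sd * a * np.cos(t)
        ey = k_sd * b * np.sin(t)
        x = self.center.x + ex * np.cos(th) - ey * np.sin(th)
        y = self.center.y + ex * np.sin(th) + ey * np.cos(th)
        return np.column_stack([x, y])


# ---------------------------------------------------------------------------
# Packaged reference tables
# ---------------------------------------------------------------------------


def _load_table(name: str) -> np.ndarray:
    with resources.files("illumdisc.data").joinpath(name).open("rb") as fh:
        return np.genfromtxt(fh, delimiter=",", skip_header=1)


_cache: dict = {}


def load_cmfs() -> np.ndarray:
    """CIE 1931 2° color-matching functions, (31, 3), canonical grid."""
    if "cmfs" not in _cache:
        t = _load_table("cie1931_2deg_10nm.csv")
        assert np.allclose(t[:, 0], CANONICAL_GRID)
        _cache["cmfs"] = t[:, 1:4]
    return _cache["cmfs"]


def load_cone_fundamentals() -> np.ndarray:
    """2° cone fundamentals (L, M, S), (31, 3), canonical grid."""
    if "cones" not in _cache:
        t = _load_table("stockman_sharpe_2deg_10nm.csv")
        assert np.allclose(t[:, 0], CANONICAL_GRID)
        _cache["cones"] = t[:, 1:4]
    return _cache["cones"]


def load_daylight_components() -> np.ndarray:
    """CIE daylight components (S0, S1, S2), (31, 3), canonical grid."""
    if "daylight" not in _cache:
        t = _load_table("cie_daylight_components_10nm.csv")
        assert np.allclose(t[:, 0], CANONICAL_GRID)
        _cache["daylight"] = t[:, 1:4]
    return _cache["daylight"]


def load_macadam_ellipses() -> list:
    """The 25 MacAdam (1942) ellipses, semi-axes at 1 SD in xy units."""
    if "macadam" not in _cache:
        t = _load_table("macadam_1942_ellipses.csv")
        ells = [
            MacAdamEllipse(
                center=ChromaticityXY(row[1], row[2]),
                semi_axes=(row[3] * 1e-3, row[4] * 1e-3),
                angle_deg=row[5],
            )
            for row in t
        ]
        assert len(ells) == 25
        _cache["macadam"] = ells
    return _cache["macadam"]


# ---------------------------------------------------------------------------
# Basic conversions
# ---------------------------------------------------------------------------


def spectrum_to_xyz(s: Spectrum, cmfs: np.ndarray | None = None) -> XYZ:
    """Integrate a spectrum against the CIE 1931 2° CMFs (canonical grid).

    Linear in the spectrum. Normalization: a unit spectral power in every
    band maps Y to the plain sum of the ȳ table (no 683 lm/W factor) —
    all luminance comparisons in this package are relative.
    """
    if cmfs is None:
        cmfs = load_cmfs()
    s.assert_same_grid(CANONICAL_GRID, what="CMF")
    X, Y, Z = s.values @ cmfs
    return XYZ(float(X), float(Y), float(Z))


def xyz_to_xy(c: XYZ) -> ChromaticityXY:
    total = c.X + c.Y + c.Z
    if total <= 0:
        raise ValueError("chromaticity undefined for X+Y+Z <= 0")
    return ChromaticityXY(c.X / total, c.Y / total)


def xy_to_XYZ(c: ChromaticityXY, Y: float = 1.0) -> XYZ:
    if c.y <= 0:
        raise ValueError("y must be positive")
    return XYZ(c.x / c.y * Y, Y, (1.0 - c.x - c.y) / c.y * Y)


def xy_to_uv1960(c: ChromaticityXY) -> UCSuv:
    d = -2.0 * c.x + 12.0 * c.y + 3.0
    if d <= 0:
        raise ValueError("xy outside 1960 UCS domain (denominator <= 0)")
    return UCSuv(4.0 * c.x / d, 6.0 * c.y / d)


def uv1960_to_xy(p: UCSuv) -> ChromaticityXY:
    d = 2.0 * p.u - 8.0 * p.v + 4.0
    if d <= 0:
        raise ValueError("uv outside invertible domain")
    return ChromaticityXY(3.0 * p.u / d, 2.0 * p.v / d)


def uv1960_to_uvprime(p: UCSuv) -> tuple:
    """CIE 1976 (u′, v′) from 1960 (u, v): u′ = u, v′ = 1.5 v."""
    return p.u, 1.5 * p.v


def _uvprime_of_xyz(c: XYZ) -> tuple:
    d = c.X + 15.0 * c.Y + 3.0 * c.Z
    if d <= 0:
        raise ValueError("u'v' undefined for this XYZ")
    return 4.0 * c.X / d, 9.0 * c.Y / d


def xyz_to_luv(c: XYZ, white: XYZ) -> LuvColor:
    """CIELUV coordinates of ``c`` against reference white ``white``."""
    if white.Y <= 0:
        raise ValueError("reference white must have Y > 0")
    yr = c.Y / white.Y
    if yr > (6.0 / 29.0) ** 3:
        L = 116.0 * yr ** (1.0 / 3.0) - 16.0
    else:
        L = (29.0 / 3.0) ** 3 * yr
    up, vp = _uvprime_of_xyz(c) if c.Y > 0 or c.X > 0 or c.Z > 0 else _uvprime_of_xyz(white)
    upn, vpn = _uvprime_of_xyz(white)
    return LuvColor(L, 13.0 * L * (up - upn), 13.0 * L * (vp - vpn), white)


def delta_e_luv(a: LuvColor, b: LuvColor) -> float:
    """Euclidean CIELUV ΔE*; both colors must share one reference white."""
    if a.white is not None and b.white is not None:
        wa, wb = a.white.as_array(), b.white.as_array()
        if not np.allclose(wa, wb, rtol=1e-9, atol=1e-12):
            raise ValueError("CIELUV ΔE requires a shared reference white")
    return float(
        np.sqrt(
            (a.Lstar - b.Lstar) ** 2
            + (a.ustar - b.ustar) ** 2
            + (a.vstar - b.vstar) ** 2
        )
    )


# ---------------------------------------------------------------------------
# Planckian locus, CCT, daylight model
# ---------------------------------------------------------------------------

_C2 = 1.4388e-2  # m·K, second radiation constant

_FINE_GRID = np.arange(400.0, 700.0 + 1e-9, 1.0)


def _fine_cmfs() -> np.ndarray:
    """CMFs interpolated to a 1 nm grid for Planck integration."""
    if "fine_cmfs" not in _cache:
        cmfs = load_cmfs()
        out = np.column_stack(
            [PchipInterpolator(CANONICAL_GRID, cmfs[:, i])(_FINE_GRID) for i in range(3)]
        )
        _cache["fine_cmfs"] = np.clip(out, 0.0, None)
    return _cache["fine_cmfs"]


def _planck_radiance(wl_nm: np.ndarray, T: float) -> np.ndarray:
    lam = wl_nm * 1e-9
    spec = lam ** -5.0 / np.expm1(_C2 / (lam * T))
    return spec / spec.max()


def planckian_uv(T: float) -> UCSuv:
    """1960 uv chromaticity of a Planckian (blackbody) radiator at T kelvin."""
    if not (1000.0 <= T <= 20000.0):
        raise ValueError("Planckian locus supported for 1000 K <= T <= 20000 K")
    cmfs = _fine_cmfs()
    xyz = _planck_radiance(_FINE_GRID, T) @ cmfs
    return xy_to_uv1960(xyz_to_xy(XYZ(*xyz)))


def cct_of_uv(p: UCSuv, max_distance: float = 0.05) -> float:
    """Correlated color temperature: nearest Planckian-locus point in 1960 uv.

    Coarse 10 K grid search over 1000–20000 K followed by bounded scalar
    refinement to ~0.1 K. Raises if the point is farther than
    ``max_distance`` (uv units) from the locus.
    """
    target = p.as_array()

    if "locus_grid" not in _cache:
        Ts = np.arange(1000.0, 20000.0 + 1e-9, 10.0)
        cmfs = _fine_cmfs()
        lam = _FINE_GRID * 1e-9
        # vectorized Planck evaluation over the whole grid
        spec = lam[None, :] ** -5.0 / np.expm1(_C2 / (lam[None, :] * Ts[:, None]))
        xyz = spec @ cmfs
        ssum = xyz.sum(axis=1)
        x = xyz[:, 0] / ssum
        y = xyz[:, 1] / ssum
        d = -2.0 * x + 12.0 * y + 3.0
        _cache["locus_grid"] = (Ts, np.column_stack([4.0 * x / d, 6.0 * y / d]))
    Ts, uvs = _cache["locus_grid"]

    d2 = ((uvs - target) ** 2).sum(axis=1)
    i = int(np.argmin(d2))
    lo = Ts[max(i - 1, 0)]
    hi = Ts[min(i + 1, len(Ts) - 1)]

    def dist(T):
        return float(((planckian_uv(T).as_array() - target) ** 2).sum())

    res = minimize_scalar(dist, bounds=(lo, hi), method="bounded",
                          options={"xatol": 0.05})
    T = float(res.x)
    if np.sqrt(res.fun) > max_distance:
        raise ValueError(
            f"point ({p.u:.4f}, {p.v:.4f}) not near Planckian locus "
            f"(distance {np.sqrt(res.fun):.4f} uv > {max_distance})"
        )
    return T


def daylight_chromaticity(cct: float) -> ChromaticityXY:
    """CIE daylight-model xy chromaticity for 4000 K <= CCT <= 25000 K."""
    if not (4000.0 <= cct <= 25000.0):
        raise ValueError("CIE daylight model defined for 4000 K <= CCT <= 25000 K")
    t = 1e3 / cct
    if cct <= 7000.0:
        x = 0.244063 + 0.09911 * t + 2.9678 * t ** 2 - 4.6070 * t ** 3
    else:
        x = 0.237040 + 0.24748 * t + 1.9018 * t ** 2 - 2.0064 * t ** 3
    y = -3.000 * x ** 2 + 2.870 * x - 0.275
    return ChromaticityXY(x, y)


def daylight_spectrum(cct: float) -> Spectrum:
    """CIE daylight spectrum S0 + M1·S1 + M2·S2 on the canonical grid."""
    xy = daylight_chromaticity(cct)
    xd, yd = xy.x, xy.y
    m = 0.0241 + 0.2562 * xd - 0.7341 * yd
    m1 = (-1.3515 - 1.7703 * xd + 5.9114 * yd) / m
    m2 = (0.0300 - 31.4424 * xd + 30.0717 * yd) / m
    comps = load_daylight_components()
    vals = comps[:, 0] + m1 * comps[:, 1] + m2 * comps[:, 2]
    if vals.min() < 0:
        if -vals.min() > _NEG_CLIP_WARN * abs(vals).max():
            warnings.warn("daylight model produced non-tiny negative power; clipped")
        vals = np.clip(vals, 0.0, None)
    return Spectrum(CANONICAL_GRID, vals, role="illuminant")


def iso_cct_direction(T: float, dT: float = 10.0) -> np.ndarray:
    """Unit normal to the Planckian locus at T, in 1960 uv.

    Tangent by central finite difference; the returned normal's sign is
    chosen so its v-component is positive (pointing above the locus,
    toward larger v — the "green" side).
    """
    p_lo = planckian_uv(T - dT).as_array()
    p_hi = planckian_uv(T + dT).as_array()
    tangent = p_hi - p_lo
    tangent /= np.linalg.norm(tangent)
    normal = np.array([-tangent[1], tangent[0]])
    if normal[1] < 0:
        normal = -normal
    return normal


# ---------------------------------------------------------------------------
# JND calibration from MacAdam ellipses
# ---------------------------------------------------------------------------


def jnd_in_delta_e(
    ellipses: list | None = None,
    k_sd: float = 1.96,
    luminance_ratio: float = 1.0,
    n_boundary: int = 64,
    white_xy: tuple = ILLUMINANT_C_XY,
) -> float:
    """Mean CIELUV ΔE of the k_sd-scaled MacAdam ellipse boundaries.

    Expresses the size of the chromaticity-discrimination ellipses in
    CIELUV ΔE units: each ellipse boundary, scaled to ``k_sd`` standard
    deviations, is sampled at ``n_boundary`` parametric angles; center
    and boundary chromaticities are converted to CIELUV at a common
    luminance (``luminance_ratio`` × the white luminance, so only the
    chromatic terms u*, v* contribute) against an illuminant-C white;
    the ΔE from center to boundary is averaged over points and ellipses.

    With the conventional 1 JND = 1.96 SD this lands near 4.5 ΔE.
    """
    if k_sd < 0:
        raise ValueError("k_sd must be nonnegative")
    if ellipses is None:
        ellipses = load_macadam_ellipses()
    if len(ellipses) == 0:
        raise ValueError("empty ellipse set")
    white = xy_to_XYZ(ChromaticityXY(*white_xy), Y=1.0)
    Y = luminance_ratio * white.Y
    total = 0.0
    count = 0
    for ell in ellipses:
        c_luv = xyz_to_luv(xy_to_XYZ(ell.center, Y=Y), white)
        for bx, by in ell.boundary(k_sd=k_sd, n=n_boundary):
            b_luv = xyz_to_luv(xy_to_XYZ(ChromaticityXY(bx, by), Y=Y), white)
            total += delta_e_luv(c_luv, b_luv)
            count += 1
    return total / count
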