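"""Synthesis of the target illuminant and directional comparison series.

A tunable multichannel LED luminaire is modelled as 13 Gaussian channel
spectra; any desired illumination is approximated as a nonnegative,
spectrally smooth combination of the channels (nonnegative least squares
with a second-difference roughness penalty — the quadratic program a
physical luminaire driver solves). The target is a smooth metamer of a
6700 K daylight ("D67"); comparison illuminations form four series whose
CIELUV ΔE from the target grows 0→50 in nominal 1-ΔE steps: blue/yellow
along the Planckian locus (toward higher/lower CCT) and green/red along
the orthogonal iso-CCT line at 6700 K (above/below the locus).

The series target chromaticity is anchored at the Planckian 6700 K
point, so that the ΔE = 0 comparison coincides with the target and
blue/yellow comparisons lie on the locus itself; the target spectrum is
the smooth LED fit of the CIE daylight D67 spectrum with its
tristimulus pinned to that chromaticity.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import brentq, nnls

from illumdisc import colorimetry as cm
from illumdisc.colorimetry import (
    CANONICAL_GRID,
    ChromaticityXY,
    Spectrum,
    UCSuv,
    XYZ,
)

__all__ = [
    "LEDBasis",
    "ChannelWeights",
    "FitReport",
    "ComparisonSeries",
    "DIRECTIONS",
    "make_led_basis",
    "fit_weights",
    "quantize_weights",
    "match_luminance",
    "series_target_uv",
    "chromaticity_at_delta_e",
    "synthesize_target",
    "generate_series",
    "delta_e_between_illuminants",
]

DIRECTIONS = ("blue", "yellow", "red", "green")

TARGET_CCT = 6700.0


# ---------------------------------------------------------------------------
# LED basis
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class LEDBasis:
    """A bank of LED channel spectra (unit peak, canonical grid)."""

    channels: tuple  # of Spectrum, role="channel"
    peaks_nm: np.ndarray
    fwhm_nm: float

    @property
    def matrix(self) -> np.ndarray:
        """(31, n_channels) matrix B stacking channel spectra as columns."""
        return np.column_stack([c.values for c in self.channels])

    def __len__(self) -> int:
        return len(self.channels)


@dataclass(frozen=True)
class ChannelWeights:
    w: np.ndarray
    quantized: bool = False
    levels: int = 2 ** 16

    def __post_init__(self):
        w = np.asarray(self.w, dtype=float)
        if np.any(w < -1e-12):
            raise ValueError("channel weights must be nonnegative")
        object.__setattr__(self, "w", np.clip(w, 0.0, None))


@dataclass(frozen=True)
class FitReport:
    spectral_rms: float
    chromaticity_error_uv: float


def make_led_basis(
    n: int = 13, peaks: np.ndarray | None = None, fwhm: float = 30.0
) -> LEDBasis:
    """Gaussian channel profiles, unit peak, on the canonical grid.

    Defaults: 13 channels, peaks equally spaced 410–690 nm, FWHM 30 nm —
    a generic stand-in for an unpublished luminaire channel set.
    """
    if n < 3:
        raise ValueError("at least 3 channels are needed to span tristimulus space")
    if peaks is None:
        peaks = np.linspace(410.0, 690.0, n)
    peaks = np.asarray(peaks, dtype=float)
    if len(peaks) != n:
        raise ValueError("len(peaks) must equal n")
    if peaks.min() < CANONICAL_GRID[0] or peaks.max() > CANONICAL_GRID[-1]:
        raise ValueError("peaks must lie within the canonical grid")
    if not np.all(np.diff(peaks) > 0):
        raise ValueError("peaks must be strictly increasing")
    if fwhm <= 0:
        raise ValueError("fwhm must be positive")
    sigma = fwhm / (2.0 * np.sqrt(2.0 * np.log(2.0)))
    chans = tuple(
        Spectrum(
            CANONICAL_GRID,
            np.exp(-0.5 * ((CANONICAL_GRID - p) / sigma) ** 2),
            role="channel",
        )
        for p in peaks
    )
    return LEDBasis(channels=chans, peaks_nm=peaks, fwhm_nm=float(fwhm))


# ---------------------------------------------------------------------------
# Metamer fitting (nonnegative, smoothness-penalized least squares)
# ---------------------------------------------------------------------------


def _second_difference(n: int) -> np.ndarray:
    d = np.zeros((n - 2, n))
    for i in range(n - 2):
        d[i, i : i + 3] = (1.0, -2.0, 1.0)
    return d


def fit_weights(
    target: Spectrum,
    basis: LEDBasis,
    smoothness: float = 1e-3,
    pin_xyz: XYZ | None = None,
    xyz_weight: float = 1e4,
) -> tuple:
    """Nonnegative smooth LED approximation of a target spectrum.

    Solves ``min_w ||Bw - s||^2 + smoothness * ||D2 (Bw)||^2  s.t. w >= 0``
    where ``B`` stacks the channel spectra and ``D2`` is the second-
    difference operator, via NNLS on the stacked system. With ``pin_xyz``
    given, three heavily weighted tristimulus rows steer the solution's
    XYZ to that value (chromaticity + luminance metamerism — the
    criterion a luminaire driver actually needs).

    Returns ``(ChannelWeights, FitReport)``; the report carries the
    spectral RMS error and the 1960-uv chromaticity error of Bw vs s.
    """
    if smoothness < 0:
        raise ValueError("smoothness must be >= 0")
    target.assert_same_grid(CANONICAL_GRID, what="basis")
    B = basis.matrix
    s = target.values
    scale = max(s.max(), 1e-300)
    rows = [B]
    rhs = [s]
    if smoothness > 0:
        D2 = _second_difference(B.shape[0])
        rows.append(np.sqrt(smoothness) * (D2 @ B))
        rhs.append(np.sqrt(smoothness) * (D2 @ s))
    if pin_xyz is not None:
        cmfs = cm.load_cmfs()
        # tristimulus rows scaled to the spectrum's magnitude so the
        # penalty weight is dimensionless
        norm = xyz_weight / (scale * cmfs[:, 1].sum())
        rows.append(norm * (cmfs.T @ B))
        rhs.append(norm * pin_xyz.as_array())
    A = np.vstack(rows)
    b = np.concatenate(rhs)
    try:
        w, _ = nnls(A, b)
    except Exception as exc:  # pragma: no cover - solver pathologies
        raise RuntimeError(f"NNLS failed on {A.shape} system: {exc}") from exc

    recon = B @ w
    rms = float(np.sqrt(np.mean((recon - s) ** 2)))
    uv_err = _uv_distance(recon, s)
    return ChannelWeights(w), FitReport(rms, uv_err)


def _uv_distance(a_vals: np.ndarray, b_vals: np.ndarray) -> float:
    if a_vals.sum() <= 0 or b_vals.sum() <= 0:
        return 0.0 if np.allclose(a_vals, b_vals) else np.inf
    ua = cm.xy_to_uv1960(cm.xyz_to_xy(cm.spectrum_to_xyz(Spectrum(CANONICAL_GRID, a_vals))))
    ub = cm.xy_to_uv1960(cm.xyz_to_xy(cm.spectrum_to_xyz(Spectrum(CANONICAL_GRID, b_vals))))
    return float(np.linalg.norm(ua.as_array() - ub.as_array()))


def quantize_weights(weights: ChannelWeights, levels: int = 2 ** 16) -> ChannelWeights:
    """Snap weights to the 16-bit drive lattice of [0, w_max]."""
    w = weights.w
    wmax = w.max()
    if wmax == 0:
        return ChannelWeights(w, quantized=True, levels=levels)
    q = np.round(w / wmax * (levels - 1)) / (levels - 1) * wmax
    return ChannelWeights(q, quantized=True, levels=levels)


def match_luminance(s: Spectrum, reference: Spectrum) -> Spectrum:
    """Scale ``s`` so its Y equals the reference's Y (chromaticity fixed)."""
    y_ref = cm.spectrum_to_xyz(reference).Y
    y_s = cm.spectrum_to_xyz(s).Y
    if y_s <= 0 or y_ref <= 0:
        raise ValueError("luminance matching requires positive Y on both sides")
    return s.scaled(y_ref / y_s)


# ---------------------------------------------------------------------------
# Comparison chromaticity placement
# ---------------------------------------------------------------------------


def series_target_uv() -> UCSuv:
    """The series target chromaticity: the Planckian locus point at 6700 K."""
    return cm.planckian_uv(TARGET_CCT)


def _de_between_uv(p: UCSuv, target: UCSuv) -> float:
    """Luminance-matched CIELUV ΔE between two chromaticities.

    With the target as reference white and equal luminance, L* = 100 for
    both and ΔE reduces to 1300 × the (u′, v′) distance.
    """
    white = cm.xy_to_XYZ(cm.uv1960_to_xy(target), Y=1.0)
    c = cm.xy_to_XYZ(cm.uv1960_to_xy(p), Y=1.0)
    return cm.delta_e_luv(cm.xyz_to_luv(c, white), cm.xyz_to_luv(white, white))


def chromaticity_at_delta_e(
    direction: str, de: float, tol: float = 0.05
) -> ChromaticityXY:
    """Chromaticity at a given CIELUV ΔE from the target, per direction.

    blue/yellow: along the Planckian locus toward higher/lower CCT from
    6700 K; red/green: along the iso-CCT line (locus normal) at 6700 K,
    red below the locus (smaller v), green above. The point is located
    by 1-D root finding so the luminance-matched ΔE equals ``de`` within
    ``tol``.
    """
    if direction not in DIRECTIONS:
        raise ValueError(f"unknown direction {direction!r}")
    if de < 0:
        raise ValueError("de must be nonnegative")
    target = series_target_uv()
    if de == 0:
        return cm.uv1960_to_xy(target)

    if direction in ("blue", "yellow"):
        bound = np.log(19900.0) if direction == "blue" else np.log(2000.0)

        def f(logT):
            return _de_between_uv(cm.planckian_uv(float(np.exp(logT))), target) - de

        a, b = sorted((np.log(TARGET_CCT), bound))
        if f(bound) < 0:
            raise ValueError(
                f"ΔE {de} unreachable on the Planckian locus in direction {direction}"
            )
        root = brentq(f, a, b, xtol=1e-10)
        uv = cm.planckian_uv(float(np.exp(root)))
    else:
        normal = cm.iso_cct_direction(TARGET_CCT)
        sign = 1.0 if direction == "green" else -1.0

        def g(s):
            p = UCSuv(*(target.as_array() + sign * s * normal))
            return _de_between_uv(p, target) - de

        s_hi = 0.05
        while g(s_hi) < 0 and s_hi < 1.0:
            s_hi *= 2.0
        root = brentq(g, 0.0, s_hi, xtol=1e-12)
        uv = UCSuv(*(target.as_array() + sign * root * normal))

    achieved = _de_between_uv(uv, target)
    if abs(achieved - de) > tol:
        raise ValueError(f"placement failed: ΔE {achieved:.3f} vs requested {de}")
    return cm.uv1960_to_xy(uv)


# ---------------------------------------------------------------------------
# Series generation
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ComparisonSeries:
    """One chromatic direction's ordered comparison illuminants."""

    direction: str
    target: Spectrum
    comparisons: tuple  # of Spectrum, luminance-matched to target
    nominal_de: np.ndarray  # integers 0..n-1
    achieved_de: np.ndarray  # measured CIELUV ΔE of each comparison
    weights: tuple = field(default=(), compare=False)

    def __len__(self) -> int:
        return len(self.comparisons)

    def spectrum_at(self, nominal: int) -> Spectrum:
        return self.comparisons[int(nominal)]

    def achieved_at(self, nominal: int) -> float:
        return float(self.achieved_de[int(nominal)])

    def to_frame(self):
        import pandas as pd

        rows = []
        for k, s in enumerate(self.comparisons):
            xyz = cm.spectrum_to_xyz(s)
            xy = cm.xyz_to_xy(xyz)
            try:
                cct = cm.cct_of_uv(cm.xy_to_uv1960(xy))
            except ValueError:
                cct = np.nan
            rows.append(
                dict(
                    index=k,
                    nominal_de=int(self.nominal_de[k]),
                    achieved_de=self.achieved_de[k],
                    x=xy.x,
                    y=xy.y,
                    Y=xyz.Y,
                    cct=cct,
                )
            )
        return pd.DataFrame(rows)


def delta_e_between_illuminants(s: Spectrum, target: Spectrum) -> float:
    """CIELUV ΔE of an illuminant from the target, target as white."""
    white = cm.spectrum_to_xyz(target)
    c = cm.spectrum_to_xyz(s)
    return cm.delta_e_luv(cm.xyz_to_luv(c, white), cm.xyz_to_luv(white, white))


def daylight_prior(cct: float) -> Spectrum:
    """Spectral prior used for metamer fits: the CIE daylight spectrum,
    normalized to unit mean power (clamped to the model's CCT domain)."""
    cct = float(np.clip(cct, 4000.0, 25000.0))
    s = cm.daylight_spectrum(cct)
    return s.scaled(1.0 / s.values.mean())


def synthesize_target(basis: LEDBasis, smoothness: float = 1e-3) -> Spectrum:
    """The D67 target metamer: smooth LED fit of the CIE daylight 6700 K
    spectrum with tristimulus pinned to the Planckian 6700 K chromaticity."""
    prior = daylight_prior(TARGET_CCT)
    pin = cm.xy_to_XYZ(cm.uv1960_to_xy(series_target_uv()), Y=cm.spectrum_to_xyz(prior).Y)
    w, _ = fit_weights(prior, basis, smoothness, pin_xyz=pin)
    return Spectrum(CANONICAL_GRID, basis.matrix @ w.w, role="illuminant")


def hypothetical_longwave_series(
    basis: LEDBasis | None = None,
    n_steps: int = 51,
    cutoff_nm: float = 600.0,
    peak_nm: float = 650.0,
    fwhm_nm: float = 60.0,
) -> ComparisonSeries:
    """A constructed "red" series whose change is confined above a cutoff.

    Comparisons add power to the target solely at wavelengths above
    ``cutoff_nm`` (a truncated Gaussian bump), scaled so the CIELUV ΔE
    from the target equals each nominal step. A surface ensemble that
    reflects nothing above the cutoff renders these comparisons
    pixel-identical to the target — the thought-experiment fixture for
    ensemble-dependent sensitivity.
    """
    if basis is None:
        basis = make_led_basis()
    target = synthesize_target(basis)
    sigma = fwhm_nm / (2.0 * np.sqrt(2.0 * np.log(2.0)))
    bump = np.exp(-0.5 * ((CANONICAL_GRID - peak_nm) / sigma) ** 2)
    bump[CANONICAL_GRID <= cutoff_nm] = 0.0
    bump *= target.values.max()

    def de_at(c):
        s = Spectrum(CANONICAL_GRID, target.values + c * bump, role="illuminant")
        return delta_e_between_illuminants(s, target)

    comparisons = []
    achieved = []
    for k in range(n_steps):
        if k == 0:
            c = 0.0
        else:
            hi = 1.0
            while de_at(hi) < k and hi < 1e4:
                hi *= 2.0
            c = brentq(lambda c_: de_at(c_) - k, 0.0, hi, xtol=1e-10)
        s = Spectrum(CANONICAL_GRID, target.values + c * bump, role="illuminant")
        comparisons.append(s)
        achieved.append(de_at(c))
    return ComparisonSeries(
        direction="red",
        target=target,
        comparisons=tuple(comparisons),
        nominal_de=np.arange(n_steps),
        achieved_de=np.asarray(achieved),
    )


def generate_series(
    direction: str,
    basis: LEDBasis | None = None,
    n_steps: int = 51,
    smoothness: float = 1e-3,
    quantize: bool = False,
) -> ComparisonSeries:
    """Build one chromatic direction's full comparison series.

    For each nominal step k = 0..n_steps-1, the comparison chromaticity
    is placed at k ΔE from the target along the direction's path, a
    nonnegative smooth LED spectrum is synthesized at that chromaticity
    (tristimulus-pinned, luminance-matched to the target), optionally
    quantized to the 16-bit drive lattice, and the achieved ΔE of the
    synthesized spectrum is recorded.
    """
    if basis is None:
        basis = make_led_basis()
    target = synthesize_target(basis, smoothness)
    target_y = cm.spectrum_to_xyz(target).Y

    comparisons = []
    weights = []
    achieved = []
    for k in range(n_steps):
        xy = chromaticity_at_delta_e(direction, float(k))
        pin = cm.xy_to_XYZ(xy, Y=target_y)
        # spectral prior: nearest daylight for the on-locus directions,
        # the target spectrum itself for the iso-CCT directions
        if direction in ("blue", "yellow"):
            try:
                cct = cm.cct_of_uv(cm.xy_to_uv1960(xy))
            except ValueError:
                cct = TARGET_CCT
            prior = daylight_prior(cct)
        else:
            prior = target
        prior = prior.scaled(target_y / cm.spectrum_to_xyz(prior).Y)
        w, _ = fit_weights(prior, basis, smoothness, pin_xyz=pin)
        if quantize:
            w = quantize_weights(w)
        spec = Spectrum(CANONICAL_GRID, basis.matrix @ w.w, role="illuminant")
        spec = match_luminance(spec, target)
        comparisons.append(spec)
        weights.append(w)
        achieved.append(delta_e_between_illuminants(spec, target))

    return ComparisonSeries(
        direction=direction,
        target=target,
        comparisons=tuple(comparisons),
        nominal_de=np.arange(n_steps),
        achieved_de=np.asarray(achieved),
        weights=tuple(weights),
    )
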