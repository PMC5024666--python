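"""Mondrian surface ensembles and flat-world multispectral rendering.

Scenes are fields of overlapping random rectangles, each assigned one of
16 smooth surface reflectances; the visible surface at a pixel is the
last rectangle painted over it. Rendering is diffuse and flat: the pixel
spectrum is reflectance × illuminant, bandwise — no interreflections,
geometry or shadows. Downstream consumers are the cone-excitation
conversion, mean-chromaticity scene selection, and display preparation
(common gamut scaling and chromaticity-preserving tone mapping).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from illumdisc import colorimetry as cm
from illumdisc.colorimetry import CANONICAL_GRID, ChromaticityXY, Spectrum, XYZ

__all__ = [
    "ReflectanceSet",
    "MondrianScene",
    "MultispectralImage",
    "default_reflectances",
    "ensemble_bias",
    "generate_mondrian",
    "render_flat",
    "mean_chromaticity",
    "select_scene",
    "to_lms",
    "scale_to_gamut",
    "tone_map_for_display",
    "surface_xyz_under",
]

# XYZ (Y-relative) -> linear sRGB
_XYZ_TO_SRGB = np.array(
    [
        [3.2406, -1.5372, -0.4986],
        [-0.9689, 1.8758, 0.0415],
        [0.0557, -0.2040, 1.0570],
    ]
)


@dataclass(frozen=True)
class ReflectanceSet:
    """Exactly 16 surface reflectances on the canonical grid."""

    surfaces: tuple  # of Spectrum, role="reflectance"
    labels: tuple

    def __post_init__(self):
        if len(self.surfaces) != 16 or len(self.labels) != 16:
            raise ValueError("a reflectance set holds exactly 16 surfaces")

    @property
    def matrix(self) -> np.ndarray:
        """(16, 31) reflectance values."""
        return np.vstack([s.values for s in self.surfaces])

    @classmethod
    def from_csv(cls, path) -> "ReflectanceSet":
        """Load 16 reflectances from a CSV: wavelength_nm, then 16 columns."""
        import pandas as pd

        df = pd.read_csv(path)
        wl = df.iloc[:, 0].to_numpy(dtype=float)
        surfaces = tuple(
            Spectrum(wl, df.iloc[:, i + 1].to_numpy(dtype=float), role="reflectance")
            for i in range(16)
        )
        return cls(surfaces=surfaces, labels=tuple(df.columns[1:17]))


def _bump(center: float, width: float, amp: float) -> np.ndarray:
    return amp * np.exp(-0.5 * ((CANONICAL_GRID - center) / width) ** 2)


def default_reflectances() -> ReflectanceSet:
    """A synthetic default ensemble of 16 smooth reflectances.

    Sums of 2–3 Gaussian bumps over a low base, spanning the hue circle
    plus neutrals. The balance of the set was fixed once so that a
    uniformly sampled Mondrian rendered under the 6700 K target has a
    mean chromaticity near CIE xy (0.323, 0.357) — a mildly
    yellowish-green average, matching a printed-poster surface world
    rather than a perfectly neutral one.
    """
    specs = [
        ("red", 0.06 + _bump(640, 40, 0.55)),
        ("orange", 0.06 + _bump(600, 35, 0.50) + _bump(660, 40, 0.25)),
        ("yellow", 0.08 + _bump(575, 45, 0.62) + _bump(640, 60, 0.30)),
        ("yellow-green", 0.07 + _bump(555, 40, 0.78)),
        ("green", 0.06 + _bump(530, 35, 0.715)),
        ("teal", 0.06 + _bump(500, 35, 0.585)),
        ("cyan", 0.06 + _bump(480, 35, 0.45)),
        ("blue", 0.05 + _bump(455, 35, 0.45)),
        ("violet", 0.05 + _bump(430, 30, 0.40) + _bump(660, 50, 0.12)),
        ("purple", 0.06 + _bump(440, 35, 0.35) + _bump(640, 45, 0.28)),
        ("magenta", 0.07 + _bump(430, 40, 0.30) + _bump(620, 50, 0.42)),
        ("brown", 0.05 + _bump(610, 60, 0.28)),
        ("olive", 0.06 + _bump(565, 55, 0.455)),
        ("light-gray", np.full_like(CANONICAL_GRID, 0.55) + _bump(545, 80, 0.35)),
        ("mid-gray", np.full_like(CANONICAL_GRID, 0.30) + _bump(550, 90, 0.21)),
        ("dark-gray", np.full_like(CANONICAL_GRID, 0.12) + _bump(550, 90, 0.105)),
    ]
    surfaces = tuple(
        Spectrum(CANONICAL_GRID, np.clip(v, 0.0, 1.0), role="reflectance")
        for _, v in specs
    )
    return ReflectanceSet(surfaces=surfaces, labels=tuple(n for n, _ in specs))


#: Surfaces counted as "long-wavelength reflecting" / "short-wavelength
#: reflecting" for the ensemble-bias variants.
_REDDISH_BLUE = ("red", "orange", "magenta", "purple", "blue", "violet")
_YELLOWISH_GREEN = ("yellow", "yellow-green", "green", "olive", "teal", "cyan")


def ensemble_bias(variant: str, factor: float = 3.0) -> np.ndarray:
    """Per-surface sampling weights for the named ensemble variant.

    ``neutral`` is uniform; ``reddish_blue`` / ``yellowish_green``
    multiply the weights of the correspondingly colored surfaces.
    """
    labels = default_reflectances().labels
    w = np.ones(16)
    if variant == "neutral":
        return w
    if variant == "reddish_blue":
        boost = _REDDISH_BLUE
    elif variant == "yellowish_green":
        boost = _YELLOWISH_GREEN
    else:
        raise ValueError(f"unknown ensemble variant {variant!r}")
    for i, lab in enumerate(labels):
        if lab in boost:
            w[i] *= factor
    return w


@dataclass(frozen=True)
class MondrianScene:
    """Overlapping-rectangle layout; later rectangles overpaint earlier."""

    width: int
    height: int
    rects: tuple  # of (x0, y0, w, h, surface_index)
    seed: int
    reflectances: ReflectanceSet

    def surface_map(self) -> np.ndarray:
        """(H, W) integer map of the visible surface at each pixel, -1 = bare."""
        m = np.full((self.height, self.width), -1, dtype=np.int32)
        for x0, y0, w, h, idx in self.rects:
            m[max(y0, 0) : y0 + h, max(x0, 0) : x0 + w] = idx
        return m

    def pixel_shares(self) -> np.ndarray:
        """Fraction of pixels owned by each of the 16 surfaces."""
        m = self.surface_map()
        counts = np.bincount(m[m >= 0].ravel(), minlength=16)[:16]
        return counts / m.size

    def with_surface(self, rect_index: int, surface_index: int) -> "MondrianScene":
        rects = list(self.rects)
        x0, y0, w, h, _ = rects[rect_index]
        rects[rect_index] = (x0, y0, w, h, int(surface_index))
        return MondrianScene(
            self.width, self.height, tuple(rects), self.seed, self.reflectances
        )


@dataclass(frozen=True)
class MultispectralImage:
    """(H, W, 31) nonnegative spectral image on the canonical grid."""

    data: np.ndarray
    wavelengths_nm: np.ndarray = None

    def __post_init__(self):
        d = np.asarray(self.data, dtype=float)
        if d.ndim != 3 or d.shape[2] != len(CANONICAL_GRID):
            raise ValueError("expected an (H, W, 31) array")
        if d.min() < 0:
            raise ValueError("spectral image must be nonnegative")
        object.__setattr__(self, "data", d)
        object.__setattr__(self, "wavelengths_nm", CANONICAL_GRID)

    @property
    def shape(self):
        return self.data.shape


def generate_mondrian(
    dims: tuple = (256, 256),
    n_rects: int = 2000,
    reflectances: ReflectanceSet | None = None,
    bias: np.ndarray | None = None,
    rng: np.random.Generator | int | None = None,
    size_range: tuple = (4, 64),
) -> MondrianScene:
    """Randomly place overlapping rectangles until the canvas is covered.

    ``n_rects`` rectangles are always placed; if bare pixels remain,
    placement continues until covered (warning past 2 × n_rects).
    Deterministic given the seed. ``bias`` gives per-surface sampling
    weights (uniform by default), supporting ensemble variants.
    """
    if reflectances is None:
        reflectances = default_reflectances()
    if isinstance(rng, (int, np.integer)) or rng is None:
        seed = int(rng) if rng is not None else 0
        rng = np.random.default_rng(seed)
    else:
        seed = -1
    if bias is None:
        bias = np.ones(16)
    bias = np.asarray(bias, dtype=float)
    if np.any(bias < 0) or bias.sum() <= 0:
        raise ValueError("bias weights must be nonnegative and not all zero")
    p = bias / bias.sum()

    w_canvas, h_canvas = dims
    covered = np.zeros((h_canvas, w_canvas), dtype=bool)
    rects = []
    lo, hi = size_range
    i = 0
    while i < n_rects or not covered.all():
        if i >= 2 * n_rects and not covered.all():
            warnings.warn(
                f"coverage not reached after {i} rectangles; continuing"
            )
        w = int(rng.integers(lo, hi + 1))
        h = int(rng.integers(lo, hi + 1))
        x0 = int(rng.integers(-w + 1, w_canvas))
        y0 = int(rng.integers(-h + 1, h_canvas))
        idx = int(rng.choice(16, p=p))
        rects.append((x0, y0, w, h, idx))
        covered[max(y0, 0) : y0 + h, max(x0, 0) : x0 + w] = True
        i += 1
    return MondrianScene(
        width=w_canvas,
        height=h_canvas,
        rects=tuple(rects),
        seed=seed,
        reflectances=reflectances,
    )


def surface_xyz_under(scene: MondrianScene, illum: Spectrum) -> np.ndarray:
    """(16, 3) XYZ of each surface rendered under the illuminant."""
    illum.assert_same_grid(CANONICAL_GRID, what="scene")
    spectra = scene.reflectances.matrix * illum.values[None, :]
    return spectra @ cm.load_cmfs()


def render_flat(scene: MondrianScene, illum: Spectrum) -> MultispectralImage:
    """Diffuse flat-world rendering: pixel spectrum = reflectance × illuminant."""
    illum.assert_same_grid(CANONICAL_GRID, what="scene")
    m = scene.surface_map()
    if (m < 0).any():
        raise ValueError("scene has uncovered pixels; regenerate with coverage")
    spectra = scene.reflectances.matrix * illum.values[None, :]  # (16, 31)
    return MultispectralImage(spectra[m])


def mean_chromaticity(img: MultispectralImage) -> ChromaticityXY:
    """Chromaticity of the image's mean tristimulus (average XYZ, then project)."""
    mean_spec = img.data.mean(axis=(0, 1))
    xyz = mean_spec @ cm.load_cmfs()
    if xyz.sum() <= 0:
        raise ValueError("mean chromaticity undefined for an all-black image")
    return cm.xyz_to_xy(XYZ(*xyz))


def select_scene(
    candidates: list, target_xy: ChromaticityXY, illum: Spectrum
) -> MondrianScene:
    """The candidate whose rendered mean chromaticity is nearest target_xy.

    Euclidean xy distance; ties broken by lowest index. Uses the exact
    surface-share decomposition of the flat rendering, so no full images
    are materialized.
    """
    if len(candidates) == 0:
        raise ValueError("no candidate scenes")
    best, best_d = None, np.inf
    t = np.array([target_xy.x, target_xy.y])
    for sc in candidates:
        xyz = sc.pixel_shares() @ surface_xyz_under(sc, illum)
        xy = cm.xyz_to_xy(XYZ(*xyz))
        d = float(np.hypot(xy.x - t[0], xy.y - t[1]))
        if d < best_d - 1e-15:
            best, best_d = sc, d
    return best


def to_lms(img: MultispectralImage, fundamentals: np.ndarray | None = None) -> np.ndarray:
    """(H, W, 3) cone excitations via the embedded 2° fundamentals."""
    if fundamentals is None:
        fundamentals = cm.load_cone_fundamentals()
    if fundamentals.shape[0] != img.data.shape[2]:
        raise ValueError(
            f"grid mismatch: image has {img.data.shape[2]} bands, "
            f"fundamentals {fundamentals.shape[0]}"
        )
    return img.data @ fundamentals


def _luminance(img: MultispectralImage) -> np.ndarray:
    return img.data @ cm.load_cmfs()[:, 1]


def scale_to_gamut(images: list) -> list:
    """Scale every image by one common factor so the maximum linear
    display-primary value across the whole collection is 1."""
    if len(images) == 0:
        raise ValueError("empty collection")
    peak = 0.0
    for img in images:
        rgb = (img.data @ cm.load_cmfs()) @ _XYZ_TO_SRGB.T
        peak = max(peak, float(rgb.max()))
    if peak <= 0:
        raise ValueError("all-zero collection cannot be gamut-scaled")
    k = 1.0 / peak
    return [MultispectralImage(img.data * k) for img in images]


def tone_map_for_display(
    images: list, reference_index: int = 0
) -> list:
    """Chromaticity-preserving tone mapping to 8-bit sRGB.

    The luminance cap is 4 × the mean luminance of the reference image;
    brighter pixels are scaled down to the cap (chromaticity preserved).
    All images then share one linear-sRGB scaling to the full gamut,
    followed by the sRGB transfer curve and 8-bit quantization.
    """
    if len(images) == 0:
        raise ValueError("empty collection")
    cap = 4.0 * float(_luminance(images[reference_index]).mean())
    linear = []
    for img in images:
        Y = _luminance(img)
        f = np.ones_like(Y)
        over = Y > cap
        f[over] = cap / Y[over]
        xyz = (img.data * f[..., None]) @ cm.load_cmfs()
        linear.append(xyz @ _XYZ_TO_SRGB.T)
    peak = max(float(np.max(a)) for a in linear)
    if peak <= 0:
        peak = 1.0
    out = []
    for a in linear:
        c = np.clip(a / peak, 0.0, 1.0)
        srgb = np.where(
            c <= 0.0031308, 12.92 * c, 1.055 * np.power(c, 1.0 / 2.4) - 0.055
        )
        out.append(np.round(srgb * 255.0).astype(np.uint8))
    return out
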