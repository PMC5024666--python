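"""Simulated observers for the three-interval illumination task.

The task: a reference interval under the target illumination, then two
test intervals — one repeats the target, one carries the comparison —
and the observer names the interval most similar to the reference.
Chance is 0.5.

Two observer families stand in for human participants:

* :class:`WeibullObserver` — a purely psychometric observer whose
  percent correct is a cumulative Weibull function of the illumination
  change ΔE (guess 0.5, lapse ≤ 0.05). It bypasses images entirely and
  provides exact ground truth for parameter-recovery tests.
* :class:`MechanisticObserver` — a process model that forms a CIELUV
  summary of each interval's image (the global image mean, or one
  tracked surface), perturbs each summary with isotropic internal
  noise, and picks the test interval whose noisy summary lies nearer
  the noisy reference summary. Its sensitivity therefore depends on the
  scene's surface ensemble, which the Weibull observer's does not.

Neither is a claim about human mechanism; they are instruments for
exercising the staircase and threshold-extraction machinery.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from illumdisc import colorimetry as cm
from illumdisc import scene as sc
from illumdisc.colorimetry import XYZ

__all__ = [
    "WeibullObserver",
    "MechanisticObserver",
    "ConstantObserver",
    "TrialStimulus",
    "p_correct",
    "simulate_trial",
    "scene_summaries",
    "SummaryProvider",
    "effective_threshold",
]


@dataclass(frozen=True)
class TrialStimulus:
    """What one trial presents, reduced to what observers consume."""

    achieved_de: float
    target_summary: np.ndarray | None = None  # CIELUV 3-vector
    comparison_summary: np.ndarray | None = None


@dataclass(frozen=True)
class WeibullObserver:
    """Percent correct = 0.5 + (0.5 − λ)(1 − exp(−(ΔE/α)^β))."""

    alpha: float
    beta: float
    lapse: float = 0.0
    guess: float = 0.5

    def __post_init__(self):
        if self.alpha <= 0 or self.beta <= 0:
            raise ValueError("alpha and beta must be positive")
        if not 0 <= self.lapse <= 0.05:
            raise ValueError("lapse must lie in [0, 0.05]")

    def p_correct(self, de: float) -> float:
        return p_correct(de, self)

    def threshold(self, criterion: float = 0.7071) -> float:
        """Analytic ΔE at the criterion percent correct."""
        from illumdisc.psychometrics import invert_weibull

        return invert_weibull(self.alpha, self.beta, self.lapse, criterion)

    def respond(self, stim: TrialStimulus, rng: np.random.Generator) -> bool:
        return bool(rng.random() < self.p_correct(stim.achieved_de))


def p_correct(de: float, obs: WeibullObserver) -> float:
    """Cumulative-Weibull probability of a correct response at ΔE = de."""
    de = np.asarray(de, dtype=float)
    if np.any(de < 0):
        raise ValueError("de must be nonnegative")
    p = obs.guess + (1.0 - obs.guess - obs.lapse) * (
        1.0 - np.exp(-((de / obs.alpha) ** obs.beta))
    )
    return float(p) if p.ndim == 0 else p


@dataclass(frozen=True)
class MechanisticObserver:
    """Noisy nearest-summary decision rule in CIELUV.

    strategy: ``"global_mean"`` compares whole-image mean colors;
    ``"single_surface"`` tracks one surface's color. noise_sd is the
    isotropic internal noise per interval, in CIELUV units.
    """

    strategy: str = "global_mean"
    noise_sd: float = 1.0
    tracked_surface: int | None = None

    def __post_init__(self):
        if self.strategy not in ("global_mean", "single_surface"):
            raise ValueError(f"unknown strategy {self.strategy!r}")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be nonnegative")
        if self.strategy == "single_surface" and self.tracked_surface is None:
            raise ValueError("single_surface strategy needs a tracked_surface")

    def respond(self, stim: TrialStimulus, rng: np.random.Generator) -> bool:
        if stim.target_summary is None or stim.comparison_summary is None:
            raise ValueError("mechanistic observer needs interval summaries")
        t = np.asarray(stim.target_summary, dtype=float)
        c = np.asarray(stim.comparison_summary, dtype=float)
        noise = rng.normal(0.0, self.noise_sd, size=(3, 3))
        m_ref = t + noise[0]
        # interval order is irrelevant to correctness; evaluate the two
        # test intervals directly
        m_target = t + noise[1]
        m_comp = c + noise[2]
        d_target = np.sum((m_target - m_ref) ** 2)
        d_comp = np.sum((m_comp - m_ref) ** 2)
        if d_target == d_comp:
            return bool(rng.random() < 0.5)
        return bool(d_target < d_comp)


@dataclass(frozen=True)
class ConstantObserver:
    """Responds correct with fixed probability p — a staircase test probe."""

    p: float

    def respond(self, stim: TrialStimulus, rng: np.random.Generator) -> bool:
        return bool(rng.random() < self.p)


# ---------------------------------------------------------------------------
# Image summaries
# ---------------------------------------------------------------------------


def _summary_from_xyz(xyz: np.ndarray, white: XYZ) -> np.ndarray:
    luv = cm.xyz_to_luv(XYZ(*xyz), white)
    return np.array([luv.Lstar, luv.ustar, luv.vstar])


def summary_of_image(
    img: sc.MultispectralImage,
    strategy: str,
    white: XYZ,
    surface_mask: np.ndarray | None = None,
) -> np.ndarray:
    """CIELUV summary vector of one interval's image."""
    xyz_img = img.data @ cm.load_cmfs()
    if strategy == "global_mean":
        xyz = xyz_img.mean(axis=(0, 1))
    else:
        if surface_mask is None or not surface_mask.any():
            raise ValueError("single_surface summary needs a nonempty mask")
        xyz = xyz_img[surface_mask].mean(axis=0)
    return _summary_from_xyz(xyz, white)


def scene_summaries(
    scene: sc.MondrianScene,
    illuminants: list,
    target,
    strategy: str = "global_mean",
    tracked_surface: int | None = None,
) -> tuple:
    """Per-illuminant CIELUV summaries of a scene, computed analytically.

    Uses the surface-share decomposition of the flat rendering (no full
    images). Returns ``(target_summary, [summary per illuminant])``; the
    reference white is the scene's mean XYZ under the target
    illumination, so the target summary is (100, 0, 0).
    """
    shares = scene.pixel_shares()

    def xyz_under(illum):
        per_surface = sc.surface_xyz_under(scene, illum)
        if strategy == "global_mean":
            return shares @ per_surface
        if tracked_surface is None:
            raise ValueError("single_surface strategy needs a tracked_surface")
        return per_surface[tracked_surface]

    white_xyz = scene.pixel_shares() @ sc.surface_xyz_under(scene, target)
    white = XYZ(*white_xyz)
    t_sum = _summary_from_xyz(np.asarray(xyz_under(target)), white)
    sums = [_summary_from_xyz(np.asarray(xyz_under(il)), white) for il in illuminants]
    return t_sum, sums


class SummaryProvider:
    """Precomputed trial stimuli for one scene × comparison series.

    Maps (direction, nominal level) to a :class:`TrialStimulus` with the
    achieved ΔE and, when a scene is given, the CIELUV interval
    summaries a mechanistic observer consumes.
    """

    def __init__(
        self,
        series_by_direction: dict,
        scene: sc.MondrianScene | None = None,
        strategy: str = "global_mean",
        tracked_surface: int | None = None,
    ):
        self.series = series_by_direction
        self._stimuli = {}
        for direction, series in series_by_direction.items():
            if scene is not None:
                t_sum, sums = scene_summaries(
                    scene,
                    list(series.comparisons),
                    series.target,
                    strategy=strategy,
                    tracked_surface=tracked_surface,
                )
            else:
                t_sum, sums = None, [None] * len(series)
            self._stimuli[direction] = [
                TrialStimulus(
                    achieved_de=float(series.achieved_de[k]),
                    target_summary=t_sum,
                    comparison_summary=sums[k],
                )
                for k in range(len(series))
            ]

    def __call__(self, direction: str, level: int) -> TrialStimulus:
        return self._stimuli[direction][int(level)]


# ---------------------------------------------------------------------------
# Trial simulation and ground-truth thresholds
# ---------------------------------------------------------------------------


def simulate_trial(
    target_img: sc.MultispectralImage,
    comparison_img: sc.MultispectralImage,
    obs,
    rng: np.random.Generator,
    achieved_de: float | None = None,
    white: XYZ | None = None,
    surface_mask: np.ndarray | None = None,
) -> bool:
    """Run one three-interval trial on rendered images; True if correct.

    Weibull observers require ``achieved_de``; mechanistic observers
    form their interval summaries from the images (white defaults to the
    target image's mean XYZ).
    """
    if target_img.shape != comparison_img.shape:
        raise ValueError(
            f"image dims differ: {target_img.shape} vs {comparison_img.shape}"
        )
    if isinstance(obs, MechanisticObserver):
        if white is None:
            white = XYZ(*(target_img.data @ cm.load_cmfs()).mean(axis=(0, 1)))
        t_sum = summary_of_image(target_img, obs.strategy, white, surface_mask)
        c_sum = summary_of_image(comparison_img, obs.strategy, white, surface_mask)
        stim = TrialStimulus(achieved_de or 0.0, t_sum, c_sum)
    else:
        if achieved_de is None:
            raise ValueError("psychometric observers need achieved_de")
        stim = TrialStimulus(achieved_de)
    return obs.respond(stim, rng)


def effective_threshold(
    obs,
    series,
    stimulus_fn=None,
    criterion: float = 0.7071,
    n_per_level: int = 10_000,
    rng: np.random.Generator | int | None = 0,
) -> float:
    """Ground-truth ΔE threshold of an observer, by dense simulation.

    Simulates ``n_per_level`` trials at every series level, enforces
    monotonicity with a running maximum, and interpolates the achieved
    ΔE at which percent correct crosses ``criterion``. Raises if the
    crossing lies outside the series range (flagging the threshold as
    unbounded).
    """
    if isinstance(rng, (int, np.integer)) or rng is None:
        rng = np.random.default_rng(0 if rng is None else int(rng))
    if stimulus_fn is None:
        stimulus_fn = SummaryProvider({series.direction: series})
    pc = []
    for k in range(len(series)):
        stim = stimulus_fn(series.direction, k)
        if isinstance(obs, WeibullObserver):
            pc.append(obs.p_correct(stim.achieved_de))
        else:
            hits = sum(obs.respond(stim, rng) for _ in range(n_per_level))
            pc.append(hits / n_per_level)
    pc = np.maximum.accumulate(np.asarray(pc))
    de = np.asarray(series.achieved_de)
    if pc[-1] < criterion:
        raise ValueError(
            f"percent correct never reaches {criterion:.4f} within the series "
            f"(max {pc[-1]:.4f}); threshold unbounded"
        )
    if pc[0] >= criterion:
        return float(de[0])
    i = int(np.argmax(pc >= criterion))
    # linear interpolation between the bracketing levels
    p0, p1 = pc[i - 1], pc[i]
    d0, d1 = de[i - 1], de[i]
    if p1 == p0:
        return float(d1)
    return float(d0 + (criterion - p0) / (p1 - p0) * (d1 - d0))
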