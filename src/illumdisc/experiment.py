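"""End-to-end orchestration of simulated discrimination experiments.

One experiment = a comparison-series set (four chromatic directions), a
Mondrian scene, a roster of simulated observers, and per observer a
number of blocks of 12 interleaved staircases; trials are binned and
fitted per direction × block, block thresholds averaged per observer,
and non-excluded observers summarized as group mean ± SEM.

Two procedural dialects mirror the real-box and rendered-scene variants
of the paradigm where they affect computation: the real dialect allows
staircases down to 0 nominal ΔE and runs one block per observer; the
simulated dialect floors the staircases at 1 and runs two blocks.
Interval timings differ between dialects but are metadata only — the
simulated observers are timing-blind.

All randomness flows from one root seed through named substreams
(scene, staircases per observer × block), so identical configurations
reproduce byte-identical outputs.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from illumdisc import illuminants as il
from illumdisc import observer as ob
from illumdisc import psychometrics as ps
from illumdisc import scene as sc
from illumdisc import staircase as st
from illumdisc.colorimetry import ChromaticityXY

__all__ = [
    "ExperimentConfig",
    "ExperimentResult",
    "run_experiment",
    "replicate_scene_effect",
    "DIALECTS",
]

#: Procedural differences between the two stimulus dialects that affect
#: computation; timings are carried as metadata only.
DIALECTS = {
    "real": dict(min_level=0, n_blocks=1, interval_ms=500),
    "simulated": dict(min_level=1, n_blocks=2, interval_ms=670),
}

#: Mean-chromaticity selection targets per ensemble variant (CIE xy of
#: the rendered scene under the target illumination).
SCENE_TARGET_XY = {
    "neutral": (0.324, 0.359),
    "reddish_blue": (0.361, 0.339),
    "yellowish_green": (0.399, 0.425),
}


@dataclass(frozen=True)
class ExperimentConfig:
    seed: int
    dialect: str = "simulated"
    directions: tuple = il.DIRECTIONS
    scene_variant: str = "neutral"
    canvas: tuple = (128, 128)
    n_rects: int = 2000
    n_scene_candidates: int = 50
    observers: tuple = (ob.WeibullObserver(alpha=10.0, beta=3.0, lapse=0.01),)
    n_blocks: int | None = None  # None -> dialect default
    n_steps: int = 51
    quantize: bool = False
    staircases_per_direction: int = 3

    def __post_init__(self):
        if self.dialect not in DIALECTS:
            raise ValueError(f"unknown dialect {self.dialect!r}")
        if self.scene_variant not in SCENE_TARGET_XY:
            raise ValueError(f"unknown scene variant {self.scene_variant!r}")

    @property
    def blocks(self) -> int:
        return self.n_blocks if self.n_blocks is not None else DIALECTS[self.dialect]["n_blocks"]

    @property
    def staircase_config(self) -> st.StaircaseConfig:
        return st.StaircaseConfig(
            min_level=DIALECTS[self.dialect]["min_level"],
            max_level=self.n_steps - 1,
        )


@dataclass
class ExperimentResult:
    config: ExperimentConfig
    series: dict  # direction -> ComparisonSeries
    scene: sc.MondrianScene
    trials: pd.DataFrame
    fits: pd.DataFrame
    per_observer: pd.DataFrame
    group_summary: pd.DataFrame

    def write(self, outdir) -> None:
        """Flush the artifact bundle (CSV tables + JSON manifest)."""
        from pathlib import Path

        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        manifest = dict(seed=self.config.seed, dialect=self.config.dialect,
                        scene_variant=self.config.scene_variant, complete=False)
        try:
            self.trials.to_csv(out / "trials.csv", index=False)
            self.fits.to_csv(out / "thresholds.csv", index=False)
            self.per_observer.to_csv(out / "observer_thresholds.csv", index=False)
            self.group_summary.to_csv(out / "group_summary.csv", index=False)
            for direction, series in self.series.items():
                series.to_frame().to_csv(out / f"series_{direction}.csv", index=False)
            manifest["complete"] = True
        finally:
            (out / "manifest.json").write_text(json.dumps(manifest, indent=2))


def _build_scene(cfg: ExperimentConfig, seed: int) -> sc.MondrianScene:
    bias = sc.ensemble_bias(cfg.scene_variant)
    rng = np.random.default_rng(seed)
    candidates = [
        sc.generate_mondrian(cfg.canvas, cfg.n_rects, bias=bias,
                             rng=int(rng.integers(2 ** 31)))
        for _ in range(cfg.n_scene_candidates)
    ]
    target_xy = ChromaticityXY(*SCENE_TARGET_XY[cfg.scene_variant])
    # selection needs the target illuminant; any direction's series target works
    target = il.synthesize_target(il.make_led_basis())
    return sc.select_scene(candidates, target_xy, target)


def run_experiment(cfg: ExperimentConfig, series: dict | None = None) -> ExperimentResult:
    """Run the full pipeline: series → scene → staircases → fits → summary."""
    root = np.random.SeedSequence(cfg.seed)
    scene_seed, stair_seed = (int(s.generate_state(1)[0] % (2 ** 31)) for s in root.spawn(2))

    if series is None:
        basis = il.make_led_basis()
        series = {
            d: il.generate_series(d, basis, n_steps=cfg.n_steps, quantize=cfg.quantize)
            for d in cfg.directions
        }
    scene = _build_scene(cfg, scene_seed)

    needs_images = any(isinstance(o, ob.MechanisticObserver) for o in cfg.observers)
    trial_rows = []
    fit_rows = []
    for oi, observer in enumerate(cfg.observers):
        if isinstance(observer, ob.MechanisticObserver):
            provider = ob.SummaryProvider(
                series, scene, strategy=observer.strategy,
                tracked_surface=observer.tracked_surface,
            )
        else:
            provider = ob.SummaryProvider(series, scene if needs_images else None)
        for block in range(cfg.blocks):
            block_rng = np.random.default_rng(
                np.random.SeedSequence([stair_seed, oi, block])
            )
            records = st.run_block(
                series, observer, provider, block_rng,
                config=cfg.staircase_config,
                staircases_per_direction=cfg.staircases_per_direction,
            )
            for r in records:
                trial_rows.append(
                    dict(observer=oi, block=block, direction=r.direction,
                         staircase_id=r.staircase_id, trial_index=r.trial_index,
                         nominal_de=r.nominal_de, achieved_de=r.achieved_de,
                         response="correct" if r.correct else "incorrect")
                )
            for direction in cfg.directions:
                sub = [r for r in records if r.direction == direction]
                res = ps.PsychometricModel(ps.bin_trials(sub)).fit()
                fit_rows.append(
                    dict(observer=oi, block=block, direction=direction,
                         alpha=res.alpha, beta=res.beta, lapse=res.lapse,
                         threshold=res.threshold_7071, valid=res.valid)
                )

    trials = pd.DataFrame(trial_rows)
    fits = pd.DataFrame(fit_rows)
    per_obs, group = ps.aggregate_observer(fits)
    return ExperimentResult(cfg, series, scene, trials, fits, per_obs, group)


def replicate_scene_effect(
    cfg: ExperimentConfig, variants: tuple = ("neutral", "reddish_blue", "yellowish_green")
) -> pd.DataFrame:
    """Thresholds per scene variant × direction for one mechanistic roster.

    Runs the full pipeline once per surface-ensemble variant with a
    shared comparison-series set, and returns the variant × direction
    threshold matrix in long form with per-direction contrasts against
    the neutral variant (``contrast_vs_neutral``).
    """
    if not any(isinstance(o, ob.MechanisticObserver) for o in cfg.observers):
        raise ValueError("scene-effect replication needs mechanistic observers")
    basis = il.make_led_basis()
    series = {
        d: il.generate_series(d, basis, n_steps=cfg.n_steps, quantize=cfg.quantize)
        for d in cfg.directions
    }
    frames = []
    for variant in variants:
        res = run_experiment(replace(cfg, scene_variant=variant), series=series)
        g = res.group_summary.copy()
        g.insert(0, "scene", variant)
        frames.append(g)
    out = pd.concat(frames, ignore_index=True)
    neutral = (
        out[out["scene"] == "neutral"]
        .drop_duplicates("direction")
        .set_index("direction")["mean"]
    )
    out["contrast_vs_neutral"] = out.apply(
        lambda r: r["mean"] - neutral.get(r["direction"], np.nan), axis=1
    )
    return out
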