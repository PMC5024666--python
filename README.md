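# illumdisc

Simulation and analysis of chromatic **illumination-discrimination
experiments**: how small a change in scene illumination can an observer
detect, and how does that depend on the chromatic direction of the change
and on the surfaces in the scene?

The package re-creates the full experimental computation as a synthetic,
testable pipeline, for vision scientists who want to probe the paradigm's
machinery (stimulus construction, adaptive staircases, threshold
extraction, image-difference metrics) without human subjects or lighting
hardware:

- **Stimulus colorimetry** — a target illuminant at correlated color
  temperature 6700 K ("D67") and four series of 51 comparison
  illuminants whose CIELUV ΔE from the target grows 0→50 in ≈1 ΔE
  steps: *blue*/*yellow* along the Planckian locus (toward higher/lower
  CCT) and *green*/*red* along the orthogonal iso-CCT line (above/below
  the locus in the CIE 1960 uv diagram). One just-noticeable difference
  corresponds to roughly 4 CIELUV ΔE by the MacAdam-ellipse calibration
  (1 JND = 1.96 SD of the 1942 ellipses).
- **LED metamer synthesis** — every illuminant is realized as a
  nonnegative, spectrally smooth combination of 13 simulated LED
  channels via the quadratic program
  `min ‖Bw − s‖² + λ‖D₂(Bw)‖²  s.t. w ≥ 0`, with tristimulus pinning and
  optional 16-bit drive quantization.
- **Scene simulation** — Mondrian patterns of 2,000 overlapping random
  rectangles over a 16-member reflectance ensemble, rendered flat-world
  (pixel spectrum = reflectance × illuminant, 31 bands, 400–700 nm),
  with cone-excitation (LMS) conversion, mean-chromaticity scene
  selection, gamut scaling and sRGB tone mapping for previews.
- **Simulated observers** — a cumulative-Weibull psychometric observer
  `p(ΔE) = 0.5 + (0.5 − λ)(1 − e^{−(ΔE/α)^β})` (ground truth for
  recovery tests), and mechanistic observers that compare noisy CIELUV
  summaries of the intervals (global image mean, or one tracked
  surface) and therefore inherit scene dependence.
- **Adaptive staircases** — the 1-up–2-down rule (equilibrium at
  p = √0.5 ≈ 70.71% correct), step schedule 15→10→5→3→1 after the first
  four reversals, termination at the sixth reversal or 50 trials,
  12 staircases interleaved per block.
- **Threshold extraction** — trials pooled per direction, sorted by
  achieved ΔE, binned by 10, fitted by binomial maximum likelihood
  (guess 0.5 fixed, lapse ∈ [0, 0.05]), threshold = ΔE at 70.71%
  correct; fits with thresholds outside (1, 50) flag the observer for
  exclusion; group summaries as mean ± SEM.
- **S-CIELAB** — the spatial color-difference metric (opponent-channel
  filtering with vision-derived kernels, then pixelwise CIELAB ΔE*ab),
  used to ask whether image differences at threshold are constant
  across directions and scenes (they are not).

## Worked example

```python
import numpy as np
from illumdisc import experiment as ex, observer as ob

cfg = ex.ExperimentConfig(
    seed=11,
    observers=tuple(ob.WeibullObserver(alpha=10.0, beta=3.0, lapse=0.01)
                    for _ in range(3)),
    canvas=(48, 48), n_rects=600, n_scene_candidates=4,
)
result = ex.run_experiment(cfg)
print(result.group_summary)
```

prints

```
  direction      mean       sem  n
0      blue  9.137286  0.199627  3
1     green  8.251573  0.964824  3
2       red  8.568841  0.614133  3
3    yellow  7.982225  0.667553  3
```

Three simulated observers, two blocks each of 12 interleaved staircases:
the group-mean 70.71%-correct thresholds per direction (in CIELUV ΔE,
with SEM over observers) cluster around the analytic 70.71% point of the
generating Weibull observer (`α=10, β=3, λ=0.01` puts it at 8.19 ΔE), so
the staircase → binning → MLE → inversion chain recovers the ground
truth. A single fit is a statsmodels-style results object:

```python
from illumdisc import psychometrics as ps, staircase as st

series = {d: result.series[d] for d in ("blue",)}
records = st.run_block(series, cfg.observers[0],
                       ob.SummaryProvider(series), rng=42)
fit = ps.PsychometricModel(ps.bin_trials(records)).fit()
print(fit.summary())       # alpha, beta, lapse, threshold, validity
```

A command-line interface wraps the same pipeline:
`illumdisc generate-series`, `illumdisc make-scene`, `illumdisc run`,
`illumdisc analyze`, `illumdisc scielab`,
`illumdisc replicate-scene-effect` (see `--help` on each).

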