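# Methods

This note documents the models, numerical choices and limitations behind
`illumdisc`. It states no empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Colorimetric foundation

All spectra live on a canonical grid of 400–700 nm in 10 nm steps
(31 bands), matching the hyperspectral rendering convention of the
paradigm. Reference functions — the CIE 1931 2° color-matching
functions, the CIE daylight components S0/S1/S2, 2° cone fundamentals of
the Stockman–Sharpe type, and the 25 MacAdam (1942) chromaticity
ellipses — ship as packaged CSV tables already on this grid. Tristimulus
integration is a plain inner product against the CMF table; luminance is
relative throughout (no 683 lm/W factor). The Planckian locus is
computed by integrating Planck's law against CMFs interpolated to a
1 nm grid (PCHIP); correlated color temperature inverts the locus by a
10 K grid search over 1000–20000 K with bounded scalar refinement to
~0.1 K, rejecting points farther than 0.05 uv (1960) from the locus.
The iso-CCT direction at temperature T is the unit normal to the locus
tangent, the tangent taken by central finite difference with
ΔT = 10 K; the sign convention puts the positive normal above the locus
(larger v — the "green" side). Grid truncation to 400–700 nm biases
absolute chromaticities by well under 0.001 (the daylight-model 6500 K
spectrum lands within 0.0008 of the published D65 chromaticity; the
test suite checks 0.002).

### The JND calibration

One just-noticeable difference is expressed in CIELUV ΔE by sampling
each MacAdam ellipse boundary, scaled to 1.96 standard deviations, at
64 equally spaced parametric angles, converting center and boundary
chromaticities to CIELUV against an illuminant-C white at **equal
luminance** (so only the chromatic terms u*, v* contribute), and
averaging the center-to-boundary ΔE over points and ellipses. Under the
equal-luminance rule the white point cancels exactly in the difference
(u*_b − u*_c = 13·L*·(u′_b − u′_c)), leaving L* as the only free
scalar; the default sets sample luminance equal to the white's
(L* = 100). The computation yields ≈ 4.0 ΔE per JND at 1.96 SD; the
value scales linearly in the SD multiplier. Published estimates of this
quantity are nearer 4.5 and evidently embed additional unstated choices
(e.g. a sample-to-white luminance ratio above 1); the
`luminance_ratio` argument exposes that sensitivity rather than
hard-coding a reconciliation.

## Stimulus construction

**LED basis.** The physical luminaire's 13 channel spectra are
unpublished; the simulated basis is 13 Gaussian channels, unit peak,
peaks equally spaced 410–690 nm, FWHM 30 nm. All of this is
configurable because conclusions should be robust to the basis choice
(the basis spans tristimulus space with rank 3 for any sane setting).

**Metamer fitting.** A desired spectrum s is approximated as Bw with
w ≥ 0 by nonnegative least squares on the stacked system
[B; √λ·D₂B; heavy XYZ rows], i.e. a spectral fidelity term, a
second-difference roughness penalty on the reconstruction (λ = 1e-3
relative to unit-normalized spectra, chosen so the D67 reconstruction's
chromaticity error stays below 1e-3 uv while suppressing comb
artifacts), and three tristimulus rows weighted 1e4 that pin the
solution's XYZ. The metamer criterion is chromaticity + luminance
match, not spectral match — the criterion a luminaire driver actually
needs. Optional quantization snaps weights to a 16-bit lattice of
[0, w_max].

**Series geometry.** The series target chromaticity is anchored at the
**Planckian locus point at 6700 K**, and the target spectrum is the
smooth LED fit of the CIE daylight 6700 K spectrum with its tristimulus
pinned there. Anchoring on the locus (rather than at the daylight-model
chromaticity, which sits ≈0.003 uv above it) is what makes the series
self-consistent: the ΔE = 0 comparison coincides with the target, and
blue/yellow comparisons lie on the locus itself. Comparison placement
solves, by 1-D root finding (bisection/Brent to ΔE tolerance 0.05), for
the locus temperature (blue: toward higher CCT; yellow: lower) or the
signed distance along the iso-CCT normal (green: above; red: below)
at which the luminance-matched CIELUV ΔE from the target equals the
nominal step. Because the series is luminance-matched with the target
as reference white, that ΔE reduces to 1300 × the (u′, v′) distance.
Achieved ΔE is recomputed from the synthesized (post-QP,
post-quantization) spectrum; the full 0–50 set is generated and dialect
configuration restricts the staircase range. Which side of the locus is
"red" versus "green" is a convention (green = larger v here); it is one
sign flip if evidence ever says otherwise.

## Scene model

Scenes are Mondrians: rectangles with uniformly random width and height
in [4, 64] px placed uniformly (partial overhang allowed) until the
canvas is fully covered, at least 2,000 of them; later rectangles
overpaint earlier ones (poster layering, no alpha). Rendering is
flat-world and diffuse: pixel spectrum = reflectance × illuminant,
bandwise. This deliberately discards the path-traced interreflections,
geometry, shadows and stereo of high-fidelity renderings; every
downstream statistic that matters here (mean chromaticity, interval
summaries, S-CIELAB on flat scenes) is linear or near-linear in the
image, so the flat model preserves the logic of the paradigm while
making scene statistics exactly decomposable into per-surface
tristimulus × pixel share — which the code exploits to avoid
materializing images in inner loops.

The 16-member reflectance ensemble is synthetic (sums of 2–3 Gaussian
bumps over a low base, spanning the hue circle plus neutrals), with a
CSV loader for user-supplied sets. Its balance was fixed once so that a
uniformly sampled scene rendered under the target has mean CIE xy
chromaticity near (0.323, 0.357) — the mildly yellowish-green average
of a printed-poster surface world; the shipped set lands within 0.01.
Ensemble variants reweight sampling: `reddish_blue` and
`yellowish_green` multiply the correspondingly colored surfaces' draw
probability (×3 default), and scene selection picks, from a candidate
set (50 by default; scale up as compute allows), the scene whose
rendered mean chromaticity is nearest the variant's reference value.
Display preparation follows the standard chain — one common scale
factor to the collection's sRGB gamut, luminance cap at 4× the
reference image's mean with chromaticity preserved, sRGB transfer —
and targets the sRGB standard rather than any calibrated monitor.

## Observers

The three-interval task (reference under the target, then
target-repeat and comparison in random order) is scored as a
2-alternative choice; chance is 0.5.

*WeibullObserver* responds correct with probability
p(ΔE) = 0.5 + (0.5 − λ)(1 − exp(−(ΔE/α)^β)), λ ∈ [0, 0.05]. It ignores
images entirely, which makes it the exact ground truth for
parameter-recovery tests and a negative control for scene effects.

*MechanisticObserver* forms a CIELUV summary of each interval — the
image's mean color (`global_mean`) or one tracked surface's color
(`single_surface`), against a white fixed at the scene's mean under the
target — adds isotropic Gaussian noise (`noise_sd`, CIELUV units,
independent per interval), and chooses the test interval whose noisy
summary is nearer the noisy reference summary. This is the simplest
noise model consistent with a CIELUV decision variable; it is an
exploratory instrument, not a claim about human mechanism. Interval
timings are metadata only.

Ground-truth thresholds for any observer come from dense simulation
(default 10,000 trials per series level), a running-maximum
monotonicity repair, and linear interpolation of the 70.71% crossing;
a series that never reaches criterion raises, flagging the threshold
as unbounded.

## Staircases and threshold extraction

The 1-up–2-down rule: the second of two consecutive corrects moves the
level down, one error moves it up; equilibrium at p = √0.5 ≈ 0.7071.
Steps follow 15, 10, 5, 3, 1, advancing after each of the first four
reversals; a reversal is a realized movement whose direction flips
relative to the previous realized movement (moves fully absorbed by
clamping at the level bounds count as no movement — the standard
convention; the first flip counts as reversal 1). Termination at the
sixth reversal or 50 trials. Twelve staircases (three per direction,
starting levels drawn from 11–20, 21–30, 31–40) interleave by uniform
random draw among unfinished staircases. The real-scene dialect floors
levels at 0 and runs one block per observer; the simulated dialect
floors at 1 and runs two blocks.

Analysis pools each direction's trials across its three staircases,
sorts by achieved ΔE (stable sort; chronology breaks ties), bins by 10
with the remainder in the last bin, and fits the Weibull by binomial
maximum likelihood (guess fixed at 0.5, lapse bounded to [0, 0.05]).
α is parametrized as the 81.6%-correct point (the λ = 0 convention);
the reported threshold is always the closed-form 70.71% inversion, so
the internal parametrization is unobservable. Optimization is L-BFGS-B
on (log α, log β, λ) from a multi-start grid (log-spaced α over the
data range × β ∈ {1, 2, 4} × λ ∈ {0, 0.025}) because
staircase-concentrated data yields multimodal likelihoods; MLE was
chosen over least squares on binned proportions as the principled
default. Thresholds outside (1, 50) mark a fit invalid; an observer
with any invalid block × direction fit is excluded from the group
summary, but all rows are kept so exclusions are auditable.

## S-CIELAB

Images are transformed to the standard opponent representation, each
plane convolved with its published sum-of-Gaussians kernel
(w·exp(−x²/σ²) with σ in degrees scaled by pixels-per-degree; weights
renormalized to unit DC gain so constants pass unchanged), transformed
back to XYZ and compared pixelwise in CIELAB. Boundary handling is
symmetric reflection; kernels truncate at ±0.5° support by default.
The default viewing geometry is 17 px/° (≈ a 256 px image spanning a
15° field). The at-threshold analysis interpolates the mean metric
linearly between the series entries bracketing each direction's
threshold and reports the max/min dispersion across directions/scenes;
the package asserts only the qualitative property (dispersion > 1 —
the metric does not equalize at threshold), not any particular value.

## Problem sizes and determinism

Default test and acceptance runs use deliberately modest sizes chosen
as good statistical practice for a desk-scale reproduction: 48–128 px
canvases, 4–50 scene candidates, 3,000–10,000 trials per simulated
percent-correct estimate, 200 simulated observer-blocks for end-to-end
recovery (median |error| < 15%). All randomness descends from one root
seed through named substreams (scene, staircases per observer × block),
so identical configurations give byte-identical CSV outputs.

## Known limitations

- Flat-world rendering has no interreflections, shadows, depth or
  stereo; effects that depend on those cannot be studied here.
- The LED basis, the 16 reflectances and the cone-fundamental table are
  synthetic stand-ins with realistic shapes, not measured data; the
  cone table in particular is a best-effort transcription of the
  standard 2° fundamentals and should be replaced by an official table
  for colorimetry-critical use.
- The JND calibration's absolute level depends on the assumed
  sample-to-white luminance ratio (see above); comparisons across
  directions, which share that scalar, are unaffected.
- Mechanistic observers explore two summary strategies only; neither is
  fitted to human thresholds, and passing recovery tests says the
  *pipeline* is correct, not that humans behave like either observer.
- Simulated scenes here share one surface ensemble per run; the
  paradigm's real-scene poster statistics (rectangle sizes in cm,
  printed-ink spectra) are not mapped to pixels.
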