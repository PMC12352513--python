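# Methods

`glossjnd` studies a deceptively simple question: when two surfaces differ
only in specular roughness, how visible is that difference — and how much
does the answer depend on everything *else* in the scene (lighting, shape,
viewpoint)? Because surface reflectance is a distal property, discrimination
can only operate on proximal image structure; the package therefore predicts
gloss discriminability from image statistics and validates those predictions
against (simulated) observer judgments.

## Reflectance model and renderer

Surfaces follow the energy-conserving Ward model: a Lambertian term ρd/π per
colour channel plus the bounded-albedo specular lobe

    f_s(ωi, ωo) = ρs / (π α²) · exp(−tan²θh / α²)
                  · 2 (1 + cosθi cosθo) / (cosθi + cosθo)⁴,

with θh the half-angle to the normal. Roughness α > 0 controls lobe width;
the study pair is α = 0.01 (glossy) vs 0.19 (matte) at fixed ρs = 0.066,
ρd = (0.1, 0.3, 0.1) — a greenish object. The form is verified behaviourally
rather than by trusting transcription: the test suite checks Helmholtz
reciprocity to 1e−12 and directional-hemispherical albedo ≤ 1 by two
independent routes (cosine-weighted Monte-Carlo at 10⁵ samples for the study
material; adaptive 1-D quadrature, which resolves lobes far narrower than MC
can, for the extreme material ρs = 0.7, ρd = 0.3 down to α = 0.01).

The renderer is deliberately minimal: analytic shapes (sphere,
superellipsoid, sinusoidally bumped sphere) defined by implicit fields,
orthographic camera at a given elevation/azimuth, point / directional /
ambient lights, local shading only (no shadows, interreflections, Fresnel).
Ambient light excites only the diffuse term. What matters downstream is that
image pairs are pixel-aligned, differ only through α, and that
full = diffuse + specular holds exactly — which is asserted to float
tolerance. Ray–surface intersection uses coarse sampling (192 steps) plus
40 bisection refinements; normals come from central differences of the
implicit field (h = 1e−5).

Tone mapping is the global photographic operator with key 0.18 and burn 0,
i.e. L_d = L′/(1+L′), L′ = key·L/geomean(L), colour preserved by luminance
ratio. Display calibration maps sRGB-decoded values to
`black + (peak − black)·Y` with peak 100 cd/m², black 1 cd/m², 120 px/deg —
the viewing conditions the analysis assumes throughout. sRGB encoding uses
the standard piecewise curve; the `DisplayModel.gamma` field records a
display's configured 2.2 exponent but takes no part in calibration.

## Specular image statistics

For each image pair the pipeline computes, per threshold level k ∈
{0, 1, 3, 5, 10, 20, 30, 40} (percent of the in-mask peak):

- **diffuse removal**: max(full − diffuse, 0), so statistics see only
  specular structure;
- **thresholding**: pixels above k% of the peak survive; k = 0 keeps all
  strictly positive pixels;
- **sub-band contrast**: the thresholded image is decomposed by radial
  difference-of-Gaussians filters in the Fourier domain (DC response
  exactly zero; default octave ladder 1–128 cycles/image, which assumes
  ≥ 256 px images — the 96 px demo passes an explicit 1–48 ladder); RMS
  contrast = RMS deviation from the masked mean, per band and combined;
- **coverage**: highlighted fraction of the object mask;
- **sharpness**: (a) mean over 32×32 windows (50% overlap) of the
  log-magnitude-vs-log-frequency spectral slope, constant windows excluded;
  (b) local maximum total variation, the max over windows of mean gradient
  magnitude;
- **skewness**: third standardised moment of the masked (un-thresholded)
  specular luminance.

The pair-level predictor for each statistic is |m(test) − m(ref)| — the
judgments being modelled concern the *size* of a gloss difference, so sign
is discarded (a signed option exists). Degenerate inputs (no highlight
pixels, constant windows) produce NaN sentinels plus a warning, never silent
zeros; an ambient-only scene legitimately has an all-zero specular image.

## Visible-differences predictor

`vdp_lite` is an original reduced detection model in the classic
visible-differences lineage: octave band-limited contrast (DoG band over a
local low-pass luminance mean), CSF-weighted contrast differences, a Weibull
transducer, and across-band probability summation

    P_map = 1 − Π_b (1 − p_b),   p_b = 1 − exp(−(S_b · |Δc_b|)^β),

with β = 3.5. The CSF is a one-line photopic approximation
S(f, L) = S₀(L)·(f/4)·exp(1 − f/4), S₀(L) = 250·(L/(L+12.5))^0.4 — band-pass
in frequency with its peak fixed at 4 cpd, saturating and non-decreasing in
adapting luminance over [1, 100] cd/m²; constants live in one table.
Side-by-side viewing (the task's display mode) is modelled as a global 0.5×
sensitivity attenuation relative to flicker; contrast masking is off by
default. Band frequencies convert to cycles/degree through the display's
ppd. Pyramid depth is floor(log₂ min(H, W)) − 2.

The predictor is *not* a re-implementation of any published metric and is
not bit-comparable to one; it is kept deliberately small so every stage is
testable. Its contracts: zero map on identical pairs, symmetry in the two
images, pooled mean monotone in difference amplitude, outputs in [0, 1], and
the signature phenomenon that motivates the whole analysis — the same
roughness step that is salient under a point light is invisible under pure
ambient light (which excites no specular structure at all).

Pooled scores: mean over the full image (the default predictor downstream),
mean over the object mask, and max. All three are always emitted.

## Synthetic study and observer models

The generator reproduces the study design at desk scale: a fully crossed
shapes × lights × viewpoints factorial (a 10×10×10 design enumerates 1000
scene pairs; tests and the demo use 3×3×3 at 96 px), each cell rendered at
both roughness levels with all else identical. Viewpoints are
farthest-point-greedy selections from the upper-hemisphere vertices of a
subdivided icosahedron — deterministic, well separated, elevations in
[0°, 90°].

Observer models:

- **Quadruplet ranking task** (which of two scene pairs shows the larger
  gloss difference): Thurstone Case V on latent pair visibilities,
  P(choose i over j) = Φ((d_i − d_j)/(σ√2)). Each observer sees all 45
  unordered pairs of 10 scenes × 6 repetitions = 270 trials, giving each
  scene 54 selection opportunities, preceded by 20 practice trials with
  known answers.
- **2AFC roughness discrimination** (method of constant stimuli): standard
  α = 0.1 against the ten log-spaced comparisons 0.0702…0.1298, 40
  repetitions each; P(comparison judged glossier) = λ + (1−2λ)·Φ(s·(pse −
  log α)), Bernoulli draws per trial.

Everything is seeded and bitwise reproducible. What the simulations do *not*
emulate: individual-difference structure beyond one σ or λ, sequential
effects, response times, lapses correlated with difficulty, or the image
ambiguity of real photographs — so passing recovery tests shows the analysis
chain is correct and adequately powered, not that real observers behave this
way.

## Behavioural analysis

Per participant, selection frequencies are tallied per scene; gates follow
the study protocol: a 90% practice-accuracy gate, then a one-sided lower
Tukey fence on each participant's mean Pearson correlation with the others
(excluded if below Q1 − 1.5·IQR; zero-variance frequency vectors are
excluded as degenerate). The published rule's wording ("exceeds the IQR ×
1.5") is ambiguous; since it targets *low*-correlation responders, the lower
fence is the faithful reading. Kept participants are pooled
trial-weighted. Predictors relate to pooled proportions by Pearson
correlation, by a binomial-logit GLM on (chosen, opportunities) — family
chosen because the response is a choice frequency; Gaussian-identity is
available as an option — and by OLS on z-scored cues (the cue-combination
model), which reports per-cue weights and the model correlation.

## Psychometric fitting

Maximum likelihood on the level table with lapse bounded in [0, 0.1], a
slight ridge (1e−4·s²) to keep separable data finite, and
multi-start L-BFGS-B (four deterministic starts, one with reversed slope
sign so reverse-coded responses simply negate the slope). Data that never
cross 0.5 are declared non-identifiable — an explicit failure status, never
a silent estimate. The reported slope is s in 1/log-units; dP/dlog α at the
PSE is (1−2λ)·s·φ(0). Uncertainty comes from a within-level nonparametric
bootstrap (percentile CI; refits warm-start at the point estimate);
condition differences are significant when the bootstrap CI of the slope
difference excludes zero.

Recovery at the study's trial counts (40 reps × 10 levels) is
median-unbiased within a few percent across slopes 5–20 per log-unit and
PSE shifts of ±0.05 log-units; the power check plants a 2× slope ratio
(7 vs 14) with lapse-free simulated observers and requires detection in
≥ 90% of 100 experiments.

## Factor importance

A random forest (500 trees, unlimited depth, one-hot factors, impurity
importances normalised to sum 1; permutation importances as an optional
cross-check) attributes variance in the per-scene discriminability score to
lighting, shape and viewpoint; per-level means ± SD give descriptive bounds,
and `percentile_scene` selects scenes at the 10th/90th percentile of the
score distribution (nearest-to-linear-interpolated-percentile convention,
ties to the smaller scene id; a decile-bin convention is also exposed).

## Numerical choices and problem sizes

Desk-scale defaults were chosen once as realistic for the study conditions:
96 px images, 3×3×3 factorial (27 pairs), 15 observers × 6 reps for ranking
recovery, 40 reps for 2AFC, 20 seeds for batch medians, 101 seeds for
median-bias estimates, 100 seeds for the power check, Monte-Carlo albedo at
10⁵ samples. The full pipeline on the 3×3×3 design runs in well under five
minutes on one CPU. Tolerances: reciprocity 1e−12 (analytic symmetry),
component additivity 1e−6 relative, sub-band DC leakage < 1e−8, detection
map zero-on-identity < 1e−6.

## Known limitations

- The renderer's local shading omits occlusion of light sources, so "point
  light" scenes lack cast shadows that real photographs would have.
- The DoG band ladder and CSF constants are reasonable but not fitted to
  any observer data; the vdp scores are ordinal predictors, not calibrated
  detection probabilities.
- The sharpness spectral slope is undefined on highlight-free images (NaN
  sentinel); analyses that consume it must handle missingness.
- Percentile conventions differ slightly from histogram-binning approaches;
  both are exposed, defaults documented above.
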